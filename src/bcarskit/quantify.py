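"""Band integration, substrate masking and group statistics.

Chemical concentration maps are produced by integrating the retrieved
Raman-like cube over marker bands (amide I 1620-1690 cm^-1 for protein,
triglyceride ester 1715-1760 cm^-1 for lipid).  Before comparing groups,
substrate pixels (no tissue: negligible CH-stretch signal) and outliers
are removed with one shared rule so the statistics of the compared
images are not distorted.  Group differences are assessed with a
two-sided Mann-Whitney rank test (null: equal medians).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .containers import Hypercube

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    """A named integration band [lo, hi] in cm^-1."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("band must satisfy lo < hi")


#: protein marker band (amide I)
AMIDE_I = BandDefinition("amide I", 1620.0, 1690.0)
#: lipid marker band (triglyceride ester carbonyl)
TRIGLYCERIDE = BandDefinition("triglycerides", 1715.0, 1760.0)
#: CH-stretch total, used as the default tissue-presence band
CH_STRETCH = BandDefinition("CH stretch", 2800.0, 3020.0)


def integrate_band(cube: Hypercube, band: BandDefinition) -> np.ndarray:
    """Per-pixel trapezoidal integral over the band, in (units x cm^-1)."""
    mask = cube.axis.select(band.lo, band.hi)
    if mask.sum() < 2:
        raise ValueError(
            f"band {band.name!r} selects {int(mask.sum())} channels; need >= 2"
        )
    x = cube.axis.values[mask]
    return np.trapezoid(cube.data[..., mask], x, axis=-1)


@dataclass(frozen=True)
class OutlierRule:
    """Drop values outside median +- factor * IQR (disabled when factor is
    None)."""

    factor: float | None = 5.0

    def keep(self, values: np.ndarray) -> np.ndarray:
        if self.factor is None:
            return np.ones(values.shape, dtype=bool)
        med = np.median(values)
        q25, q75 = np.percentile(values, [25, 75])
        iqr = q75 - q25
        lo, hi = med - self.factor * iqr, med + self.factor * iqr
        return (values >= lo) & (values <= hi)


def mask_and_filter(
    image: np.ndarray,
    substrate_threshold: float,
    outlier_rule: OutlierRule | None = None,
    presence_image: np.ndarray | None = None,
) -> np.ndarray:
    """Flatten an intensity image to the pixel values that enter statistics.

    Pixels whose tissue-presence value (from `presence_image`, typically a
    CH-stretch band integral; defaults to `image` itself) falls below
    `substrate_threshold` are dropped, then `outlier_rule` is applied to
    the remaining values.  Apply the SAME threshold and rule to every
    compared image.
    """
    if np.isnan(substrate_threshold):
        raise ValueError("substrate threshold must not be NaN")
    # -inf is allowed and disables the substrate mask
    image = np.asarray(image, dtype=float)
    presence = image if presence_image is None else np.asarray(presence_image)
    if presence.shape != image.shape:
        raise ValueError("presence image shape must match")
    values = image[presence >= substrate_threshold]
    n_substrate = image.size - values.size
    if outlier_rule is None:
        outlier_rule = OutlierRule()
    if values.size:
        keep = outlier_rule.keep(values)
        n_outliers = int(values.size - keep.sum())
        values = values[keep]
    else:
        n_outliers = 0
    logger.info(
        "mask_and_filter: dropped %d substrate and %d outlier pixels, kept %d",
        n_substrate, n_outliers, values.size,
    )
    if values.size == 0:
        raise ValueError("masking removed every pixel")
    return values


@dataclass(frozen=True)
class BoxStats:
    """Box-plot summary: quartiles by linear interpolation, 1.5 IQR
    whiskers."""

    median: float
    mean: float
    q25: float
    q75: float
    iqr: float
    whisker_lo: float
    whisker_hi: float
    n: int


def box_stats(values) -> BoxStats:
    """Box-plot statistics; whiskers at the most extreme data within
    quartiles +- 1.5 IQR."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size < 4:
        raise ValueError("need at least 4 values for box statistics")
    q25, med, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    inside = v[(v >= q25 - 1.5 * iqr) & (v <= q75 + 1.5 * iqr)]
    return BoxStats(
        median=float(med), mean=float(v.mean()), q25=float(q25), q75=float(q75),
        iqr=float(iqr), whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()), n=int(v.size),
    )


def _exact_mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided test by enumeration of all group assignments.

    Uses midranks, so ties are handled; feasible for min(n) <= 8 and
    moderate totals.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n2 = a.size, b.size
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    total = n1 + n2
    count_le = 0
    count_ge = 0
    n_assign = comb(total, n1)
    for idx in combinations(range(total), n1):
        u = float(np.sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2)
        if u <= u_obs + 1e-12:
            count_le += 1
        if u >= u_obs - 1e-12:
            count_ge += 1
    p = min(1.0, 2.0 * min(count_le, count_ge) / n_assign)
    return u_obs, p


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group A, p-value).

    U counts, over all cross-group pairs, how often a value of group A
    exceeds one of group B (ties count 1/2); U = 0 when every A value lies
    below every B value.  Small samples (min(n) <= 8, <= 2x10^5
    assignments) are tested by exact enumeration with midranks; larger
    samples use the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if min(a.size, b.size) <= 8 and comb(a.size + b.size, a.size) <= 200_000:
        return _exact_mann_whitney(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             use_continuity=True, method="asymptotic")
    return float(res.statistic), float(res.pvalue)
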