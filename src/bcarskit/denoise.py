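"""Variance-stabilized SVD denoising of hypercubes.

SVD truncation is optimal for additive white Gaussian noise, but CCD
counts carry mixed Poisson-Gaussian noise whose variance scales with the
signal.  The Anscombe transform x -> 2 sqrt(x + 3/8) (or its generalized
form when the detector gain and read noise are known) stabilizes the
variance to ~1, after which the cube is unfolded to an s x p matrix
(rows = spectral channels, columns = pixels), decomposed as M = U S V*,
the singular values beyond a cutoff are zeroed, the matrix is rebuilt as
M-hat = U S-hat V*, refolded, and mapped back through the inverse
transform.

The cutoff can be a fixed rank, a singular-value threshold, or an
automatic knee estimate on the log singular-value scree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import Hypercube

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Anscombe transform


def anscombe(values, gain: float = 1.0, sigma: float = 0.0):
    """Generalized Anscombe variance-stabilizing transform.

    For pure Poisson data (``gain=1, sigma=0``) this is 2 sqrt(x + 3/8);
    with detector gain g (counts per photoelectron) and Gaussian read noise
    sigma it becomes (2/g) sqrt(g x + 3/8 g^2 + sigma^2).  The transformed
    noise has variance ~1.
    """
    x = np.asarray(values, dtype=float)
    if gain <= 0:
        raise ValueError("gain must be positive")
    offset = 0.375 * gain**2 + sigma**2
    arg = gain * x + offset
    if np.any(arg < 0):
        raise ValueError(
            f"values below the transform domain; minimum allowed is "
            f"{-offset / gain:.4f}"
        )
    return (2.0 / gain) * np.sqrt(arg)


def inverse_anscombe(values, gain: float = 1.0, sigma: float = 0.0):
    """Algebraic inverse of :func:`anscombe` (exact round trip)."""
    y = np.asarray(values, dtype=float)
    offset = 0.375 * gain**2 + sigma**2
    return ((gain * y / 2.0) ** 2 - offset) / gain


# ---------------------------------------------------------------------------
# unfold / refold


def unfold(cube_data: np.ndarray) -> np.ndarray:
    """(m, n, s) cube -> (s, p) matrix with p = m*n pixel columns."""
    m, n, s = cube_data.shape
    return cube_data.reshape(m * n, s).T


def refold(matrix: np.ndarray, shape: tuple) -> np.ndarray:
    """(s, p) matrix -> (m, n, s) cube; exact inverse of :func:`unfold`."""
    m, n, s = shape
    return matrix.T.reshape(m, n, s)


@dataclass
class SVDResult:
    """Factors of the unfolded matrix with the kept rank."""

    U: np.ndarray
    S: np.ndarray
    Vt: np.ndarray
    rank_kept: int


def _knee_rank(s: np.ndarray) -> int:
    """Knee of the log-scree: farthest point from the line joining its ends."""
    y = np.log(np.maximum(s, np.finfo(float).tiny))
    x = np.arange(y.size, dtype=float)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    d = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    return max(1, int(np.argmax(d)))


class AnscombeSVDDenoiser(BaseEstimator, TransformerMixin):
    """Anscombe + truncated-SVD hypercube denoiser.

    Parameters
    ----------
    rank : int or None
        Number of singular values kept.  Mutually exclusive with
        `threshold`; if both are None the knee of the log scree is used.
    threshold : float or None
        Keep singular values >= threshold instead of a fixed rank.
    gain, sigma : float
        Detector gain (counts/photoelectron) and Gaussian read-noise sigma
        for the generalized Anscombe transform.
    stabilize : bool
        Apply the Anscombe transform before the SVD (default).  Disable
        for data whose noise is already additive Gaussian; the truncation
        then acts directly on the counts and exact low-rank inputs are
        reproduced exactly.

    Attributes
    ----------
    singular_values_ : ndarray
        Full singular-value spectrum of the stabilized unfolded matrix.
    rank_ : int
        Rank actually kept.
    """

    def __init__(self, rank: int | None = 6, threshold: float | None = None,
                 gain: float = 1.0, sigma: float = 0.0, stabilize: bool = True):
        self.rank = rank
        self.threshold = threshold
        self.gain = gain
        self.sigma = sigma
        self.stabilize = stabilize

    # -- internal ----------------------------------------------------------

    def _stabilize(self, data):
        if not self.stabilize:
            return data, 0.0
        lo = float(data.min())
        floor = -(0.375 * self.gain**2 + self.sigma**2) / self.gain
        shift = 0.0
        if lo < floor:
            # negative counts from dark subtraction: shift into the domain
            shift = floor - lo
            logger.info("offsetting data by %.3f before Anscombe", shift)
        return anscombe(data + shift, self.gain, self.sigma), shift

    def _pick_rank(self, s: np.ndarray) -> int:
        if self.rank is not None and self.threshold is not None:
            raise ValueError("specify rank or threshold, not both")
        if self.threshold is not None:
            return max(1, int(np.sum(s >= self.threshold)))
        if self.rank is None:
            return _knee_rank(s)
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.rank >= s.size:
            warnings.warn(
                "requested rank >= full rank; denoising is a no-op", stacklevel=2
            )
            return s.size
        return int(self.rank)

    # -- sklearn surface ----------------------------------------------------

    def fit(self, X: Hypercube, y=None):
        """Decompose the stabilized unfolded cube; store factors and rank."""
        data = X.data if isinstance(X, Hypercube) else np.asarray(X, dtype=float)
        if data.ndim != 3:
            raise ValueError("expected an (m, n, s) cube or Hypercube")
        if not np.all(np.isfinite(data)):
            raise ValueError("cube contains non-finite values")
        stab, shift = self._stabilize(data)
        mat = unfold(stab)
        U, s, Vt = np.linalg.svd(mat, full_matrices=False)
        self.svd_ = SVDResult(U=U, S=s, Vt=Vt, rank_kept=self._pick_rank(s))
        self.singular_values_ = s
        self.rank_ = self.svd_.rank_kept
        self._shift = shift
        self._shape = data.shape
        return self

    def transform(self, X: Hypercube):
        """Reconstruct from the leading `rank_` components of the fitted cube.

        The denoiser is fit per cube (the factorization belongs to one
        dataset); `X` must be the cube passed to :meth:`fit`.
        """
        check_is_fitted(self, "svd_")
        data = X.data if isinstance(X, Hypercube) else np.asarray(X, dtype=float)
        if data.shape != self._shape:
            raise ValueError("transform expects the cube the denoiser was fit on")
        r = self.rank_
        U, s, Vt = self.svd_.U, self.svd_.S, self.svd_.Vt
        rec = (U[:, :r] * s[:r]) @ Vt[:r]
        out = refold(rec, self._shape)
        if self.stabilize:
            out = inverse_anscombe(out, self.gain, self.sigma) - self._shift
        if isinstance(X, Hypercube):
            return X.with_data(out)
        return out

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)


def svd_denoise(cube: Hypercube, cutoff: int | float = 6,
                gain: float = 1.0, sigma: float = 0.0) -> Hypercube:
    """One-call denoising: integer `cutoff` = rank, float = singular-value
    threshold."""
    if isinstance(cutoff, (int, np.integer)):
        est = AnscombeSVDDenoiser(rank=int(cutoff), gain=gain, sigma=sigma)
    else:
        est = AnscombeSVDDenoiser(rank=None, threshold=float(cutoff),
                                  gain=gain, sigma=sigma)
    return est.fit_transform(cube)
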