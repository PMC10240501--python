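"""Two-color and three-color Raman excitation profiles.

A vibrational coherence at Raman shift Omega is driven by every pair of
excitation frequencies separated by Omega.  Summed over the spectra this
is a cross-correlation over frequency detuning:

* two-color:   X2(Omega) = (E_S * E_p)(Omega) = int conj(E_S(w)) E_p(w+Omega) dw
  — one pump and one Stokes photon; covers shifts equal to the
  pump-Stokes detuning range (up to ~3400 cm^-1 for a 1035 nm pump and a
  Stokes reaching 1600 nm).
* three-color: X3(Omega) = (E_S * E_S)(Omega)
  — two photons of the broadband Stokes alone (impulsive/ISRS
  excitation).  The number of intra-pulse frequency pairs at separation
  Omega shrinks with Omega, so the profile peaks at Omega -> 0 and
  vanishes at the Stokes spectral width; spectral chirp scrambles the
  pair phases and suppresses it further.

The correlations are evaluated with the complex fields (phases included),
so chirp and pump delay act on the profiles exactly as they act on the
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axes import WavenumberAxis
from .fields import SpectralField


def complex_cross_correlation(a: SpectralField, b: SpectralField):
    """(b star a)(Omega) = sum conj(b(w)) a(w+Omega) dw on the discrete lag grid.

    Returns (lags_cm1, values): `values[k]` pairs every sample of `b` with the
    sample of `a` lying `lags_cm1[k]` above it.  Fields must share the grid
    step.
    """
    da, db = a.step_cm1, b.step_cm1
    if not np.isclose(da, db, rtol=1e-6):
        raise ValueError("fields must share the same frequency-grid step")
    c = np.correlate(a.amplitude, b.amplitude, mode="full") * da
    nb = b.amplitude.size
    k = np.arange(c.size)
    lags = (a.frequency_cm1[0] - b.frequency_cm1[0]) + (k - (nb - 1)) * da
    return lags, c


@dataclass(frozen=True)
class ExcitationProfile:
    """Nonnegative two- and three-color excitation amplitudes per channel."""

    axis: WavenumberAxis
    two_color_weight: np.ndarray
    three_color_weight: np.ndarray

    def __post_init__(self):
        for name in ("two_color_weight", "three_color_weight"):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.shape != self.axis.values.shape:
                raise ValueError(f"{name} must match the axis length")
            if np.any(w < 0):
                raise ValueError(f"{name} must be nonnegative")
            object.__setattr__(self, name, w)


def excitation_profiles(
    pump: SpectralField,
    stokes: SpectralField,
    axis: WavenumberAxis | None = None,
) -> ExcitationProfile:
    """Map |pump-Stokes| and |Stokes-Stokes| cross-correlations onto a Raman axis.

    If `axis` is omitted, a uniform axis at the field grid step covering all
    positive two-color lags is used.
    """
    lag2, x2 = complex_cross_correlation(pump, stokes)
    lag3, x3 = complex_cross_correlation(stokes, stokes)
    if lag2[-1] <= 0:
        raise ValueError(
            "pump and Stokes grids yield no positive Raman shift; disjoint or"
            " reversed grids"
        )
    if axis is None:
        step = pump.step_cm1
        n = max(16, int(np.floor(lag2[-1] / step)) + 1)
        axis = WavenumberAxis(step * np.arange(n))
    w2 = np.interp(axis.values, lag2, np.abs(x2), left=0.0, right=0.0)
    w3 = np.interp(axis.values, lag3, np.abs(x3), left=0.0, right=0.0)
    return ExcitationProfile(axis=axis, two_color_weight=w2, three_color_weight=w3)


def two_color_coverage_cm1(pump_center_nm: float, stokes_edge_nm: float) -> float:
    """Highest Raman shift reachable by two-color excitation.

    For a pump at `pump_center_nm` and a Stokes spectrum extending to
    `stokes_edge_nm` on the long-wavelength side, the maximum pump-Stokes
    detuning is 1e7*(1/pump - 1/edge) cm^-1 (~3400 cm^-1 for 1035/1600 nm).
    """
    if stokes_edge_nm <= pump_center_nm:
        raise ValueError("Stokes edge must lie beyond the pump wavelength")
    return 1e7 * (1.0 / pump_center_nm - 1.0 / stokes_edge_nm)
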