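"""Nonresonant-background removal by time-domain Kramers-Kronig retrieval.

A raw CARS spectrum is |chi_R + chi_NR|^2 filtered by the instrument: the
resonances ride on the nonresonant background as dispersive, shifted
lineshapes.  Because chi(Omega) is analytic in the upper half plane
(causal response) and the NRB is spectrally flat, the log-magnitude and
the phase of chi/chi_NR form a Hilbert-transform pair:

    phi(Omega) = H[ 1/2 ln R ](Omega),      R = I_CARS / I_NRB

where I_NRB is the spectrum of a resonance-free reference (bare quartz).
The complex spectrum sqrt(R) exp(i phi) then has an imaginary part
proportional to Im chi_R — a Raman-like spectrum with peaks back at the
true mode positions, directly comparable to spontaneous Raman.

The Hilbert transform is evaluated in the time domain via FFT on a
smoothly continued, padded copy of the log ratio.  A residual slowly
varying "error phase" — from the mismatch between the quartz reference
and the true in-sample NRB and from excitation-envelope leakage — is
estimated with a long-window Savitzky-Golay smoother on phi and
subtracted before the imaginary part is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import hilbert, savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .axes import WavenumberAxis
from .containers import Hypercube, ReferenceSet


@dataclass(frozen=True)
class KKSettings:
    """Numerical knobs of the time-domain Kramers-Kronig retrieval.

    pad_factor : total FFT length as a multiple of the spectrum length.
    smoother_window : channels in the error-phase smoother; None = s//2
        (forced odd, >= 5).  Long windows only remove truly slow phase
        drifts; short windows start following resonances and carve
        negative lobes around strong peaks.
    smoother_polyorder : polynomial order of the Savitzky-Golay smoother.
    clip_negative : clip retrieved values below zero (presentation only;
        statistics stay unbiased with the default False).
    nrb_floor_rel : nonpositive NRB channels are floored to this fraction
        of the NRB maximum.
    """

    pad_factor: int = 4
    smoother_window: int | None = None
    smoother_polyorder: int = 2
    clip_negative: bool = False
    nrb_floor_rel: float = 1e-6

    def __post_init__(self):
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")


@dataclass
class RetrievedSpectrum:
    """Raman-like spectrum and retrieved phase on a wavenumber axis."""

    axis: WavenumberAxis
    raman_like: np.ndarray
    phase: np.ndarray


def hilbert_phase(half_log_ratio: np.ndarray, pad_factor: int = 4) -> np.ndarray:
    """Hilbert-transform conjugate of 1/2 ln R, computed in the time domain.

    The input is continued smoothly back to its first sample over the pad
    region (raised-cosine bridge) so the periodic FFT sees no jump, then
    the discrete Hilbert transform is taken and the pad discarded.
    Accepts (..., s) arrays.
    """
    x = np.asarray(half_log_ratio, dtype=float)
    s = x.shape[-1]
    npad = s * (pad_factor - 1)
    if npad > 0:
        t = np.arange(1, npad + 1) / (npad + 1)
        ramp = 0.5 - 0.5 * np.cos(np.pi * t)  # (npad,)
        bridge = x[..., -1:] + (x[..., :1] - x[..., -1:]) * ramp
        ext = np.concatenate([x, bridge], axis=-1)
    else:
        ext = x
    phi = np.imag(hilbert(ext, axis=-1))
    return phi[..., :s]


def _error_phase(phi: np.ndarray, settings: KKSettings) -> np.ndarray:
    """Slowly varying phase background, estimated peak-robustly.

    A first Savitzky-Golay pass gives a draft background; channels whose
    residual exceeds 3 robust standard deviations (the resonances) are
    replaced by the draft and the smoother is re-run, so sharp spectral
    features do not leak into the background estimate and get subtracted
    from themselves.
    """
    s = phi.shape[-1]
    w = settings.smoother_window if settings.smoother_window is not None else s // 2
    w = max(5, int(w) | 1)  # odd, at least 5
    if w >= s:
        w = (s - 1) | 1 if (s - 1) % 2 else s - 1
    order = min(settings.smoother_polyorder, w - 1)
    base = savgol_filter(phi, w, order, axis=-1)
    for _ in range(2):
        resid = phi - base
        med = np.median(resid, axis=-1, keepdims=True)
        mad = np.median(np.abs(resid - med), axis=-1, keepdims=True)
        cut = 3.0 * 1.4826 * np.maximum(mad, 1e-12)
        filled = np.where(np.abs(resid - med) > cut, base, phi)
        base = savgol_filter(filled, w, order, axis=-1)
    return base


def _retrieve_array(cars: np.ndarray, nrb: np.ndarray, settings: KKSettings):
    """Core retrieval on (..., s) CARS data against a (s,) NRB reference."""
    cars = np.asarray(cars, dtype=float)
    nrb = np.asarray(nrb, dtype=float)
    if cars.shape[-1] != nrb.shape[-1]:
        raise ValueError("CARS and NRB reference lengths differ")
    if not np.all(np.isfinite(cars)) or not np.all(np.isfinite(nrb)):
        raise ValueError("non-finite values in retrieval input")
    floor = settings.nrb_floor_rel * float(nrb.max())
    if floor <= 0:
        raise ValueError("NRB reference has no positive signal")
    nrb = np.maximum(nrb, floor)
    ratio = np.maximum(cars, floor * settings.nrb_floor_rel) / nrb
    half_log = 0.5 * np.log(ratio)
    phi = hilbert_phase(half_log, settings.pad_factor)
    phi_res = phi - _error_phase(phi, settings)
    raman = np.sqrt(ratio) * np.sin(phi_res)
    if settings.clip_negative:
        raman = np.clip(raman, 0.0, None)
    return raman, phi


def kk_retrieve(
    cars: np.ndarray,
    nrb_ref: np.ndarray,
    settings: KKSettings | None = None,
    axis: WavenumberAxis | None = None,
) -> RetrievedSpectrum:
    """Retrieve a Raman-like spectrum from one CARS spectrum.

    `nrb_ref` is the resonance-free reference spectrum (e.g. averaged
    quartz, dark-subtracted).  Returns the imaginary part of
    sqrt(R) exp(i (phi - phi_err)) together with the raw retrieved phase.
    """
    settings = settings or KKSettings()
    raman, phi = _retrieve_array(cars, nrb_ref, settings)
    if axis is None:
        axis = WavenumberAxis(np.arange(raman.shape[-1], dtype=float))
    return RetrievedSpectrum(axis=axis, raman_like=raman, phase=phi)


def kk_retrieve_cube(
    cube: Hypercube,
    nrb_ref: np.ndarray,
    settings: KKSettings | None = None,
) -> Hypercube:
    """Per-pixel Kramers-Kronig retrieval of a whole hypercube (vectorized)."""
    settings = settings or KKSettings()
    m, n, s = cube.data.shape
    raman, _ = _retrieve_array(cube.data.reshape(m * n, s), nrb_ref, settings)
    out = cube.with_data(raman.reshape(m, n, s))
    out.meta["kk_pad_factor"] = settings.pad_factor
    return out


class KramersKronigRetriever(BaseEstimator, TransformerMixin):
    """Transformer wrapper: fit on the NRB reference, transform CARS data.

    ``fit`` accepts a :class:`ReferenceSet` (uses dark-subtracted
    ``nrb_mean``) or a plain NRB spectrum; ``transform`` accepts a
    :class:`Hypercube`, a single spectrum or an (n_spectra, s) array.
    """

    def __init__(self, pad_factor: int = 4, smoother_window: int | None = None,
                 smoother_polyorder: int = 2, clip_negative: bool = False):
        self.pad_factor = pad_factor
        self.smoother_window = smoother_window
        self.smoother_polyorder = smoother_polyorder
        self.clip_negative = clip_negative

    def _settings(self) -> KKSettings:
        return KKSettings(
            pad_factor=self.pad_factor,
            smoother_window=self.smoother_window,
            smoother_polyorder=self.smoother_polyorder,
            clip_negative=self.clip_negative,
        )

    def fit(self, X, y=None):
        if isinstance(X, ReferenceSet):
            self.nrb_ = X.nrb_mean - X.dark_mean
        else:
            self.nrb_ = np.asarray(X, dtype=float)
        if self.nrb_.ndim != 1:
            raise ValueError("NRB reference must be a single spectrum")
        return self

    def transform(self, X):
        check_is_fitted(self, "nrb_")
        settings = self._settings()
        if isinstance(X, Hypercube):
            return kk_retrieve_cube(X, self.nrb_, settings)
        raman, _ = _retrieve_array(np.asarray(X, dtype=float), self.nrb_, settings)
        return raman
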