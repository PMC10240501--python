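"""Wavenumber-axis calibration and dark subtraction.

The spectrometer records channel indices; a known-line analyte (toluene)
maps them to Raman shifts.  Peaks are detected in the averaged analyte
spectrum, refined to sub-channel accuracy with a 3-point parabolic
centroid, matched in order to a sorted reference line list, and a
low-degree polynomial channel -> cm^-1 is least-squares fitted.  The fit
is rejected unless it is strictly monotonic over the detector range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .axes import WavenumberAxis
from .containers import Hypercube


class CalibrationError(RuntimeError):
    pass


def subtract_dark(cube_or_spectrum, dark_mean: np.ndarray):
    """Channel-wise dark subtraction; output may go negative (no clipping).

    Accepts a :class:`Hypercube`, a spectrum, or any (..., s) array.
    """
    dark = np.asarray(dark_mean, dtype=float)
    if isinstance(cube_or_spectrum, Hypercube):
        if cube_or_spectrum.data.shape[-1] != dark.shape[-1]:
            raise ValueError("dark spectrum length does not match the cube")
        return cube_or_spectrum.with_data(cube_or_spectrum.data - dark)
    arr = np.asarray(cube_or_spectrum, dtype=float)
    if arr.shape[-1] != dark.shape[-1]:
        raise ValueError("dark spectrum length does not match the data")
    return arr - dark


def _parabolic_centroid(y: np.ndarray, i: int) -> float:
    """Sub-channel peak position from a 3-point parabola through i-1, i, i+1."""
    if i <= 0 or i >= y.size - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0:
        return float(i)
    return float(i + 0.5 * (y[i - 1] - y[i + 1]) / denom)


def detect_peak_channels(
    spectrum: np.ndarray, n_peaks: int, prominence_rel: float = 0.02
) -> np.ndarray:
    """Sub-channel positions of the `n_peaks` most prominent local maxima,
    sorted by channel."""
    y = np.asarray(spectrum, dtype=float)
    span = float(y.max() - y.min())
    if span <= 0:
        raise CalibrationError("flat spectrum: no peaks to detect")
    idx, props = find_peaks(y, prominence=prominence_rel * span)
    if idx.size < n_peaks:
        raise CalibrationError(
            f"calibration failure: found {idx.size} peaks, need {n_peaks}"
        )
    order = np.argsort(props["prominences"])[::-1][:n_peaks]
    chosen = np.sort(idx[order])
    return np.array([_parabolic_centroid(y, int(i)) for i in chosen])


@dataclass
class CalibrationModel:
    """Polynomial channel-index -> wavenumber mapping with fit diagnostics."""

    coefficients: np.ndarray  # ascending powers
    degree: int
    residual_rms: float
    line_pairs: list  # (sub-channel position, reference cm^-1)
    channel_count: int

    def __call__(self, channels) -> np.ndarray:
        return np.polynomial.polynomial.polyval(
            np.asarray(channels, dtype=float), self.coefficients
        )

    def axis(self) -> WavenumberAxis:
        return WavenumberAxis(self(np.arange(self.channel_count)))


class WavenumberCalibrator(BaseEstimator, RegressorMixin):
    """Fit the channel -> cm^-1 mapping from an analyte spectrum.

    Feed it the Kramers-Kronig-retrieved analyte spectrum where possible:
    raw CARS line maxima are shifted by interference with the nonresonant
    background and by the excitation envelope, while retrieved peaks sit at
    the true Raman shifts.

    Parameters
    ----------
    reference_lines : sequence of float
        Known Raman shifts (cm^-1) of the analyte's detectable lines,
        matched to detected peaks in sorted order.
    degree : int
        Polynomial degree (1-3; default 2, standard spectrograph practice).
    prominence_rel : float
        Peak-detection prominence as a fraction of the spectrum's range.

    Attributes
    ----------
    model_ : CalibrationModel
    axis_ : WavenumberAxis for the full detector.
    """

    def __init__(self, reference_lines=(), degree: int = 2,
                 prominence_rel: float = 0.02):
        self.reference_lines = reference_lines
        self.degree = degree
        self.prominence_rel = prominence_rel

    def fit(self, X, y=None):
        """`X` is the averaged (dark-subtracted) analyte spectrum."""
        lines = np.sort(np.asarray(self.reference_lines, dtype=float))
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")
        if lines.size < self.degree + 1:
            raise ValueError(
                f"need at least {self.degree + 1} reference lines for degree "
                f"{self.degree}"
            )
        spectrum = np.asarray(X, dtype=float)
        channels = detect_peak_channels(spectrum, lines.size, self.prominence_rel)
        coeffs = np.polynomial.polynomial.polyfit(channels, lines, self.degree)
        fitted = np.polynomial.polynomial.polyval(channels, coeffs)
        rms = float(np.sqrt(np.mean((fitted - lines) ** 2)))
        full = np.polynomial.polynomial.polyval(
            np.arange(spectrum.size, dtype=float), coeffs
        )
        if np.any(np.diff(full) <= 0):
            raise CalibrationError(
                "fitted mapping is not monotonic over the detector range"
            )
        self.model_ = CalibrationModel(
            coefficients=coeffs,
            degree=self.degree,
            residual_rms=rms,
            line_pairs=list(zip(channels.tolist(), lines.tolist())),
            channel_count=spectrum.size,
        )
        self.axis_ = WavenumberAxis(full)
        return self

    def predict(self, channels) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_(channels)


def fit_wavenumber_axis(
    analyte_mean: np.ndarray, reference_lines, degree: int = 2,
    prominence_rel: float = 0.02,
) -> CalibrationModel:
    """Functional wrapper around :class:`WavenumberCalibrator`."""
    cal = WavenumberCalibrator(
        reference_lines=reference_lines, degree=degree,
        prominence_rel=prominence_rel,
    )
    return cal.fit(analyte_mean).model_
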