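"""Pump and Stokes excitation fields sampled in the spectral domain.

A :class:`SpectralField` holds a complex field amplitude E(omega) on a
uniform grid of absolute optical frequency expressed in wavenumbers
(cm^-1).  Two factories cover the two beams of a broadband CARS
instrument:

* :func:`make_pump_field` — a narrowband pump with a Lorentzian modulus
  spectrum (etalon-filtered), e.g. 1035 nm with <9 cm^-1 intensity FWHM.
  The pump linewidth sets the spectral resolution of the instrument.
* :func:`make_stokes_field` — a broadband Stokes continuum, e.g.
  1200-1600 nm, flat-top with raised-cosine edges, optionally chirped
  (quadratic spectral phase) and optionally hard-masked on its
  short-wavelength side by the prism-compressor mask.

Spectral phase conventions: the time-domain envelope is the inverse
Fourier transform of E(omega); a quadratic phase 0.5*GDD*(w-w0)^2 (GDD in
fs^2, w in rad/fs) stretches the pulse, a linear phase exp(i*w*tau) delays
it by tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .axes import C_CM_PER_FS, nm_to_wavenumber

#: rad/fs per cm^-1 — angular frequency of a 1 cm^-1 wavenumber
OMEGA_RAD_FS_PER_CM1 = 2.0 * np.pi * C_CM_PER_FS


@dataclass(frozen=True)
class SpectralField:
    """Complex spectral amplitude of a pulse on a uniform wavenumber grid.

    Parameters
    ----------
    frequency_cm1 : ndarray
        Strictly increasing, uniformly spaced absolute optical frequency
        samples in cm^-1.
    amplitude : ndarray
        Complex field amplitude per sample; zero outside the pulse support.
    center_wavelength_nm : float
        Nominal center wavelength, bookkeeping only.
    group_delay_dispersion_fs2 : float
        GDD imprinted on the field (already applied to `amplitude`).
    delay_fs : float
        Arrival-time offset imprinted as a linear spectral phase.
    """

    frequency_cm1: np.ndarray
    amplitude: np.ndarray
    center_wavelength_nm: float
    group_delay_dispersion_fs2: float = 0.0
    delay_fs: float = 0.0

    def __post_init__(self):
        f = np.asarray(self.frequency_cm1, dtype=float)
        a = np.asarray(self.amplitude, dtype=complex)
        if f.ndim != 1 or f.size < 4 or a.shape != f.shape:
            raise ValueError("frequency grid and amplitude must be matching 1-d arrays")
        d = np.diff(f)
        if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-8):
            raise ValueError("frequency grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(a)):
            raise ValueError("amplitude must be finite")
        if not np.sum(np.abs(a) ** 2) > 0:
            raise ValueError("field energy must be positive")
        object.__setattr__(self, "frequency_cm1", f)
        object.__setattr__(self, "amplitude", a)

    @property
    def step_cm1(self) -> float:
        return float(self.frequency_cm1[1] - self.frequency_cm1[0])

    @property
    def energy(self) -> float:
        """Integral of |E|^2 over the grid (arbitrary units x cm^-1)."""
        return float(np.sum(np.abs(self.amplitude) ** 2) * self.step_cm1)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2

    def center_cm1(self) -> float:
        """Intensity-weighted mean optical frequency in cm^-1."""
        w = self.intensity
        return float(np.sum(self.frequency_cm1 * w) / np.sum(w))

    def delayed(self, delay_fs: float) -> "SpectralField":
        """Field delayed by `delay_fs` via a linear spectral phase."""
        if delay_fs == 0.0:
            return self
        phase = np.exp(1j * OMEGA_RAD_FS_PER_CM1 * self.frequency_cm1 * delay_fs)
        return replace(
            self,
            amplitude=self.amplitude * phase,
            delay_fs=self.delay_fs + delay_fs,
        )

    def time_envelope(self, pad_factor: int = 8):
        """Time-domain intensity envelope |e(t)|^2 by zero-padded inverse FFT.

        Returns (t_fs, intensity); t_fs spans the FFT window centered on 0.
        """
        n = int(self.frequency_cm1.size * pad_factor)
        spec = np.zeros(n, dtype=complex)
        spec[: self.amplitude.size] = self.amplitude
        env = np.fft.ifft(spec)
        env = np.fft.fftshift(env)
        dt = 1.0 / (n * self.step_cm1 * C_CM_PER_FS)  # fs per sample
        t = (np.arange(n) - n // 2) * dt
        return t, np.abs(env) ** 2

    def time_fwhm_fs(self, pad_factor: int = 16) -> float:
        """Intensity FWHM of the time-domain envelope, in fs."""
        t, inten = self.time_envelope(pad_factor)
        return _fwhm(t, inten)


def _fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """FWHM of a single-peaked curve by linear interpolation at half max."""
    y = np.asarray(y, dtype=float)
    i = int(np.argmax(y))
    half = y[i] / 2.0
    # walk left
    lo = i
    while lo > 0 and y[lo] > half:
        lo -= 1
    hi = i
    while hi < y.size - 1 and y[hi] > half:
        hi += 1
    if y[lo] > half or y[hi] > half:
        raise ValueError("curve does not fall below half maximum inside the grid")

    def cross(a, b):
        if y[b] == y[a]:
            return x[a]
        return x[a] + (half - y[a]) * (x[b] - x[a]) / (y[b] - y[a])

    return float(cross(hi - 1, hi) - cross(lo + 1, lo))


def make_pump_field(
    center_nm: float,
    fwhm_cm1: float,
    grid: np.ndarray | None = None,
    step_cm1: float = 0.5,
) -> SpectralField:
    """Narrowband pump with a Lorentzian modulus-squared spectrum.

    Parameters
    ----------
    center_nm : float
        Center wavelength in nm (1035 nm for a Yb-laser system).
    fwhm_cm1 : float
        Intensity (|E|^2) full width at half maximum in cm^-1.  An etalon
        filter narrows the pump to <9 cm^-1, which then defines the
        spectral resolution of the rendered CARS spectra.
    grid : ndarray, optional
        Uniform optical-frequency grid (cm^-1).  Must cover the line center
        by at least +-20 FWHM.  Default: a grid of `step_cm1` spacing
        spanning +-40 FWHM.
    """
    if fwhm_cm1 <= 0:
        raise ValueError("pump FWHM must be positive")
    nu0 = nm_to_wavenumber(center_nm)
    if grid is None:
        half = 40.0 * fwhm_cm1
        n = int(round(2 * half / step_cm1)) + 1
        grid = nu0 - half + step_cm1 * np.arange(n)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid[0] > nu0 - 20 * fwhm_cm1 or grid[-1] < nu0 + 20 * fwhm_cm1:
            raise ValueError(
                "pump grid must cover the line center by at least 20 FWHM"
            )
    # Lorentzian MODULUS (etalon transmission); its square must have the
    # stated intensity FWHM: |E|^2 half-max falls where |E| = 2^-1/2, i.e.
    # at sqrt(sqrt(2)-1) modulus half-widths.
    gamma_a = fwhm_cm1 / (2.0 * np.sqrt(np.sqrt(2.0) - 1.0))
    amplitude = (1.0 / (1.0 + ((grid - nu0) / gamma_a) ** 2)).astype(complex)
    return SpectralField(
        frequency_cm1=grid, amplitude=amplitude, center_wavelength_nm=center_nm
    )


def make_stokes_field(
    support_nm: tuple[float, float],
    shape: str = "flat",
    gdd_fs2: float = 0.0,
    mask_edge_nm: float | None = None,
    edge_width_cm1: float = 60.0,
    step_cm1: float = 0.5,
) -> SpectralField:
    """Broadband Stokes continuum on `support_nm = (min_nm, max_nm)`.

    The modulus is a flat-top with raised-cosine edges of width
    `edge_width_cm1` ("flat"), or a Gaussian filling the support
    ("gaussian").  `mask_edge_nm` emulates the hard mask in the prism
    compressor that cuts the short-wavelength side: amplitude is zeroed
    for wavelengths below it.  `gdd_fs2` applies a quadratic spectral
    phase about the band center; 0 means transform-limited.
    """
    lo_nm, hi_nm = support_nm
    if not 0 < lo_nm < hi_nm:
        raise ValueError("support must satisfy 0 < min_nm < max_nm")
    if mask_edge_nm is not None and not (lo_nm <= mask_edge_nm < hi_nm):
        raise ValueError("mask edge must lie inside the support")
    nu_lo = nm_to_wavenumber(hi_nm)  # long wavelength -> low frequency
    nu_hi = nm_to_wavenumber(lo_nm)
    pad = 4.0 * edge_width_cm1
    n = int(round((nu_hi - nu_lo + 2 * pad) / step_cm1)) + 1
    grid = (nu_lo - pad) + step_cm1 * np.arange(n)

    if shape == "flat":
        modulus = _raised_cosine_top(grid, nu_lo, nu_hi, edge_width_cm1)
    elif shape == "gaussian":
        nu_c = 0.5 * (nu_lo + nu_hi)
        sigma = (nu_hi - nu_lo) / 4.0
        modulus = np.exp(-0.5 * ((grid - nu_c) / sigma) ** 2)
    else:
        raise ValueError(f"unknown spectral shape {shape!r}")

    if mask_edge_nm is not None:
        modulus = modulus.copy()
        modulus[grid > nm_to_wavenumber(mask_edge_nm)] = 0.0
    if not np.any(modulus > 0):
        raise ValueError("mask removed the entire Stokes support")

    nu_c = float(np.sum(grid * modulus**2) / np.sum(modulus**2))
    w = OMEGA_RAD_FS_PER_CM1 * (grid - nu_c)  # rad/fs detuning
    phase = 0.5 * gdd_fs2 * w**2
    amplitude = modulus * np.exp(1j * phase)
    center_nm = float(1e7 / nu_c)
    return SpectralField(
        frequency_cm1=grid,
        amplitude=amplitude,
        center_wavelength_nm=center_nm,
        group_delay_dispersion_fs2=gdd_fs2,
    )


def _raised_cosine_top(grid, nu_lo, nu_hi, edge):
    """Flat-top window = 1 on [nu_lo+edge, nu_hi-edge], cosine edges, 0 outside."""
    if nu_hi - nu_lo <= 2 * edge:
        raise ValueError("support narrower than twice the edge width")
    m = np.zeros_like(grid)
    core = (grid >= nu_lo + edge) & (grid <= nu_hi - edge)
    m[core] = 1.0
    left = (grid >= nu_lo) & (grid < nu_lo + edge)
    m[left] = 0.5 * (1 - np.cos(np.pi * (grid[left] - nu_lo) / edge))
    right = (grid > nu_hi - edge) & (grid <= nu_hi)
    m[right] = 0.5 * (1 - np.cos(np.pi * (nu_hi - grid[right]) / edge))
    return m
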