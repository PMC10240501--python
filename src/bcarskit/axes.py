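"""Wavenumber axes and unit conversions.

All spectral quantities in this package live on axes of Raman shift or
absolute optical frequency expressed in wavenumbers (cm^-1).  Laser
wavelengths are quoted in nm; the conversion is nu[cm^-1] = 1e7 / lambda[nm].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: speed of light in cm/fs — converts wavenumbers to inverse femtoseconds
C_CM_PER_FS = 2.99792458e-5


def nm_to_wavenumber(wavelength_nm):
    """Convert vacuum wavelength (nm) to wavenumber (cm^-1)."""
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl <= 0):
        raise ValueError("wavelength must be positive")
    return 1e7 / wl


def wavenumber_to_nm(wavenumber_cm1):
    """Convert wavenumber (cm^-1) to vacuum wavelength (nm)."""
    nu = np.asarray(wavenumber_cm1, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("wavenumber must be positive")
    return 1e7 / nu


def oscillation_period_fs(wavenumber_cm1: float) -> float:
    """Vibrational oscillation period T = 1/(c * nu) in femtoseconds.

    A mode at 1380 cm^-1 oscillates with a ~24 fs period; impulsive
    (three-color) excitation of that mode requires a pulse shorter than T.
    """
    if wavenumber_cm1 <= 0:
        raise ValueError("wavenumber must be positive")
    return 1.0 / (C_CM_PER_FS * wavenumber_cm1)


@dataclass(frozen=True)
class WavenumberAxis:
    """A strictly increasing Raman-shift axis in cm^-1.

    Parameters
    ----------
    values : ndarray
        Raman shifts, strictly increasing, finite, at least 16 samples.
    """

    values: np.ndarray = field()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 16:
            raise ValueError("axis needs at least 16 one-dimensional samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("axis values must be finite")
        if np.any(np.diff(v) <= 0):
            raise ValueError("axis must be strictly increasing")
        object.__setattr__(self, "values", v)

    @property
    def channel_count(self) -> int:
        return int(self.values.size)

    @property
    def step(self) -> float:
        """Mean channel spacing in cm^-1."""
        return float(np.mean(np.diff(self.values)))

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.values)
        return bool(np.allclose(d, d[0], rtol=1e-9, atol=1e-9))

    @classmethod
    def linspace(cls, lo: float, hi: float, n: int = 1340) -> "WavenumberAxis":
        """Uniform axis from `lo` to `hi` cm^-1 with `n` channels.

        The default channel count matches a 1340-pixel CCD spectrometer row.
        """
        return cls(np.linspace(lo, hi, n))

    @classmethod
    def from_step(cls, lo: float, hi: float, step: float) -> "WavenumberAxis":
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))

    def select(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of channels with lo <= value <= hi."""
        return (self.values >= lo) & (self.values <= hi)

    def index_of(self, value: float) -> int:
        """Channel index closest to `value`."""
        return int(np.argmin(np.abs(self.values - value)))

    def __len__(self) -> int:
        return self.channel_count
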