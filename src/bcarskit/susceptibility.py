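"""Third-order susceptibility model: Lorentzian Raman modes + constant NRB.

The sample response entering the CARS signal is chi3 = chi_R + chi_NR.  The
resonant part is a sum of complex Lorentzians, one per vibrational mode,

    chi_R(Omega) = sum_j A_j / (Omega_j - Omega - i Gamma_j)

with mode position Omega_j, amplitude A_j and half-width Gamma_j, all in
cm^-1 except the dimensionless amplitude.  The nonresonant part chi_NR is a
real constant: electronic four-wave mixing with no spectral structure.  On
resonance an isolated mode contributes Im chi = A_j / Gamma_j with a full
width at half maximum of 2 Gamma_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axes import WavenumberAxis


@dataclass(frozen=True)
class LorentzianMode:
    """A single Raman mode: position (cm^-1), amplitude, half-width (cm^-1)."""

    position: float
    amplitude: float
    gamma: float

    def __post_init__(self):
        if self.position <= 0:
            raise ValueError("mode position must be positive")
        if self.gamma <= 0:
            raise ValueError("mode half-width must be positive")
        if self.amplitude < 0:
            raise ValueError("mode amplitude must be nonnegative")

    @property
    def peak_height(self) -> float:
        """On-resonance Im chi of the isolated mode, A/Gamma."""
        return self.amplitude / self.gamma

    @property
    def dephasing_time_fs(self) -> float:
        """Coherence decay time 1/(2 pi c Gamma) in fs."""
        from .axes import C_CM_PER_FS

        return 1.0 / (2.0 * np.pi * C_CM_PER_FS * self.gamma)


@dataclass(frozen=True)
class Susceptibility:
    """chi3 of a medium: a list of Lorentzian modes plus a real NRB constant."""

    modes: tuple = field(default=())
    chi_nr: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "modes", tuple(self.modes))
        if self.chi_nr < 0:
            raise ValueError("nonresonant susceptibility must be nonnegative")

    def resonant(self, shifts) -> np.ndarray:
        """Complex chi_R evaluated on an array of Raman shifts (cm^-1)."""
        omega = np.asarray(
            shifts.values if isinstance(shifts, WavenumberAxis) else shifts,
            dtype=float,
        )
        chi = np.zeros(omega.shape, dtype=complex)
        for m in self.modes:
            chi += m.amplitude / (m.position - omega - 1j * m.gamma)
        return chi

    def __call__(self, shifts) -> np.ndarray:
        """Complex chi_R + chi_NR on an array of Raman shifts (cm^-1)."""
        return self.resonant(shifts) + self.chi_nr

    def scaled(self, factor: float) -> "Susceptibility":
        """Susceptibility with all amplitudes and chi_NR multiplied by factor."""
        return Susceptibility(
            modes=tuple(
                LorentzianMode(m.position, m.amplitude * factor, m.gamma)
                for m in self.modes
            ),
            chi_nr=self.chi_nr * factor,
        )

    def __add__(self, other: "Susceptibility") -> "Susceptibility":
        return Susceptibility(
            modes=self.modes + other.modes, chi_nr=self.chi_nr + other.chi_nr
        )


def evaluate_susceptibility(chi: Susceptibility, axis: WavenumberAxis) -> np.ndarray:
    """Evaluate chi_R + chi_NR per channel of `axis`.

    Returns a complex spectrum; its imaginary part is the Raman-like
    (spontaneous-Raman-comparable) lineshape of the medium.
    """
    return chi(axis.values)
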