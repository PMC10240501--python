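"""Forward model: synthesize CARS spectra and noisy hypercubes.

The rendered signal follows the standard heterodyne CARS picture: the
excitation cross-correlation drives the vibrational coherence, the
sample susceptibility chi_R + chi_NR filters it, and readout by the
narrowband pump convolves the product with the pump lineshape before
square-law detection:

    I(w_aS) ~ | [ X(Omega) * (chi_R(Omega) + chi_NR) ] conv E_p |^2

with X the two-color (pump-Stokes) and/or three-color (Stokes-Stokes)
excitation amplitude of :mod:`bcarskit.excitation`.  Because chi_NR sits
inside the modulus, resonances appear as dispersive (shifted, asymmetric)
lineshapes on top of the nonresonant background — the distortion that the
Kramers-Kronig retrieval later removes.

Pump-Stokes delay enters as a linear spectral phase on the pump.  A
delayed pump no longer overlaps the Stokes pulse, so the nonresonant and
two-color contributions die on the pulse-overlap timescale, while
three-color resonant coherences — already rung up by the Stokes alone —
decay with each mode's dephasing time 1/(2 pi c Gamma_j).  This is the
optical NRB suppression of time-delayed CARS.

Detector noise is Poisson-Gaussian: counts = gain * Poisson(I/gain)
+ Normal(0, sigma) + dark, so the shot-noise variance is gain * I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axes import WavenumberAxis, nm_to_wavenumber
from .containers import Hypercube, ReferenceSet
from .excitation import complex_cross_correlation
from .fields import SpectralField
from .susceptibility import Susceptibility


# ---------------------------------------------------------------------------
# clean-signal synthesis


def _pump_kernel(pump: SpectralField):
    """Pump modulus vs detuning from its center, unit-sum; sets the resolution."""
    nu0 = nm_to_wavenumber(pump.center_wavelength_nm)
    detuning = pump.frequency_cm1 - nu0
    k = np.abs(pump.amplitude)
    return detuning, k / np.sum(k)


def _pulse_overlap(pump: SpectralField, stokes: SpectralField, delay_fs: float) -> float:
    """Normalized temporal overlap of the pump and Stokes amplitude envelopes.

    Computed on a shared FFT time grid (both fields share the frequency
    step, hence the time window).  Equals 1 at zero delay by construction.
    """
    n = 1 << int(np.ceil(np.log2(8 * max(pump.amplitude.size, stokes.amplitude.size))))

    def envelope(f: SpectralField):
        spec = np.zeros(n, dtype=complex)
        spec[: f.amplitude.size] = f.amplitude
        return np.abs(np.fft.ifft(spec))

    ep0 = envelope(pump)
    ep = envelope(pump.delayed(delay_fs)) if delay_fs else ep0
    es = envelope(stokes)
    denom = float(np.sum(ep0 * es))
    if denom <= 0:
        return 0.0
    return float(np.sum(ep * es) / denom)


def cars_amplitude(
    chi: Susceptibility,
    pump: SpectralField,
    stokes: SpectralField,
    axis: WavenumberAxis,
    delay_fs: float = 0.0,
    two_color: bool = True,
    three_color: bool = True,
    mechanism_balance: float = 1.0,
) -> np.ndarray:
    """Complex anti-Stokes field amplitude on `axis` before detection.

    The detected intensity is ``|cars_amplitude(...)|**2``; the amplitude is
    linear in the susceptibility, so mixtures can be rendered by summing the
    amplitudes of their components weighted by abundance.

    Each mechanism's excitation amplitude is normalized to unit maximum at
    zero delay (overall prefactors — beam powers, focusing, collection —
    are arbitrary units anyway), and `mechanism_balance` scales the
    three-color term relative to the two-color one.  This emulates an
    instrument tuned so the two spectral regions have comparable signal.
    """
    if not np.isfinite(delay_fs):
        raise ValueError("delay must be finite")
    step = pump.step_cm1
    if not np.isclose(step, stokes.step_cm1, rtol=1e-6):
        raise ValueError("pump and Stokes must share the frequency-grid step")

    det, kernel = _pump_kernel(pump)
    pad = max(abs(det[0]), abs(det[-1]))
    lo = max(axis.values[0] - pad, step)
    hi = axis.values[-1] + pad
    n = int(np.ceil((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n)

    drive = np.zeros(n, dtype=complex)
    if two_color:
        lag2, x2 = complex_cross_correlation(pump.delayed(delay_fs), stokes)
        if delay_fs:
            lag0, x0 = complex_cross_correlation(pump, stokes)
            norm2 = np.max(np.abs(x0[lag0 > 0]))
        else:
            norm2 = np.max(np.abs(x2[lag2 > 0]))
        x2g = np.interp(grid, lag2, x2.real, left=0.0, right=0.0) + 1j * np.interp(
            grid, lag2, x2.imag, left=0.0, right=0.0
        )
        drive += (x2g / norm2) * (chi.resonant(grid) + chi.chi_nr)
    if three_color:
        lag3, x3 = complex_cross_correlation(stokes, stokes)
        norm3 = np.max(np.abs(x3[lag3 > 0]))
        x3g = np.interp(grid, lag3, x3.real, left=0.0, right=0.0) + 1j * np.interp(
            grid, lag3, x3.imag, left=0.0, right=0.0
        )
        x3g = mechanism_balance * x3g / norm3
        if delay_fs > 0:
            g = _pulse_overlap(pump, stokes, delay_fs)
            res = np.zeros(n, dtype=complex)
            for m in chi.modes:
                decay = np.exp(-delay_fs / m.dephasing_time_fs)
                res += decay * m.amplitude / (m.position - grid - 1j * m.gamma)
            drive += x3g * (chi.chi_nr * g + res)
        else:
            g = _pulse_overlap(pump, stokes, delay_fs) if delay_fs else 1.0
            drive += x3g * g * (chi.resonant(grid) + chi.chi_nr)

    amp = np.convolve(drive, kernel.astype(complex), mode="same")
    return np.interp(axis.values, grid, amp.real) + 1j * np.interp(
        axis.values, grid, amp.imag
    )


def cars_spectrum(
    chi: Susceptibility,
    pump: SpectralField,
    stokes: SpectralField,
    axis: WavenumberAxis,
    delay_fs: float = 0.0,
    two_color: bool = True,
    three_color: bool = True,
) -> np.ndarray:
    """Detected CARS intensity (arbitrary units, >= 0) on `axis`."""
    amp = cars_amplitude(
        chi, pump, stokes, axis, delay_fs=delay_fs, two_color=two_color,
        three_color=three_color,
    )
    return np.abs(amp) ** 2


# ---------------------------------------------------------------------------
# noise and scenes


@dataclass(frozen=True)
class NoiseModel:
    """Poisson-Gaussian detector noise.

    counts = poisson_gain * Poisson(clean / poisson_gain)
             + Normal(0, gaussian_sigma) + dark_level

    so Var(counts) = poisson_gain * clean + gaussian_sigma^2.  Setting
    ``poisson_gain = 0`` disables the shot-noise term (the deterministic
    limit); ``gaussian_sigma = 0`` disables the read-noise term.
    """

    poisson_gain: float = 1.0
    gaussian_sigma: float = 5.0
    dark_level: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.poisson_gain < 0 or self.gaussian_sigma < 0:
            raise ValueError("noise parameters must be nonnegative")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Noisy detector counts for nonnegative clean signal `clean`."""
        clean = np.asarray(clean, dtype=float)
        if np.any(clean < 0):
            raise ValueError("clean signal must be nonnegative")
        out = clean.astype(float).copy()
        if self.poisson_gain > 0:
            out = self.poisson_gain * rng.poisson(clean / self.poisson_gain)
        if self.gaussian_sigma > 0:
            out = out + rng.normal(0.0, self.gaussian_sigma, size=clean.shape)
        return out + self.dark_level

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SceneSpec:
    """Spatial layout of a synthetic field of view.

    `species` is a list of (Susceptibility, abundance image) pairs; each
    abundance image is an (m, n) array of nonnegative weights.  Scenes meant
    for endmember-recovery tests should contain at least one pure pixel
    (abundance 1 for that species, 0 for the others) per species.
    """

    shape: tuple
    species: list
    axis: WavenumberAxis

    def __post_init__(self):
        m, n = self.shape
        if not self.species:
            raise ValueError("scene needs at least one species")
        for chi, ab in self.species:
            ab = np.asarray(ab, dtype=float)
            if ab.shape != (m, n):
                raise ValueError("abundance image shape must match the scene")
            if np.any(ab < 0):
                raise ValueError("abundances must be nonnegative")
            if not isinstance(chi, Susceptibility):
                raise TypeError("species entries must be (Susceptibility, image)")
        self.species = [
            (chi, np.asarray(ab, dtype=float)) for chi, ab in self.species
        ]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def abundance_stack(self) -> np.ndarray:
        """(m, n, k) stack of the true abundance images."""
        return np.stack([ab for _, ab in self.species], axis=-1)


@dataclass
class GroundTruth:
    """Noise-free record accompanying a rendered hypercube."""

    clean: np.ndarray  # (m, n, s) counts before noise and dark
    endmember_spectra: np.ndarray  # (k, s) clean pure-species spectra
    abundances: np.ndarray  # (m, n, k)
    axis: WavenumberAxis


def render_hypercube(
    scene: SceneSpec,
    pump: SpectralField,
    stokes: SpectralField,
    noise: NoiseModel,
    exposure_ms: float = 1.0,
    peak_counts: float = 5000.0,
    delay_fs: float = 0.0,
    two_color: bool = True,
    three_color: bool = True,
) -> tuple[Hypercube, GroundTruth]:
    """Render a noisy BCARS hypercube plus its ground truth.

    Each pixel's clean intensity is |sum_k a_k * A_k|^2 where A_k is the
    complex anti-Stokes amplitude of pure species k — mixing happens at the
    amplitude level, as it does physically within one focal volume.  The
    cube is scaled so its brightest clean channel equals
    `peak_counts * exposure_ms`, then Poisson-Gaussian noise and the dark
    level are added.
    """
    if exposure_ms <= 0:
        raise ValueError("exposure must be positive")
    m, n = scene.shape
    axis = scene.axis
    amps = np.stack(
        [
            cars_amplitude(
                chi, pump, stokes, axis, delay_fs=delay_fs,
                two_color=two_color, three_color=three_color,
            )
            for chi, _ in scene.species
        ]
    )  # (k, s)
    ab = scene.abundance_stack().reshape(m * n, -1)  # (p, k)
    field_px = ab @ amps  # (p, s) complex
    clean = np.abs(field_px) ** 2
    scale = peak_counts * exposure_ms / clean.max() if clean.max() > 0 else 1.0
    clean = (clean * scale).reshape(m, n, -1)
    endmembers = np.abs(amps) ** 2 * scale

    rng = noise.rng()
    data = noise.apply(clean, rng)
    cube = Hypercube(
        data=data,
        axis=axis,
        meta={
            "exposure_ms": exposure_ms,
            "seed": noise.seed,
            "dark_level": noise.dark_level,
            "delay_fs": delay_fs,
        },
    )
    truth = GroundTruth(
        clean=clean,
        endmember_spectra=endmembers,
        abundances=scene.abundance_stack(),
        axis=axis,
    )
    return cube, truth


def make_reference_set(
    pump: SpectralField,
    stokes: SpectralField,
    analyte_chi: Susceptibility,
    nrb_chi: Susceptibility,
    noise: NoiseModel,
    axis: WavenumberAxis,
    n_spectra: int = 100,
    exposure_ms: float = 1.0,
    peak_counts: float = 5000.0,
    two_color: bool = True,
    three_color: bool = True,
) -> ReferenceSet:
    """Averaged analyte, NRB (quartz-like) and dark reference spectra.

    Emulates the calibration protocol of averaging ~100 spectra per set.
    The analyte and NRB spectra share one intensity scale so their ratio is
    meaningful for Kramers-Kronig normalization.  Dark spectra contain only
    the dark level and read noise.
    """
    if n_spectra < 1:
        raise ValueError("n_spectra must be >= 1")
    kw = dict(two_color=two_color, three_color=three_color)
    analyte_clean = cars_spectrum(analyte_chi, pump, stokes, axis, **kw)
    nrb_clean = cars_spectrum(nrb_chi, pump, stokes, axis, **kw)
    scale = peak_counts * exposure_ms / analyte_clean.max()
    analyte_clean = analyte_clean * scale
    nrb_clean = nrb_clean * scale

    rng = noise.rng()
    s = axis.channel_count

    def averaged(clean):
        acc = np.zeros(s)
        for _ in range(n_spectra):
            acc += noise.apply(clean, rng)
        return acc / n_spectra

    return ReferenceSet(
        axis=axis,
        analyte_mean=averaged(analyte_clean),
        nrb_mean=averaged(nrb_clean),
        dark_mean=averaged(np.zeros(s)),
        n_averaged=n_spectra,
    )
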