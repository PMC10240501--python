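"""Packaged susceptibility fixtures and demo scenes.

Mode lists are synthetic stand-ins built from standard Raman band
positions (toluene solvent lines; protein amide/phenylalanine bands;
lipid CH2/ester bands; nucleic-acid backbone bands) — they are fixtures
for testing the pipeline, not measurements.  Quartz is modeled as a
purely nonresonant medium, which is why a bare quartz coverslip serves
as the NRB reference.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .axes import WavenumberAxis
from .fields import SpectralField, make_pump_field, make_stokes_field
from .simulate import NoiseModel, SceneSpec
from .susceptibility import LorentzianMode, Susceptibility


def _chi(bands, chi_nr):
    """Susceptibility from (position, Im-peak height, half-width) triples."""
    return Susceptibility(
        modes=tuple(LorentzianMode(p, h * g, g) for p, h, g in bands),
        chi_nr=chi_nr,
    )


def toluene_susceptibility() -> Susceptibility:
    """Toluene-like solvent: sharp ring modes, a 1380 cm^-1 band, CH stretches.

    The highest fingerprint mode at ~1380 cm^-1 (oscillation period ~24 fs)
    marks the practical upper edge of impulsive three-color excitation for a
    sub-20 fs Stokes pulse.
    """
    return _chi(
        [
            (521, 0.6, 3.0),
            (786, 1.0, 4.0),
            (1004, 1.0, 3.0),
            (1031, 0.6, 4.0),
            (1211, 0.4, 4.0),
            (1380, 0.3, 6.0),
            (1605, 0.4, 4.0),
            (2921, 0.8, 10.0),
            (3057, 0.6, 10.0),
        ],
        chi_nr=0.5,
    )


def quartz_susceptibility(chi_nr: float = 1.0) -> Susceptibility:
    """Quartz coverslip: pure nonresonant response (no Raman structure)."""
    return Susceptibility(modes=(), chi_nr=chi_nr)


def protein_susceptibility() -> Susceptibility:
    """Protein-rich endmember: phenylalanine 1002, amide II/I, CH3 stretch."""
    return _chi(
        [
            (831, 0.2, 8.0),
            (1002, 0.5, 4.0),
            (1125, 0.2, 8.0),
            (1450, 0.4, 10.0),
            (1567, 0.3, 10.0),
            (1660, 1.0, 14.0),
            (2935, 0.9, 18.0),
        ],
        chi_nr=1.0,
    )


def lipid_susceptibility() -> Susceptibility:
    """Lipid-rich endmember: acyl-chain bands, triglyceride ester at 1750."""
    return _chi(
        [
            (1257, 0.25, 10.0),
            (1301, 0.4, 9.0),
            (1440, 0.7, 11.0),
            (1750, 0.5, 12.0),
            (2850, 1.0, 12.0),
            (2885, 0.6, 14.0),
        ],
        chi_nr=1.0,
    )


def nucleic_acid_susceptibility() -> Susceptibility:
    """Nucleic-acid endmember: backbone/base ring modes."""
    return _chi(
        [
            (785, 0.6, 8.0),
            (1095, 0.5, 10.0),
            (1340, 0.4, 10.0),
            (1485, 0.5, 9.0),
            (1575, 0.6, 9.0),
        ],
        chi_nr=1.0,
    )


# ---------------------------------------------------------------------------
# default instrument

#: Raman-shift coverage (cm^-1) of the impulsive three-color mechanism in the
#: reference instrument configuration: Stokes compression and the compressor
#: mask are tuned so intra-pulse excitation spans ~400-1400 cm^-1 and the
#: two-color mechanism takes over exactly where it vanishes.
THREE_COLOR_BAND = (400.0, 1400.0)


def highest_three_color_mode(chi: Susceptibility,
                             band: tuple[float, float] = THREE_COLOR_BAND) -> LorentzianMode:
    """Highest-wavenumber mode of `chi` inside the impulsive-excitation band.

    Its oscillation period bounds the Stokes pulse duration needed to drive
    it impulsively (~24 fs for the 1380 cm^-1 toluene band).
    """
    lo, hi = band
    inside = [m for m in chi.modes if lo <= m.position <= hi]
    if not inside:
        raise ValueError("no mode inside the impulsive-excitation band")
    return max(inside, key=lambda m: m.position)


def default_pump() -> SpectralField:
    """1035 nm pump, 9 cm^-1 intensity FWHM (etalon-narrowed)."""
    return make_pump_field(1035.0, 9.0)


def default_stokes(
    support_nm: tuple[float, float] = (1100.0, 1600.0),
    gdd_fs2: float = 0.0,
    mask_edge_nm: float | None = None,
) -> SpectralField:
    """Broadband Stokes continuum; default 1100-1600 nm, transform-limited.

    With `mask_edge_nm=1200` the short-wavelength side is cut to the masked
    1200-1600 nm configuration whose two-color coverage starts where the
    three-color mechanism dies out.
    """
    return make_stokes_field(support_nm, gdd_fs2=gdd_fs2, mask_edge_nm=mask_edge_nm)


def default_axis(lo: float = 900.0, hi: float = 3100.0, step: float = 2.0) -> WavenumberAxis:
    return WavenumberAxis.from_step(lo, hi, step)


# ---------------------------------------------------------------------------
# abundance-map helpers


def _smooth_field(rng: np.random.Generator, shape, sigma=4.0) -> np.ndarray:
    """Seeded smooth random field scaled to [0, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return f


def _plant_pure_pixels(maps: list[np.ndarray], rng: np.random.Generator):
    """Force one pure pixel per species (abundance 1, all others 0)."""
    m, n = maps[0].shape
    taken = set()
    for k, _ in enumerate(maps):
        while True:
            i, j = int(rng.integers(m)), int(rng.integers(n))
            if (i, j) not in taken:
                taken.add((i, j))
                break
        for kk, amap in enumerate(maps):
            amap[i, j] = 1.0 if kk == k else 0.0


def demo_scene(
    name: str,
    shape: tuple[int, int] = (50, 50),
    seed: int = 42,
    axis: WavenumberAxis | None = None,
):
    """Packaged demonstration scenes.

    * ``"cells"`` — one scene with lipid, protein and nucleic-acid species
      (plus quartz substrate filling the rest), >= 1 pure pixel each.
    * ``"nash_vs_control"`` — a (control, diseased) scene pair of protein
      and lipid species on quartz; identical layouts except the
      triglyceride-bearing lipid species' mean abundance is raised 1.5x in
      the diseased scene.
    * ``"tumor"`` — one scene with tumor / healthy / interface species.

    Returns a SceneSpec (or a tuple of two for the paired scene).
    """
    if axis is None:
        axis = default_axis()
    rng = np.random.default_rng(seed)
    m, n = shape
    quartz = quartz_susceptibility()

    def with_substrate(species_maps, tissue_mask=None):
        total = np.sum([amap for _, amap in species_maps], axis=0)
        quartz_map = np.clip(1.0 - total, 0.0, None)
        return SceneSpec(
            shape=shape, species=list(species_maps) + [(quartz, quartz_map)], axis=axis
        )

    if name == "cells":
        lipid = 0.9 * _smooth_field(rng, shape, 3.0) ** 2
        protein = 0.8 * _smooth_field(rng, shape, 4.0)
        nucleic = 0.9 * _smooth_field(rng, shape, 2.5) ** 2
        maps = [lipid, protein, nucleic]
        _plant_pure_pixels(maps, rng)
        return with_substrate(
            [
                (lipid_susceptibility(), maps[0]),
                (protein_susceptibility(), maps[1]),
                (nucleic_acid_susceptibility(), maps[2]),
            ]
        )

    if name == "nash_vs_control":
        # shared tissue footprint; substrate (bare quartz) elsewhere
        tissue = _smooth_field(rng, shape, 5.0) > 0.25
        protein = 0.7 * _smooth_field(rng, shape, 4.0) + 0.2
        lipid_base = 0.45 * _smooth_field(rng, shape, 3.0) + 0.1
        protein = np.where(tissue, protein, 0.0)
        lipid_ctrl = np.where(tissue, lipid_base, 0.0)
        lipid_nash = 1.5 * lipid_ctrl
        maps_c = [protein.copy(), lipid_ctrl.copy()]
        maps_n = [protein.copy(), lipid_nash.copy()]
        _plant_pure_pixels(maps_c, np.random.default_rng(seed + 1))
        _plant_pure_pixels(maps_n, np.random.default_rng(seed + 1))
        control = with_substrate(
            [(protein_susceptibility(), maps_c[0]), (lipid_susceptibility(), maps_c[1])]
        )
        nash = with_substrate(
            [(protein_susceptibility(), maps_n[0]), (lipid_susceptibility(), maps_n[1])]
        )
        return control, nash

    if name == "tumor":
        base = _smooth_field(rng, shape, 6.0)
        tumor_mask = base > 0.6
        healthy_mask = base < 0.45
        interface = ~tumor_mask & ~healthy_mask
        texture = 0.3 * _smooth_field(rng, shape, 2.0)
        tumor_map = np.where(tumor_mask, 0.7 + texture, 0.0)
        healthy_map = np.where(healthy_mask, 0.7 + texture, 0.0)
        iface_map = np.where(interface, 0.7 + texture, 0.0)
        maps = [tumor_map, healthy_map, iface_map]
        _plant_pure_pixels(maps, rng)
        tumor_chi = nucleic_acid_susceptibility() + _chi([(1660, 0.6, 14.0)], 0.0)
        healthy_chi = lipid_susceptibility()
        iface_chi = _chi(  # collagen/elastin-like connective tissue
            [(820, 0.6, 10.0), (855, 0.5, 10.0), (1258, 0.6, 12.0), (1660, 0.7, 16.0)],
            chi_nr=1.0,
        )
        return with_substrate(
            [(tumor_chi, maps[0]), (healthy_chi, maps[1]), (iface_chi, maps[2])]
        )

    raise ValueError(
        f"unknown scene {name!r}; options: cells, nash_vs_control, tumor"
    )


def default_noise(seed: int = 0) -> NoiseModel:
    """Default detector noise: gain 1 count/e-, 5 counts read noise."""
    return NoiseModel(poisson_gain=1.0, gaussian_sigma=5.0, dark_level=100.0, seed=seed)
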