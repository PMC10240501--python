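"""End-to-end orchestration: simulate -> denoise -> KK -> unmix -> quantify.

The stages always run in this order (the denoiser sees raw counts, the
retrieval sees denoised counts, the unmixer sees Raman-like spectra);
individual stages can be toggled off.  Every run serializes its full
configuration and a SHA-256 config hash into the report so outputs are
traceable and bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io
from .calibration import subtract_dark
from .containers import Hypercube
from .denoise import AnscombeSVDDenoiser
from .kk import KKSettings, kk_retrieve_cube
from .quantify import (
    AMIDE_I, CH_STRETCH, TRIGLYCERIDE, BandDefinition, OutlierRule, box_stats,
    integrate_band, mann_whitney, mask_and_filter,
)
from .scenes import default_axis, default_pump, default_stokes, demo_scene
from .simulate import NoiseModel, make_reference_set, render_hypercube
from .scenes import quartz_susceptibility, toluene_susceptibility
from .unmixing import NFINDR

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run (YAML-serializable)."""

    scene: str = "cells"
    shape: tuple = (50, 50)
    seed: int = 42
    # instrument
    pump_center_nm: float = 1035.0
    pump_fwhm_cm1: float = 9.0
    stokes_support_nm: tuple = (1100.0, 1600.0)
    stokes_gdd_fs2: float = 0.0
    axis_lo_cm1: float = 900.0
    axis_hi_cm1: float = 3100.0
    axis_step_cm1: float = 2.0
    # rendering
    exposure_ms: float = 1.0
    peak_counts: float = 5000.0
    noise_gain: float = 1.0
    noise_sigma: float = 5.0
    dark_level: float = 100.0
    # stages
    denoise_enabled: bool = True
    denoise_rank: int = 6
    kk_enabled: bool = True
    kk_pad_factor: int = 4
    kk_smoother_window: int | None = None
    unmix_enabled: bool = True
    unmix_k: int = 3
    unmix_restarts: int = 5
    quantify_enabled: bool = True
    bands: tuple = (
        ("amide I", 1620.0, 1690.0),
        ("triglycerides", 1715.0, 1760.0),
    )
    substrate_frac: float = 0.2
    outlier_iqr_factor: float = 5.0
    n_reference_spectra: int = 100

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("shape", "stokes_support_nm"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.bands = tuple(tuple(b) for b in cfg.bands)
        return cfg


@dataclass
class PipelineResult:
    """Outputs of one run; `report` is the JSON-serializable summary."""

    cubes: list
    retrieved: list
    endmembers: np.ndarray | None
    abundances: list
    band_images: list
    report: dict


def _timed(report, stage, fn):
    t0 = time.perf_counter()
    out = fn()
    report.setdefault("timings_s", {})[stage] = round(time.perf_counter() - t0, 3)
    logger.info("stage %s done in %.2f s", stage, report["timings_s"][stage])
    return out


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run the configured chain on the configured demo scene(s).

    For the paired ``nash_vs_control`` scene the two cubes are unmixed
    jointly (concatenated as one dataset, as for multi-sample comparisons)
    and the quantify stage compares the groups with a Mann-Whitney test.
    """
    report: dict = {"config": config.to_dict(), "config_hash": config.hash(),
                    "scene": config.scene}
    axis = default_axis(config.axis_lo_cm1, config.axis_hi_cm1, config.axis_step_cm1)
    pump = default_pump() if (config.pump_center_nm, config.pump_fwhm_cm1) == (
        1035.0, 9.0) else None
    if pump is None:
        from .fields import make_pump_field

        pump = make_pump_field(config.pump_center_nm, config.pump_fwhm_cm1)
    stokes = default_stokes(tuple(config.stokes_support_nm),
                            gdd_fs2=config.stokes_gdd_fs2)
    noise = NoiseModel(poisson_gain=config.noise_gain,
                       gaussian_sigma=config.noise_sigma,
                       dark_level=config.dark_level, seed=config.seed)

    scenes = demo_scene(config.scene, shape=tuple(config.shape),
                        seed=config.seed, axis=axis)
    if not isinstance(scenes, tuple):
        scenes = (scenes,)

    # --- simulate ---------------------------------------------------------
    def simulate():
        cubes, truths = [], []
        for i, sc in enumerate(scenes):
            nm = dataclasses.replace(noise, seed=config.seed + 1000 * i)
            cube, truth = render_hypercube(
                sc, pump, stokes, nm, exposure_ms=config.exposure_ms,
                peak_counts=config.peak_counts)
            cube.meta["config_hash"] = config.hash()
            cubes.append(cube)
            truths.append(truth)
        return cubes, truths

    cubes, truths = _timed(report, "simulate", simulate)

    refs = _timed(report, "references", lambda: make_reference_set(
        pump, stokes, toluene_susceptibility(), quartz_susceptibility(),
        dataclasses.replace(noise, seed=config.seed + 77), axis,
        n_spectra=config.n_reference_spectra, exposure_ms=config.exposure_ms,
        peak_counts=config.peak_counts))

    # --- dark subtraction + denoise ---------------------------------------
    def preprocess():
        out = []
        for cube in cubes:
            c = subtract_dark(cube, np.full(axis.channel_count, config.dark_level))
            if config.denoise_enabled:
                den = AnscombeSVDDenoiser(rank=config.denoise_rank,
                                          gain=config.noise_gain,
                                          sigma=config.noise_sigma)
                c = den.fit_transform(c)
                report.setdefault("denoise_rank", den.rank_)
            out.append(c)
        return out

    cubes_pp = _timed(report, "denoise", preprocess)

    # --- Kramers-Kronig ----------------------------------------------------
    def retrieve():
        if not config.kk_enabled:
            return cubes_pp
        nrb = refs.nrb_mean - refs.dark_mean
        settings = KKSettings(pad_factor=config.kk_pad_factor,
                              smoother_window=config.kk_smoother_window)
        return [kk_retrieve_cube(c, nrb, settings) for c in cubes_pp]

    retrieved = _timed(report, "kk", retrieve)

    # --- unmixing ----------------------------------------------------------
    endmembers, abundances = None, []
    if config.unmix_enabled:
        def unmix():
            merged = np.concatenate([c.pixels() for c in retrieved], axis=0)
            est = NFINDR(n_endmembers=config.unmix_k,
                         n_restarts=config.unmix_restarts,
                         random_state=config.seed)
            est.fit(merged)
            ab = [est.transform(c) for c in retrieved]
            report["unmix_volume"] = est.volume_
            report["unmix_k"] = config.unmix_k
            return est.endmembers_.spectra, ab

        endmembers, abundances = _timed(report, "unmix", unmix)

    # --- quantification ----------------------------------------------------
    band_images = []
    if config.quantify_enabled:
        def quantify():
            bands = [BandDefinition(*b) for b in config.bands]
            presence = [integrate_band(c, CH_STRETCH) for c in retrieved]
            pooled = np.concatenate([p.ravel() for p in presence])
            thr = config.substrate_frac * np.percentile(pooled, 95)
            rule = OutlierRule(factor=config.outlier_iqr_factor)
            images = []
            for band in bands:
                per_scene = [integrate_band(c, band) for c in retrieved]
                images.append(per_scene)
                groups = [
                    mask_and_filter(img, thr, rule, presence_image=pres)
                    for img, pres in zip(per_scene, presence)
                ]
                entry = {
                    "band": [band.name, band.lo, band.hi],
                    "groups": [dataclasses.asdict(box_stats(g)) for g in groups],
                }
                if len(groups) == 2:
                    u, p = mann_whitney(groups[0], groups[1])
                    entry["mann_whitney_U"] = u
                    entry["p_value"] = p
                report.setdefault("bands", []).append(entry)
            return images

        band_images = _timed(report, "quantify", quantify)

    # --- persist ------------------------------------------------------------
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, (cube, ret) in enumerate(zip(cubes, retrieved)):
            _io.save_hypercube(out / f"cube_{i}.h5", cube)
            _io.save_hypercube(out / f"retrieved_{i}.h5", ret)
        if endmembers is not None:
            _io.save_spectrum(out / "endmember_0.txt", axis, endmembers[0])
            np.savetxt(out / "endmembers.csv",
                       np.column_stack([axis.values, endmembers.T]),
                       delimiter=",",
                       header="wavenumber_cm-1," + ",".join(
                           f"endmember_{k}" for k in range(endmembers.shape[0])))
            for i, ab in enumerate(abundances):
                _io.export_tiff(out / f"abundances_{i}.tif", ab)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))

    return PipelineResult(cubes=cubes, retrieved=retrieved, endmembers=endmembers,
                          abundances=abundances, band_images=band_images,
                          report=report)
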