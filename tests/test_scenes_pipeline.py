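import json

import numpy as np
import pytest

from bcarskit import (
    NoiseModel, PipelineConfig, WavenumberAxis, cars_spectrum, demo_scene,
    kk_retrieve, quartz_susceptibility, render_hypercube, run_pipeline,
)
from bcarskit.kk import kk_retrieve_cube
from bcarskit.scenes import THREE_COLOR_BAND, highest_three_color_mode, toluene_susceptibility
from bcarskit.unmixing import NFINDR
from conftest import best_match_cosine


class TestDemoScenes:
    def test_cells_scene_has_pure_pixels_per_species(self, axis_coarse):
        scene = demo_scene("cells", shape=(30, 30), seed=1, axis=axis_coarse)
        ab = scene.abundance_stack()
        for k in range(3):  # the three cellular species (substrate aside)
            pure = (ab[..., k] == 1.0) & (ab.sum(axis=-1) == 1.0)
            assert pure.any()

    def test_disease_pair_differs_only_in_lipid_abundance(self, axis_coarse):
        control, nash = demo_scene("nash_vs_control", shape=(30, 30), seed=1,
                                   axis=axis_coarse)
        ab_c, ab_n = control.abundance_stack(), nash.abundance_stack()
        # species 0 = protein: identical layouts
        assert np.array_equal(ab_c[..., 0], ab_n[..., 0])
        # species 1 = lipid: raised 1.5x in the diseased scene (tissue pixels)
        tissue = (ab_c[..., 1] > 0) & (ab_c[..., 1] != 1.0)
        ratio = ab_n[..., 1][tissue] / ab_c[..., 1][tissue]
        assert np.allclose(ratio, 1.5)

    def test_unknown_scene_lists_options(self):
        with pytest.raises(ValueError, match="cells"):
            demo_scene("nope")

    def test_toluene_impulsive_band_mode(self):
        mode = highest_three_color_mode(toluene_susceptibility())
        assert THREE_COLOR_BAND[0] <= mode.position <= THREE_COLOR_BAND[1]
        assert mode.position == 1380.0


class TestEndToEnd:
    def test_zero_noise_scene_unmixes_to_its_species(self, pump, stokes,
                                                     axis_coarse):
        """Render -> KK -> N-FINDR at matching k recovers each species'
        retrieved spectrum with cosine > 0.99."""
        scene = demo_scene("cells", shape=(24, 24), seed=3, axis=axis_coarse)
        noise0 = NoiseModel(poisson_gain=0.0, gaussian_sigma=0.0,
                            dark_level=0.0, seed=0)
        cube, truth = render_hypercube(scene, pump, stokes, noise0)
        nrb = cars_spectrum(quartz_susceptibility(), pump, stokes, axis_coarse)
        ret = kk_retrieve_cube(cube, nrb)
        est = NFINDR(n_endmembers=4, random_state=0).fit(ret)
        scale = truth.clean.max()
        for chi, _ in scene.species[:3]:  # substrate retrieves to ~0
            pure_raw = cars_spectrum(chi, pump, stokes, axis_coarse)
            pure_raw = pure_raw * scale / pure_raw.max()
            oracle = kk_retrieve(pure_raw, nrb, axis=axis_coarse).raman_like
            assert best_match_cosine(est.components_, oracle) > 0.99


@pytest.fixture(scope="module")
def small_config():
    return PipelineConfig(scene="nash_vs_control", shape=(16, 16), seed=5,
                          unmix_k=2, unmix_restarts=2,
                          n_reference_spectra=10)


@pytest.fixture(scope="module")
def result(small_config):
    return run_pipeline(small_config)


class TestPipeline:
    def test_report_contains_required_keys(self, result, small_config):
        rep = result.report
        assert rep["config_hash"] == small_config.hash()
        assert rep["unmix_k"] == 2
        assert {e["band"][0] for e in rep["bands"]} == {"amide I",
                                                        "triglycerides"}
        for entry in rep["bands"]:
            assert len(entry["groups"]) == 2
            assert "p_value" in entry
        assert json.dumps(rep, default=float)  # serializable

    def test_determinism_under_fixed_seed(self, small_config, result):
        again = run_pipeline(small_config)
        for a, b in zip(result.abundances, again.abundances):
            assert np.array_equal(a, b)
        assert np.array_equal(result.cubes[0].data, again.cubes[0].data)

    def test_stages_can_be_disabled(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, denoise_enabled=False,
                                  unmix_enabled=False)
        res = run_pipeline(cfg)
        assert res.endmembers is None
        assert "bands" in res.report  # KK + quantify still ran on raw cube

    def test_outputs_persisted_with_provenance(self, small_config, tmp_path):
        run_pipeline(small_config, out_dir=tmp_path)
        report = json.loads((tmp_path / "report.json").read_text())
        assert report["config_hash"] == small_config.hash()
        from bcarskit.io import load_hypercube

        cube = load_hypercube(tmp_path / "cube_0.h5")
        assert cube.meta["config_hash"] == small_config.hash()
        assert (tmp_path / "endmembers.csv").exists()


class TestIO:
    def test_hypercube_hdf5_round_trip(self, tmp_path, cells_cube_noisy):
        from bcarskit.io import load_hypercube, save_hypercube

        cube, _ = cells_cube_noisy
        save_hypercube(tmp_path / "c.h5", cube)
        back = load_hypercube(tmp_path / "c.h5")
        assert np.array_equal(back.data, cube.data)
        assert np.array_equal(back.axis.values, cube.axis.values)
        assert back.meta["seed"] == cube.meta["seed"]

    def test_spectrum_text_round_trip(self, tmp_path, axis_coarse):
        from bcarskit.io import load_spectrum, save_spectrum

        y = np.linspace(0, 1, axis_coarse.channel_count)
        save_spectrum(tmp_path / "s.txt", axis_coarse, y)
        ax, back = load_spectrum(tmp_path / "s.txt")
        assert np.allclose(back, y)
        assert np.allclose(ax.values, axis_coarse.values)

    def test_reference_set_round_trip(self, tmp_path, pump, stokes):
        from bcarskit import make_reference_set
        from bcarskit.io import load_reference_set, save_reference_set

        axis = WavenumberAxis.from_step(900.0, 1500.0, 2.0)
        refs = make_reference_set(pump, stokes, toluene_susceptibility(),
                                  quartz_susceptibility(), NoiseModel(seed=1),
                                  axis, n_spectra=3)
        save_reference_set(tmp_path / "refs", refs)
        back = load_reference_set(tmp_path / "refs")
        assert np.allclose(back.nrb_mean, refs.nrb_mean)
        assert back.n_averaged == 3

    def test_rgb_composite_export(self, tmp_path):
        from PIL import Image

        from bcarskit.io import export_rgb_png

        ab = np.random.default_rng(1).random((10, 12, 3))
        export_rgb_png(tmp_path / "rgb.png", ab)
        img = Image.open(tmp_path / "rgb.png")
        assert img.size == (12, 10)

    def test_tiff_export(self, tmp_path):
        import tifffile

        from bcarskit.io import export_tiff

        stack = np.random.default_rng(0).random((8, 9, 3))
        export_tiff(tmp_path / "a.tif", stack)
        back = tifffile.imread(tmp_path / "a.tif")
        assert back.shape == (3, 8, 9)


class TestCLI:
    def test_simulate_and_denoise_commands(self, tmp_path):
        from click.testing import CliRunner

        from bcarskit.cli import main

        runner = CliRunner()
        cube_path = str(tmp_path / "cube.h5")
        r = runner.invoke(main, ["simulate", "--scene", "cells", "--shape",
                                 "12", "12", "--seed", "1", cube_path])
        assert r.exit_code == 0, r.output
        r2 = runner.invoke(main, ["denoise", cube_path,
                                  str(tmp_path / "den.h5"), "--rank", "4"])
        assert r2.exit_code == 0, r2.output
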