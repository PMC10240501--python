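import numpy as np
import pytest

from bcarskit import (
    LorentzianMode, NoiseModel, SceneSpec, Susceptibility, WavenumberAxis,
    cars_spectrum, make_reference_set, quartz_susceptibility, render_hypercube,
    toluene_susceptibility,
)
from bcarskit.fields import _fwhm
from bcarskit.scenes import protein_susceptibility


@pytest.fixture(scope="module")
def axis(pump):
    return WavenumberAxis.from_step(500.0, 1600.0, 1.0)


class TestCarsSpectrum:
    def test_nrb_only_sample_is_smooth_and_peak_free(self, pump, stokes, axis):
        spec = cars_spectrum(quartz_susceptibility(1.0), pump, stokes, axis)
        assert np.all(spec >= 0)
        # no feature sharper than the resolution: second differences tiny
        # compared with the overall level
        d2 = np.abs(np.diff(spec, 2))
        assert d2.max() < 1e-3 * spec.max()

    def test_dispersive_lineshape_offset_from_mode_position(self, pump, stokes, axis):
        """With dominant NRB the raw peak is pushed off the true position."""
        chi = Susceptibility(modes=(LorentzianMode(1000.0, 5.0, 5.0),), chi_nr=10.0)
        raw = cars_spectrum(chi, pump, stokes, axis, three_color=False)
        nrb = cars_spectrum(quartz_susceptibility(10.0), pump, stokes, axis,
                            three_color=False)
        contrast = raw / nrb  # remove the excitation envelope
        win = axis.select(960, 1040)
        peak = axis.values[win][np.argmax(contrast[win])]
        assert abs(peak - 1000.0) > 2.0

    def test_resolution_set_by_pump_linewidth(self, pump, stokes):
        """A vanishingly narrow mode renders at the pump intensity FWHM."""
        ax = WavenumberAxis.from_step(1300.0, 1500.0, 0.25)
        chi = Susceptibility(
            modes=(LorentzianMode(1400.0, 50.0, 0.05),), chi_nr=0.0)
        raw = cars_spectrum(chi, pump, stokes, ax, three_color=False)
        assert _fwhm(ax.values, raw) == pytest.approx(9.0, abs=2 * ax.step)

    def test_nonnegative_everywhere(self, pump, stokes, axis):
        spec = cars_spectrum(toluene_susceptibility(), pump, stokes, axis)
        assert np.all(spec >= 0)


class TestTimeDelay:
    def test_delay_suppresses_nrb_more_than_tenfold(self, pump, stokes, axis):
        nrb = quartz_susceptibility(1.0)
        at0 = cars_spectrum(nrb, pump, stokes, axis, delay_fs=0.0)
        at3ps = cars_spectrum(nrb, pump, stokes, axis, delay_fs=3000.0)
        assert at0.mean() / at3ps.mean() > 10.0

    def test_resonant_peak_survives_delay(self, pump, stokes, axis):
        # narrow mode: T2 = 2.65 ps, still ringing at 3 ps delay
        chi = Susceptibility(modes=(LorentzianMode(1000.0, 2.0, 2.0),), chi_nr=1.0)
        sig = cars_spectrum(chi, pump, stokes, axis, delay_fs=3000.0)
        bg = cars_spectrum(quartz_susceptibility(1.0), pump, stokes, axis,
                           delay_fs=3000.0)
        win = axis.select(980, 1020)
        assert sig[win].max() > 2.0 * bg[win].max()

    @pytest.mark.parametrize("tau", [500.0, 1000.0, 2000.0])
    def test_three_color_resonance_decays_with_dephasing_time(
            self, pump, stokes, axis, tau):
        """Signal amplitude ~ exp(-tau / T2) with T2 = 1/(2 pi c Gamma)."""
        mode = LorentzianMode(1000.0, 5.0, 5.0)
        chi = Susceptibility(modes=(mode,), chi_nr=1.0)
        nrb = quartz_susceptibility(1.0)
        j = axis.index_of(1000.0)

        def peak_amp(t):
            sig = cars_spectrum(chi, pump, stokes, axis, delay_fs=t,
                                two_color=False)
            bg = cars_spectrum(nrb, pump, stokes, axis, delay_fs=t,
                               two_color=False)
            return np.sqrt(max(sig[j] - bg[j], 0.0))

        ratio = peak_amp(tau) / peak_amp(0.0)
        assert ratio == pytest.approx(np.exp(-tau / mode.dephasing_time_fs),
                                      rel=0.10)


class TestRenderHypercube:
    def _uniform_scene(self, axis, chi, shape=(8, 8)):
        ab = np.ones(shape)
        return SceneSpec(shape=shape, species=[(chi, ab)], axis=axis)

    def test_noiseless_limit_equals_clean_plus_dark(self, pump, stokes, axis):
        scene = self._uniform_scene(axis, toluene_susceptibility())
        noise = NoiseModel(poisson_gain=0.0, gaussian_sigma=0.0,
                           dark_level=40.0, seed=0)
        cube, truth = render_hypercube(scene, pump, stokes, noise)
        assert np.allclose(cube.data, truth.clean + 40.0)

    def test_seeded_determinism(self, pump, stokes, axis):
        scene = self._uniform_scene(axis, toluene_susceptibility())
        noise = NoiseModel(seed=123)
        c1, _ = render_hypercube(scene, pump, stokes, noise)
        c2, _ = render_hypercube(scene, pump, stokes, noise)
        assert np.array_equal(c1.data, c2.data)

    def test_noise_variance_follows_poisson_gaussian_model(self, pump, stokes):
        """Var(counts - clean) = gain * clean + sigma^2, channel by channel."""
        axis = WavenumberAxis.from_step(900.0, 1200.0, 2.0)
        scene = self._uniform_scene(axis, protein_susceptibility(), shape=(64, 64))
        gain, sigma = 2.0, 4.0
        noise = NoiseModel(poisson_gain=gain, gaussian_sigma=sigma,
                           dark_level=0.0, seed=5)
        cube, truth = render_hypercube(scene, pump, stokes, noise,
                                       peak_counts=2000.0)
        resid = cube.data - truth.clean
        var = resid.reshape(-1, axis.channel_count).var(axis=0)
        expected = gain * truth.clean[0, 0] + sigma**2
        assert np.median(np.abs(var / expected - 1.0)) < 0.05

    def test_zero_exposure_rejected(self, pump, stokes, axis):
        scene = self._uniform_scene(axis, toluene_susceptibility())
        with pytest.raises(ValueError):
            render_hypercube(scene, pump, stokes, NoiseModel(), exposure_ms=0.0)

    def test_scene_validation(self, axis):
        with pytest.raises(ValueError):
            SceneSpec(shape=(4, 4), species=[], axis=axis)
        with pytest.raises(ValueError):
            SceneSpec(shape=(4, 4),
                      species=[(toluene_susceptibility(), -np.ones((4, 4)))],
                      axis=axis)


class TestReferenceSet:
    def test_averaging_reduces_noise_by_sqrt_n(self, pump, stokes, axis):
        noise = NoiseModel(poisson_gain=0.0, gaussian_sigma=10.0,
                           dark_level=0.0, seed=3)
        single = make_reference_set(pump, stokes, toluene_susceptibility(),
                                    quartz_susceptibility(), noise, axis,
                                    n_spectra=1)
        clean = make_reference_set(
            pump, stokes, toluene_susceptibility(), quartz_susceptibility(),
            NoiseModel(poisson_gain=0.0, gaussian_sigma=0.0, dark_level=0.0,
                       seed=0), axis, n_spectra=1)
        avg = make_reference_set(pump, stokes, toluene_susceptibility(),
                                 quartz_susceptibility(), noise, axis,
                                 n_spectra=100)
        err1 = np.std(single.analyte_mean - clean.analyte_mean)
        err100 = np.std(avg.analyte_mean - clean.analyte_mean)
        assert err1 / err100 == pytest.approx(10.0, rel=0.2)

    def test_dark_reference_is_constant_without_read_noise(self, pump, stokes, axis):
        noise = NoiseModel(poisson_gain=0.0, gaussian_sigma=0.0,
                           dark_level=77.0, seed=0)
        refs = make_reference_set(pump, stokes, toluene_susceptibility(),
                                  quartz_susceptibility(), noise, axis,
                                  n_spectra=3)
        assert np.allclose(refs.dark_mean, 77.0)
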