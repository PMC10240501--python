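import numpy as np
import pytest
from sklearn.base import clone

from bcarskit import (
    Hypercube, KKSettings, KramersKronigRetriever, LorentzianMode,
    Susceptibility, WavenumberAxis, cars_spectrum, kk_retrieve,
    kk_retrieve_cube, quartz_susceptibility,
)
from bcarskit.fields import _fwhm
from bcarskit.kk import hilbert_phase
from bcarskit.simulate import _pump_kernel


def principal_value_phase(half_log: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Brute-force Kramers-Kronig phase: trapezoidal principal-value integral
    phi(w) = (1/pi) PV int g(w') / (w - w') dw', on a padded copy of g."""
    npad = 4 * half_log.size
    dx = x[1] - x[0]
    g = np.concatenate([
        np.full(npad, half_log[0]), half_log, np.full(npad, half_log[-1])])
    xx = np.concatenate([
        x[0] - dx * np.arange(npad, 0, -1), x, x[-1] + dx * np.arange(1, npad + 1)])
    phi = np.empty(x.size)
    for i, w in enumerate(x):
        diff = w - xx
        with np.errstate(divide="ignore", invalid="ignore"):
            integrand = g / diff
        j = npad + i
        integrand[j] = 0.0  # singular sample: odd part cancels in the PV sense
        # the PV of the singular interval is -2 dx g'(w); the trapezoid with
        # the zeroed sample already supplies half of it
        local = -(g[j + 1] - g[j - 1]) / 2.0
        phi[i] = (np.trapezoid(integrand, xx) + local) / np.pi
    return phi


class TestHilbertPhaseOracle:
    def test_matches_principal_value_integral(self):
        """Time-domain FFT phase vs direct PV quadrature on a small
        instance."""
        x = np.linspace(400.0, 1600.0, 600)
        chi = Susceptibility(
            modes=(LorentzianMode(1000.0, 5.0, 5.0),), chi_nr=5.0)
        half_log = 0.5 * np.log(np.abs(chi(x) / chi.chi_nr) ** 2)
        fast = hilbert_phase(half_log, pad_factor=8)
        slow = principal_value_phase(half_log, x)
        interior = slice(30, -30)
        rms = np.sqrt(np.mean((fast - slow)[interior] ** 2))
        assert rms < 1e-3

    def test_recovers_analytic_phase_of_causal_susceptibility(self):
        x = np.linspace(400.0, 1600.0, 2401)
        chi = Susceptibility(
            modes=(LorentzianMode(1000.0, 3.0, 6.0),), chi_nr=2.0)
        spec = chi(x)
        phi = hilbert_phase(0.5 * np.log(np.abs(spec / chi.chi_nr) ** 2), 8)
        rms = np.sqrt(np.mean((phi - np.angle(spec))[100:-100] ** 2))
        assert rms < 1e-3


class TestKKRetrieve:
    def test_pure_nrb_pixel_retrieves_to_zero(self, pump, stokes, axis_fine,
                                              nrb_reference):
        ret = kk_retrieve(nrb_reference, nrb_reference, axis=axis_fine)
        chi = Susceptibility(
            modes=(LorentzianMode(1002.0, 6.0, 6.0),), chi_nr=10.0)
        peak_sig = cars_spectrum(chi, pump, stokes, axis_fine, three_color=False)
        peak = kk_retrieve(peak_sig, nrb_reference, axis=axis_fine).raman_like.max()
        assert np.abs(ret.raman_like).max() < 0.01 * peak

    @pytest.mark.parametrize("contrast", [0.5, 2.0, 10.0, 20.0])
    def test_peak_position_restored_across_nrb_contrast(
            self, pump, stokes, axis_fine, contrast):
        """Raw CARS maxima are offset; retrieved maxima sit at the mode
        position for NRB-to-peak ratios spanning 0.5-20."""
        gamma = 6.0
        chi = Susceptibility(modes=(LorentzianMode(1200.0, gamma, gamma),),
                             chi_nr=contrast)
        nrb = cars_spectrum(quartz_susceptibility(contrast), pump, stokes,
                            axis_fine, three_color=False)
        raw = cars_spectrum(chi, pump, stokes, axis_fine, three_color=False)
        ret = kk_retrieve(raw, nrb, axis=axis_fine).raman_like
        win = axis_fine.select(1100, 1300)
        peak = axis_fine.values[win][np.argmax(ret[win])]
        assert abs(peak - 1200.0) <= axis_fine.step

    @pytest.mark.parametrize("gamma", [2.5, 5.0, 10.0, 20.0])
    def test_lineshape_width_matches_resolution_convolution(
            self, pump, stokes, axis_fine, gamma):
        """Retrieved FWHM ~ (2 Gamma Lorentzian) conv (pump kernel) within
        15%."""
        chi = Susceptibility(modes=(LorentzianMode(1400.0, gamma, gamma),),
                             chi_nr=10.0)
        nrb = cars_spectrum(quartz_susceptibility(10.0), pump, stokes,
                            axis_fine, three_color=False)
        raw = cars_spectrum(chi, pump, stokes, axis_fine, three_color=False)
        ret = kk_retrieve(raw, nrb, axis=axis_fine).raman_like
        _, kernel = _pump_kernel(pump)
        oracle = np.convolve(np.imag(chi(axis_fine.values)), kernel, "same")
        assert _fwhm(axis_fine.values, ret) == pytest.approx(
            _fwhm(axis_fine.values, oracle), rel=0.15)

    def test_scale_covariance_sqrt(self, pump, stokes, axis_fine, nrb_reference):
        chi = Susceptibility(modes=(LorentzianMode(1002.0, 6.0, 6.0),),
                             chi_nr=10.0)
        raw = cars_spectrum(chi, pump, stokes, axis_fine, three_color=False)
        r1 = kk_retrieve(raw, nrb_reference, axis=axis_fine).raman_like
        r4 = kk_retrieve(4.0 * raw, nrb_reference, axis=axis_fine).raman_like
        assert np.allclose(r4, 2.0 * r1, rtol=1e-8, atol=1e-12)

    def test_toluene_correlates_with_im_chi_oracle(self, pump, stokes,
                                                   axis_fine):
        """Fingerprint-window Pearson r > 0.99 against the resolution-matched
        Im chi ground truth at zero noise."""
        from scipy.stats import pearsonr

        from bcarskit import toluene_susceptibility

        tol = toluene_susceptibility()
        nrb = cars_spectrum(quartz_susceptibility(tol.chi_nr), pump, stokes,
                            axis_fine)
        raw = cars_spectrum(tol, pump, stokes, axis_fine)
        ret = kk_retrieve(raw, nrb, axis=axis_fine).raman_like
        _, kernel = _pump_kernel(pump)
        oracle = np.convolve(np.imag(tol(axis_fine.values)), kernel, "same")
        w = axis_fine.select(600, 1800)
        assert pearsonr(ret[w], oracle[w]).statistic > 0.99

    def test_nan_input_rejected(self, nrb_reference):
        bad = nrb_reference.copy()
        bad[5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            kk_retrieve(bad, nrb_reference)

    def test_clip_negative_setting(self, pump, stokes, axis_fine, nrb_reference):
        chi = Susceptibility(modes=(LorentzianMode(1002.0, 6.0, 6.0),),
                             chi_nr=10.0)
        raw = cars_spectrum(chi, pump, stokes, axis_fine, three_color=False)
        ret = kk_retrieve(raw, nrb_reference, KKSettings(clip_negative=True),
                          axis=axis_fine)
        assert np.all(ret.raman_like >= 0)


class TestCubeRetrieval:
    def test_uniform_cube_matches_single_spectrum(self, pump, stokes,
                                                  axis_fine, nrb_reference):
        chi = Susceptibility(modes=(LorentzianMode(1450.0, 8.0, 8.0),),
                             chi_nr=10.0)
        raw = cars_spectrum(chi, pump, stokes, axis_fine, three_color=False)
        cube = Hypercube(data=np.broadcast_to(raw, (3, 4, raw.size)).copy(),
                         axis=axis_fine)
        out = kk_retrieve_cube(cube, nrb_reference)
        single = kk_retrieve(raw, nrb_reference, axis=axis_fine).raman_like
        assert np.allclose(out.data, single[None, None, :])

    def test_retriever_estimator_composes_with_sklearn(self, pump, stokes,
                                                       axis_fine, nrb_reference):
        est = KramersKronigRetriever(pad_factor=4)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        chi = Susceptibility(modes=(LorentzianMode(1002.0, 6.0, 6.0),),
                             chi_nr=10.0)
        raw = cars_spectrum(chi, pump, stokes, axis_fine, three_color=False)
        out = cloned.fit(nrb_reference).transform(raw[None, :])
        assert out.shape == (1, axis_fine.channel_count)
        peak = axis_fine.values[np.argmax(out[0])]
        assert abs(peak - 1002.0) <= axis_fine.step
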