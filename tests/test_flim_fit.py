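"""Decay model, reconvolution fitting, and lifetime-map utilities."""

import numpy as np
import pytest

from omiflim import flim_fit as ff
from omiflim import synthetic_data as sd
from omiflim.io_formats import FlimStack


def brute_force_convolution(decay, kernel):
    """Direct double-sum discrete convolution (independent oracle)."""
    n = decay.size
    out = np.zeros(n)
    for i in range(n):
        for j in range(i + 1):
            out[i] += kernel[j] * decay[i - j]
    return out


class TestModelDecay:
    def test_delta_irf_gives_pure_biexponential(self, small_irf):
        p = ff.BiExpParams(0.6, 0.4, 0.5, 2.0, offset_c=3.0)
        t = (np.arange(64) + 0.5) * 0.05
        expected = 0.6 * np.exp(-t / 0.5) + 0.4 * np.exp(-t / 2.0) + 3.0
        model = ff.model_decay(p, small_irf, 64, 0.05)
        np.testing.assert_allclose(model, expected, rtol=1e-12)

    def test_mono_shape_when_alpha2_zero(self, small_irf):
        p = ff.BiExpParams(1.0, 0.0, 1.0, 5.0)
        t = (np.arange(64) + 0.5) * 0.05
        model = ff.model_decay(p, small_irf, 64, 0.05)
        np.testing.assert_allclose(model, np.exp(-t / 1.0), rtol=1e-12)

    def test_matches_brute_force_convolution(self):
        n, bw = 128, 0.05
        t = (np.arange(n) + 0.5) * bw
        kernel = np.exp(-0.5 * ((t - 0.5) / 0.1) ** 2)
        irf = ff.InstrumentResponse(kernel, bw)
        p = ff.BiExpParams(0.7, 0.3, 0.4, 2.5)
        decay = 0.7 * np.exp(-t / 0.4) + 0.3 * np.exp(-t / 2.5)
        oracle = brute_force_convolution(decay, irf.kernel)
        model = ff.model_decay(p, irf, n, bw)
        np.testing.assert_allclose(model, oracle, atol=1e-10)

    def test_grid_mismatch_rejected(self, small_irf):
        p = ff.BiExpParams(0.7, 0.3, 0.4, 2.5)
        with pytest.raises(ValueError, match="grid"):
            ff.model_decay(p, small_irf, 128, 0.05)

    def test_photon_conservation_on_default_grid(self, irf):
        # with C = 0, truncation of the reconvolved curve on the default
        # 12.5 ns window loses < 1% of the total amplitude
        p = ff.BiExpParams(0.7, 0.3, 0.4, 2.5)
        delta = ff.InstrumentResponse.delta(irf.n_bins, irf.bin_width_ns)
        model = ff.model_decay(p, delta, irf.n_bins, irf.bin_width_ns)
        total = (p.alpha1 * p.tau1 + p.alpha2 * p.tau2) / irf.bin_width_ns
        assert model.sum() == pytest.approx(total, rel=0.01)


class TestMeanLifetime:
    def test_printed_formula_arithmetic(self):
        assert ff.mean_lifetime(ff.BiExpParams(0.7, 0.3, 0.4, 2.5)) == \
            pytest.approx(1.03)

    def test_pure_mono_limit(self):
        assert ff.mean_lifetime(ff.BiExpParams(1.0, 0.0, 0.9, 2.0)) == \
            pytest.approx(0.9)

    def test_random_params_against_dot_product_oracle(self, rng):
        for _ in range(200):
            a1 = rng.uniform(0.01, 0.99)
            t1 = rng.uniform(0.1, 1.0)
            t2 = rng.uniform(1.5, 5.0)
            p = ff.BiExpParams(a1, 1 - a1, t1, t2)
            oracle = float(np.dot([a1, 1 - a1], [t1, t2]))
            assert abs(ff.mean_lifetime(p) - oracle) < 1e-12


class TestBiExpParamsValidation:
    @pytest.mark.parametrize("a1,a2,t1,t2", [
        (0.7, 0.2, 0.4, 2.5),   # alphas don't sum to 1
        (0.7, 0.3, 2.5, 0.4),   # reversed lifetimes
        (0.7, 0.3, 0.0, 2.5),   # zero lifetime
    ])
    def test_invalid_rejected(self, a1, a2, t1, t2):
        with pytest.raises(ValueError):
            ff.BiExpParams(a1, a2, t1, t2)


class TestIrfFwhm:
    def test_rectangular_kernel_width(self):
        k = np.zeros(128)
        k[10:20] = 1.0  # 10 bins of 50 ps = 500 ps wide
        irf = ff.InstrumentResponse(k, 0.05)
        assert ff.irf_fwhm(irf) == pytest.approx(500.0, abs=50.0)

    @pytest.mark.parametrize("sigma_ps", [60.0, 93.4, 150.0, 250.0])
    def test_sampled_gaussian_matches_analytic(self, sigma_ps):
        bw = 0.0122
        n = 1024
        t = (np.arange(n) + 0.5) * bw
        k = np.exp(-0.5 * ((t - 2.0) / (sigma_ps / 1000)) ** 2)
        irf = ff.InstrumentResponse(k, bw)
        analytic = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma_ps
        assert ff.irf_fwhm(irf) == pytest.approx(analytic, abs=bw * 1000)


class TestBinPixels:
    def _stack(self, counts):
        return FlimStack(counts=counts, bin_width_ns=0.05, channel="NADH")

    def test_radius_zero_identity(self, rng):
        s = self._stack(rng.poisson(3.0, size=(16, 6, 6)))
        assert ff.bin_pixels(s, 0) is s

    def test_uniform_interior_times_nine(self):
        s = self._stack(np.ones((16, 8, 8), dtype=int))
        out = ff.bin_pixels(s, 1)
        assert np.all(out.counts[:, 1:-1, 1:-1] == 9)
        assert out.counts[0, 0, 0] == 4  # corner window is 2x2

    def test_random_stack_against_sliding_window_oracle(self, rng):
        counts = rng.poisson(2.0, size=(16, 7, 9))
        out = ff.bin_pixels(self._stack(counts), 1).counts
        for y in range(7):
            for x in range(9):
                window = counts[:, max(y - 1, 0):y + 2, max(x - 1, 0):x + 2]
                np.testing.assert_array_equal(out[:, y, x],
                                              window.sum(axis=(1, 2)))


class TestIntensityImage:
    def test_zero_and_single_voxel(self):
        counts = np.zeros((16, 4, 4), dtype=int)
        s = FlimStack(counts, 0.05, "NADH")
        assert ff.intensity_image(s).sum() == 0
        counts[5, 2, 3] = 1
        s = FlimStack(counts, 0.05, "NADH")
        img = ff.intensity_image(s)
        assert img[2, 3] == 1 and img.sum() == 1

    def test_random_stack_axis_sum_oracle(self, rng):
        counts = rng.poisson(1.5, size=(20, 5, 5))
        s = FlimStack(counts, 0.05, "NADH")
        np.testing.assert_array_equal(ff.intensity_image(s),
                                      counts.sum(axis=0))


class TestFitBiexponential:
    TRUTH = ff.BiExpParams(0.7, 0.3, 0.4, 2.5)

    def test_noiseless_recovery_within_1e3(self, irf):
        curve = ff.model_decay(self.TRUTH, irf, irf.n_bins,
                               irf.bin_width_ns, scale=1e5)
        res = ff.fit_biexponential(
            ff.DecayHistogram(curve, irf.bin_width_ns), irf)
        assert res.converged
        p = res.params
        assert p.alpha1 == pytest.approx(0.7, rel=1e-3)
        assert p.tau1 == pytest.approx(0.4, rel=1e-3)
        assert p.tau2 == pytest.approx(2.5, rel=1e-3)
        assert res.photons == int(curve.sum())

    def test_reconvolution_roundtrip_with_offset(self, irf):
        truth = ff.BiExpParams(0.6, 0.4, 0.5, 2.2, offset_c=5.0)
        curve = ff.model_decay(truth, irf, irf.n_bins,
                               irf.bin_width_ns, scale=2e4)
        res = ff.fit_biexponential(
            ff.DecayHistogram(curve, irf.bin_width_ns), irf)
        assert res.params.tau_m == pytest.approx(truth.tau_m, rel=1e-3)

    def test_tau_ordering_enforced(self, irf, rng):
        for s in range(5):
            d = sd.simulate_decay(self.TRUTH, irf, 5e3, seed=s)
            p = ff.fit_biexponential(d, irf).params
            assert p.tau1 < p.tau2

    def test_all_zero_decay_raises_insufficient_photons(self, irf):
        d = ff.DecayHistogram(np.zeros(irf.n_bins, dtype=int),
                              irf.bin_width_ns)
        with pytest.raises(ff.InsufficientPhotonsError,
                           match="insufficient photons"):
            ff.fit_biexponential(d, irf)

    def test_neyman_weighting_also_recovers_noiseless(self, irf):
        curve = ff.model_decay(self.TRUTH, irf, irf.n_bins,
                               irf.bin_width_ns, scale=1e5)
        res = ff.fit_biexponential(
            ff.DecayHistogram(curve, irf.bin_width_ns), irf,
            weighting="neyman")
        assert res.params.tau_m == pytest.approx(self.TRUTH.tau_m, rel=1e-3)


class TestFitMonoexponential:
    def test_delta_irf_noiseless_tau(self):
        n, bw = 256, 0.05
        irf = ff.InstrumentResponse.delta(n, bw)
        t = (np.arange(n) + 0.5) * bw
        curve = 1e4 * np.exp(-t / 1.0)
        tau = ff.fit_monoexponential(ff.DecayHistogram(curve, bw), irf)
        assert tau == pytest.approx(1.0, abs=1e-3)

    def test_simulated_3ns_mean_within_one_percent(self, irf):
        p = ff.BiExpParams(1.0, 0.0, 3.0, 12.0)
        taus = [ff.fit_monoexponential(
            sd.simulate_decay(p, irf, 1e5, seed=s), irf) for s in range(20)]
        assert np.mean(taus) == pytest.approx(3.0, rel=0.01)


class TestFitImage:
    def test_empty_stack_all_invalid(self, irf):
        counts = np.zeros((irf.n_bins, 4, 4), dtype=int)
        s = FlimStack(counts, irf.bin_width_ns, "NADH")
        out = ff.fit_image(s, irf)
        assert not out.valid_mask.any()
        assert np.isnan(out.tau_m).all()

    def test_single_cell_scene_recovers_tau_m(self, irf):
        preset = sd.ScenePreset(shape=(32, 32), n_cells=1, cell_radius=6,
                                nucleus_radius=2)
        nadh, _, masks, truth = sd.render_scene(preset, seed=3)
        out = ff.fit_image(nadh, irf)
        cyto = masks.cytoplasm == 1
        valid = cyto & out.valid_mask
        assert valid.sum() > 0.9 * cyto.sum()
        true_tm = truth["nadh_tau_m"].iloc[0]
        rel_err = np.abs(out.tau_m[valid] / true_tm - 1.0)
        assert np.median(rel_err) < 0.05
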