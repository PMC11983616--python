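import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specfuse import preprocessing as pp
from specfuse.io import CANONICAL_GRID, SpectraMatrix
from specfuse import synthetic as sy


class TestSavitzkyGolay:
    def test_degree4_polynomial_is_fixed_point(self):
        # a degree-4 polynomial is reproduced exactly by degree-4 local fits
        lam = np.linspace(-1, 1, 300)
        poly = 2 + 3 * lam + lam ** 2 - 0.5 * lam ** 3 + 0.1 * lam ** 4
        out = pp.sg_smooth(poly)
        np.testing.assert_allclose(out, poly, rtol=0, atol=1e-9)

    def test_smoothing_contracts_white_noise(self, rng):
        noise = rng.normal(0, 1, 2151)
        assert pp.sg_smooth(noise).var() < noise.var()

    def test_impulse_response_matches_projection_matrix_oracle(self):
        # oracle: the 13x13 least-squares projection matrix built from
        # scratch; its center row is the impulse response at the center
        cfg = pp.SGConfig(degree=4, half_width=6)
        t = np.arange(13, dtype=float)
        A = np.vander(t, cfg.degree + 1, increasing=True)
        P = A @ np.linalg.inv(A.T @ A) @ A.T
        for k in range(13):
            impulse = np.zeros(41)
            impulse[14 + k] = 1.0  # interior window around position 20
            out = pp.sg_smooth(impulse, cfg)
            assert out[20] == pytest.approx(P[6, k], abs=1e-10)

    def test_window_must_fit(self):
        with pytest.raises(ValueError, match="exceed"):
            pp.sg_smooth(np.zeros(10), pp.SGConfig(degree=4, half_width=6))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            pp.SGConfig(degree=5, half_width=2)


class TestSNV:
    def test_hand_example(self):
        np.testing.assert_allclose(pp.snv(np.array([1.0, 2.0, 3.0])),
                                   [-1.0, 0.0, 1.0], atol=1e-12)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, seed):
        x = np.random.default_rng(seed).normal(0, 1, 50)
        np.testing.assert_allclose(pp.snv(3.0 * x + 0.7), pp.snv(x), atol=1e-9)

    def test_output_moments(self, rng):
        out = pp.snv(rng.normal(0.3, 0.05, (5, 200)))
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pp.snv(np.full(10, 0.4))


class TestMSC:
    def test_reference_regression_recovers_itself(self, rng):
        ref = rng.uniform(0.1, 0.5, 80)
        corrected, fit = pp.msc_apply(ref, ref)
        np.testing.assert_allclose(corrected, ref, atol=1e-12)
        assert fit.alpha[0] == pytest.approx(1.0) and fit.beta[0] == pytest.approx(0.0, abs=1e-12)

    def test_affine_distortion_removed_exactly(self, rng):
        ref = rng.uniform(0.1, 0.5, 80)
        corrected, _ = pp.msc_apply(2.0 * ref + 3.0, ref)
        np.testing.assert_allclose(corrected, ref, atol=1e-10)

    def test_slope_offset_match_least_squares_oracle(self, rng):
        ref = rng.uniform(0.1, 0.5, 80)
        x = rng.normal(0.3, 0.1, 80)
        _, fit = pp.msc_apply(x, ref)
        A = np.column_stack([ref, np.ones(80)])
        slope, intercept = np.linalg.lstsq(A, x, rcond=None)[0]
        assert fit.alpha[0] == pytest.approx(slope, abs=1e-10)
        assert fit.beta[0] == pytest.approx(intercept, abs=1e-10)

    def test_reference_needs_two_samples(self):
        with pytest.raises(ValueError, match="at least 2"):
            pp.msc_fit(np.ones((1, 10)))


class TestPAN:
    def test_constant_half_normalizes_to_inverse_range(self):
        out = pp.pan(np.full(2151, 0.5), CANONICAL_GRID)
        np.testing.assert_allclose(out, 1.0 / 2150.0, atol=1e-15)

    def test_unit_area_and_idempotence(self, rng):
        x = rng.uniform(0.05, 0.6, 2151)
        once = pp.pan(x, CANONICAL_GRID)
        assert np.trapezoid(once, CANONICAL_GRID) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(pp.pan(once, CANONICAL_GRID), once, atol=1e-12)

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValueError, match="area"):
            pp.pan(np.full(2151, -0.1), CANONICAL_GRID)


class TestCWT:
    def test_constant_gives_zero_coefficients(self):
        for a in (2, 32, 1024):
            out = pp.cwt_scale(np.full(2151, 0.37), a)
            np.testing.assert_allclose(out, 0, atol=1e-9)

    def test_linearity(self, rng):
        x, y = rng.normal(0, 1, 2151), rng.normal(0, 1, 2151)
        lhs = pp.cwt_scale(1.5 * x - 2.0 * y, 16)
        rhs = 1.5 * pp.cwt_scale(x, 16) - 2.0 * pp.cwt_scale(y, 16)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_step_edge_response_matches_integral_oracle(self):
        # oracle: direct numerical integration of the transform integral
        # with the sampled mother wavelet, at 11 bands around the edge
        import pywt
        k = 1000
        step = np.zeros(2151)
        step[k:] = 1.0
        scale = 4
        got = pp.cwt_scale(step, scale)
        wav = pywt.ContinuousWavelet("gaus1")
        psi, xg = wav.wavefun(length=4096)
        for b in range(k - 5, k + 6):
            lam = np.arange(-5 * scale, 5 * scale + 1)
            f = np.where(b + lam >= k, 1.0, 0.0)  # step in mirror-free zone
            w = np.interp(lam / scale, xg, psi, left=0, right=0) / np.sqrt(scale)
            w -= w.mean()
            assert got[b] == pytest.approx(float(np.sum(f * w)), abs=1e-4)
        # edge localization: |coefficient| maximal at the step
        inner = np.abs(got[100:-100])
        assert abs(np.argmax(inner) + 100 - k) <= 1

    def test_unsupported_scale_rejected(self):
        with pytest.raises(ValueError, match="unsupported scale"):
            pp.cwt_scale(np.zeros(2151), 3)

    def test_stack_has_ten_planes_same_band_count(self, rng):
        x = rng.normal(0.3, 0.02, (2, 2151))
        stack = pp.cwt_all(x)
        assert stack.coefficients.shape == (2, 10, 2151)
        assert stack.scales == tuple(2 ** k for k in range(1, 11))


class TestDispatcher:
    def test_raw_tag_is_identity(self, small_world):
        _, _, _, spectra = small_world
        out = pp.preprocess(spectra, "R")
        np.testing.assert_array_equal(out.values, spectra.values)

    def test_cwt5_is_sg_then_scale32(self, small_world):
        _, _, _, spectra = small_world
        out = pp.preprocess(spectra, "CWT-5")
        expected = pp.cwt_scale(pp.sg_smooth(spectra.values), 32)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_msc_reference_comes_from_calibration_only(self, small_world):
        _, _, _, spectra = small_world
        cal = spectra.sample_ids[:20]
        out = pp.preprocess(spectra, "SG-MSC", calibration_ids=cal)
        assert out.meta["msc_reference_ids"] == cal
        # the recorded reference provenance excludes every other sample
        assert not set(out.meta["msc_reference_ids"]) & set(spectra.sample_ids[20:])

    def test_unknown_tag_lists_valid_tags(self, small_world):
        _, _, _, spectra = small_world
        with pytest.raises(ValueError, match="SG-SNV"):
            pp.preprocess(spectra, "CWT-11")

    def test_sample_and_band_counts_preserved(self, small_world):
        _, _, _, spectra = small_world
        for tag in ("SG", "SG-SNV", "SG-PAN", "CWT-3"):
            out = pp.preprocess(spectra, tag)
            assert out.values.shape == spectra.values.shape


class TestScatterRemoval:
    def test_snv_and_msc_remove_generator_scatter(self, small_config):
        """SNV/MSC collapse the synthetic per-sample gain/offset artifacts:
        deviation from the scatter-free run shrinks by >= 90 percent."""
        from dataclasses import replace
        clean_cfg = replace(small_config.noiseless())
        scat_cfg = replace(clean_cfg, scatter_gain_sd=0.05, scatter_offset_sd=0.01)
        design = sy.generate_design(clean_cfg)
        physio = sy.generate_physio(design, clean_cfg, seed=3)
        clean = sy.generate_spectra(physio, design, clean_cfg, seed=3).values
        scat = sy.generate_spectra(physio, design, scat_cfg, seed=3).values

        def rel_dev(a, b):
            return np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b ** 2))

        before = rel_dev(scat, clean)
        after_snv = rel_dev(pp.snv(scat), pp.snv(clean))
        ref = pp.msc_fit(clean[:40])
        after_msc = rel_dev(pp.msc_apply(scat, ref)[0], pp.msc_apply(clean, ref)[0])
        assert after_snv <= 0.1 * before
        assert after_msc <= 0.1 * before
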