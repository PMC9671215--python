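"""Lamellar structure factor: model, profiles, period, fitting, typing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipoplex import synth, tem


def oracle_structure_factor(s0, k, d, delta, alpha, b, r):
    """Independent scalar transcription of the damped-compacted-sine model."""
    out = []
    for ri in np.atleast_1d(r):
        local = d * (1.0 + delta * ri)
        out.append(b + s0 * math.exp(-k * ri) * abs(math.sin(math.pi * ri / local)) ** alpha)
    return np.array(out)


class TestEvaluateModel:
    @given(
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=0, max_value=0.5),
        st.floats(min_value=1.0, max_value=20),
        st.floats(min_value=0, max_value=0.05),
        st.floats(min_value=1, max_value=12),
        st.floats(min_value=0, max_value=2),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_independent_oracle(self, s0, k, d, delta, alpha, b):
        m = tem.LamellarModel(s0, k, d, delta, alpha, b)
        r = np.linspace(0, 50, 73)
        assert np.allclose(
            tem.evaluate_model(m, r), oracle_structure_factor(s0, k, d, delta, alpha, b, r),
            rtol=1e-12, atol=1e-12,
        )

    def test_sine_roots_and_peak(self):
        m = tem.LamellarModel(2.0, 0.0, 5.0, 0.0, 1.0, 0.0)
        roots = tem.evaluate_model(m, np.array([0.0, 5.0, 10.0, 15.0]))
        assert np.allclose(roots, 0.0, atol=1e-12)
        assert tem.evaluate_model(m, np.array([2.5]))[0] == pytest.approx(2.0, rel=1e-12)

    def test_compaction_narrows_peaks(self):
        d = 5.4
        fwhm = {
            a: tem.dense_layer_thickness(d, a) for a in (1.0, 8.0)
        }
        assert fwhm[1.0] == pytest.approx(2 * d / 3, rel=1e-12)
        assert fwhm[8.0] == pytest.approx(0.261 * d, abs=0.005)

    def test_negative_radius_rejected(self):
        m = tem.LamellarModel(1.0, 0.0, 5.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            tem.evaluate_model(m, np.array([-1.0]))


class TestDenseLayerThickness:
    def test_closed_form_values(self):
        assert tem.dense_layer_thickness(5.4, 8.0) == pytest.approx(1.41, abs=0.01)

    def test_strictly_decreasing_in_alpha_linear_in_D(self):
        alphas = np.linspace(1, 32, 30)
        d_vals = [tem.dense_layer_thickness(5.4, a) for a in alphas]
        assert all(x > y for x, y in zip(d_vals, d_vals[1:]))
        assert tem.dense_layer_thickness(10.8, 8.0) == pytest.approx(
            2 * tem.dense_layer_thickness(5.4, 8.0), rel=1e-12
        )

    def test_large_alpha_limit(self):
        # d ~ D*(2/pi)*sqrt(2 ln2 / alpha) -> 0 as alpha grows
        assert tem.dense_layer_thickness(5.4, 1e6) < 0.01
        assert tem.dense_layer_thickness(5.4, 1e8) < tem.dense_layer_thickness(5.4, 1e6)


class TestExtractLineProfile:
    def test_constant_image_constant_profile(self):
        img = np.full((64, 64), 7.0)
        prof = tem.extract_line_profile(img, (32, 4), (32, 60), width=3, pixel_size_nm=0.5)
        assert np.allclose(prof.intensities, 7.0)
        assert prof.distances[0] == 0.0
        assert np.allclose(np.diff(prof.distances), 0.5)

    def test_ring_image_period_recovery(self, lamellar_presets):
        m = lamellar_presets["A1"]
        spec = synth.SyntheticImageSpec(model=m, seed=0)
        img, rec = synth.make_lamellar_image(spec)
        prof = tem.extract_line_profile(
            img.astype(float), (128, 128), (128, 236), width=1, pixel_size_nm=0.5
        )
        period = tem.estimate_period(prof)
        assert abs(period - m.spacing_D) <= 0.5  # within one pixel

    def test_zero_noise_image_matches_model(self, lamellar_presets):
        m = lamellar_presets["A1"]
        spec = synth.SyntheticImageSpec(model=m, seed=0)
        img, rec = synth.make_lamellar_image(spec)
        scale = rec.parameters["intensity_scale"]
        prof = tem.extract_line_profile(
            img.astype(float), (128, 128), (128, 236), width=1, pixel_size_nm=0.5
        )
        model_vals = tem.evaluate_model(m, prof.distances) * scale
        rel = np.abs(prof.intensities - model_vals) / model_vals.max()
        assert rel.max() < 1e-3

    def test_width_one_equals_single_line(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        a = tem.extract_line_profile(img, (10, 5), (50, 55), width=1, pixel_size_nm=1.0)
        b = tem.extract_line_profile(img, (10, 5), (50, 55), width=1, pixel_size_nm=1.0)
        assert np.array_equal(a.intensities, b.intensities)

    def test_endpoint_outside_image_rejected(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError):
            tem.extract_line_profile(img, (0, 0), (40, 40), pixel_size_nm=1.0)

    def test_pixel_size_mandatory(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError):
            tem.extract_line_profile(img, (0, 0), (10, 10), pixel_size_nm=None)


class TestEstimatePeriod:
    def test_pure_sinusoid(self, radius_grid):
        m = tem.LamellarModel(1.0, 0.0, 5.4, 0.0, 1.0, 0.0)
        prof = tem.RadialProfile(radius_grid, tem.evaluate_model(m, radius_grid))
        assert tem.estimate_period(prof) == pytest.approx(5.4, abs=0.1)

    def test_constant_profile_errors(self, radius_grid):
        prof = tem.RadialProfile(radius_grid, np.full_like(radius_grid, 3.0))
        with pytest.raises(tem.PeriodEstimationError):
            tem.estimate_period(prof)

    def test_two_tone_returns_stronger_and_flags(self, radius_grid):
        r = radius_grid
        strong = np.abs(np.sin(np.pi * r / 5.0))
        weak = 0.6 * np.abs(np.sin(np.pi * r / 8.0))
        prof = tem.RadialProfile(r, strong + weak)
        diag = tem.estimate_period(prof, return_diagnostics=True)
        assert diag["period_nm"] == pytest.approx(5.0, abs=0.2)
        assert diag["ambiguous"]


class TestFitLamellar:
    @pytest.mark.parametrize("preset", ["A1", "A2", "B"])
    def test_noise_free_recovery(self, preset, clean_profile, lamellar_presets):
        m = lamellar_presets[preset]
        fit = tem.fit_lamellar(clean_profile(m))
        assert fit.converged
        truth = m.as_vector()
        est = fit.params.as_vector()
        for t, e in zip(truth, est):
            if t == 0:
                assert abs(e) < 1e-4
            else:
                assert abs(e - t) / t < 0.005

    def test_refit_from_truth_is_fixed_point(self, clean_profile, lamellar_presets):
        m = lamellar_presets["A1"]
        fit = tem.fit_lamellar(clean_profile(m), init=m)
        assert fit.residual_norm < 1e-8
        assert np.allclose(fit.params.as_vector(), m.as_vector(), rtol=1e-6, atol=1e-9)

    def test_short_profile_rejected(self):
        r = np.linspace(0.5, 5, 10)
        with pytest.raises(ValueError):
            tem.fit_lamellar(tem.RadialProfile(r, np.ones_like(r)))

    def test_hopeless_profile_flags_nonconverged_or_poor(self, radius_grid):
        # pure noise with no oscillation: must not return a silent answer
        rng = np.random.default_rng(0)
        prof = tem.RadialProfile(radius_grid, rng.random(radius_grid.size))
        fit = tem.fit_lamellar(prof)
        # either flagged non-converged or carries a substantial residual
        assert (not fit.converged) or fit.residual_norm > 0.1

    def test_noisy_b_preset_alpha_near_one(self, radius_grid, lamellar_presets):
        m = lamellar_presets["B"]
        pscale = synth.poisson_scale_for_snr(m, 10.0)
        ok = 0
        for seed in range(20):
            y, _ = synth.make_noisy_profile(m, radius_grid, poisson_scale=pscale, seed=seed)
            fit = tem.fit_lamellar(tem.RadialProfile(radius_grid, y))
            if 1.0 <= fit.params.compaction_alpha <= 1.5:
                ok += 1
        assert ok >= 18  # >= 90%


class TestClassifyParticle:
    def _fit_of(self, model, profile_factory):
        return tem.fit_lamellar(profile_factory(model))

    @pytest.mark.parametrize(
        "preset,label",
        [
            ("A1", tem.ParticleLabel.A1_COMPACT),
            ("A2", tem.ParticleLabel.A2_CORE_SHELL),
            ("B", tem.ParticleLabel.B_HOLLOW),
        ],
    )
    def test_preset_typology(self, preset, label, clean_profile, lamellar_presets):
        fit = self._fit_of(lamellar_presets[preset], clean_profile)
        cls = tem.classify_particle(fit)
        assert cls.label is label
        assert cls.rule_trace

    def test_nonconverged_fit_unclassified(self):
        m = tem.LamellarModel(1.0, 0.0, 5.0, 0.0, 1.0)
        bad = tem.LamellarFit(
            params=m, std_errors={}, residual_norm=np.inf, converged=False, n_starts_used=1
        )
        assert tem.classify_particle(bad).label is tem.ParticleLabel.UNCLASSIFIED
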