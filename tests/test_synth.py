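"""Synthetic-instrument generators: determinism, presets, noise model."""

import numpy as np
import pytest

from lipoplex import dls, synth, tem
from lipoplex.formulation import recipe_report
from lipoplex.io import read_recipe


class TestLamellarPresets:
    def test_presets_carry_printed_parameters(self):
        a1 = synth.lamellar_preset("A1")
        assert (a1.spacing_D, a1.compaction_alpha, a1.decay_k) == (5.4, 8.0, 0.0)
        a2 = synth.lamellar_preset("A2")
        assert (a2.spacing_D, a2.decay_k) == (7.3, 0.05)
        b = synth.lamellar_preset("B")
        assert (b.spacing_D, b.compaction_alpha) == (5.2, 1.0)

    def test_invented_parameters_tagged(self):
        assert "dilation_delta" in synth.lamellar_preset_synthetic_choices("A2")
        assert "compaction_alpha" in synth.lamellar_preset_synthetic_choices("A2")

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            synth.lamellar_preset("C")


class TestLamellarImage:
    def test_seeded_hash_stability(self):
        m = synth.lamellar_preset("A1")
        spec = synth.SyntheticImageSpec(model=m, poisson_scale=100.0, seed=5)
        img1, rec1 = synth.make_lamellar_image(spec)
        img2, rec2 = synth.make_lamellar_image(spec)
        assert rec1.content_hash == rec2.content_hash
        assert np.array_equal(img1, img2)

    def test_different_seed_same_truth(self):
        m = synth.lamellar_preset("A1")
        s1 = synth.SyntheticImageSpec(model=m, poisson_scale=100.0, seed=5)
        s2 = synth.SyntheticImageSpec(model=m, poisson_scale=100.0, seed=6)
        img1, rec1 = synth.make_lamellar_image(s1)
        img2, rec2 = synth.make_lamellar_image(s2)
        assert rec1.content_hash != rec2.content_hash
        assert rec1.parameters["model"] == rec2.parameters["model"]

    def test_zero_noise_profile_identity(self):
        m = synth.lamellar_preset("B")
        spec = synth.SyntheticImageSpec(model=m, seed=0)
        img, rec = synth.make_lamellar_image(spec)
        prof = tem.extract_line_profile(
            img.astype(float), (128, 128), (128, 236), width=1, pixel_size_nm=0.5
        )
        model_vals = tem.evaluate_model(m, prof.distances) * rec.parameters["intensity_scale"]
        assert np.abs(prof.intensities - model_vals).max() / model_vals.max() < 1e-3

    def test_oversized_particle_rejected(self):
        m = synth.lamellar_preset("A1")
        with pytest.raises(ValueError):
            synth.SyntheticImageSpec(model=m, outer_radius_nm=200.0, seed=0)

    def test_corona_region_uses_corona_model(self):
        core = synth.lamellar_preset("A1")
        corona = synth.lamellar_preset("B")
        spec = synth.SyntheticImageSpec(
            model=core, corona_start_radius_nm=30.0, corona_model=corona, seed=0
        )
        field = synth.clean_intensity_field(spec)
        # at radius 40 nm along the axis the corona model must apply
        r_px = int(40.0 / spec.pixel_size_nm)
        val = field[128, 128 + r_px]
        assert val == pytest.approx(float(tem.evaluate_model(corona, np.array([40.0]))[0]))


class TestPoissonScaleForSnr:
    def test_target_snr_reached_empirically(self):
        m = synth.lamellar_preset("A1")
        pscale = synth.poisson_scale_for_snr(m, 10.0)
        peak = float(tem.evaluate_model(m, np.linspace(0, 50, 2048)).max())
        draws = np.random.default_rng(0).poisson(peak * pscale, size=20000) / pscale
        assert draws.std() == pytest.approx(peak / 10.0, rel=0.05)

    def test_excess_gaussian_noise_rejected(self):
        m = synth.lamellar_preset("A1")
        with pytest.raises(ValueError):
            synth.poisson_scale_for_snr(m, 10.0, gaussian_sigma=10.0)


class TestDlsGenerator:
    def test_pellet_preset_monomodal_near_172(self):
        trace, rec = synth.make_dls_dataset("pellet", seed=0)
        res = dls.cumulant_fit(trace)
        assert res.hydrodynamic_diameter == pytest.approx(172.0, rel=0.05)
        assert rec.parameters["pdi_target"] == 1.18

    def test_single_size_zero_noise_single_exponential(self):
        trace, _ = synth.make_dls_dataset([100.0], seed=0)
        D = dls.diffusion_from_diameter(100.0)
        q = trace.scattering_vector_q
        expected = 1.0 + np.exp(-2 * D * q**2 * trace.lags)
        assert np.allclose(trace.g2, expected, rtol=1e-12)

    def test_seeded_determinism(self):
        t1, r1 = synth.make_dls_dataset("pellet", noise_sigma=0.01, seed=9)
        t2, r2 = synth.make_dls_dataset("pellet", noise_sigma=0.01, seed=9)
        assert r1.content_hash == r2.content_hash
        assert np.array_equal(t1.g2, t2.g2)


class TestZetaGenerator:
    def test_pellet_preset_statistics(self):
        true_z, sigma, n = synth.zeta_preset("pellet")
        means = []
        for seed in range(200):
            values, _ = synth.make_zeta_replicates(true_z, sigma, n, seed=seed)
            means.append(values.mean())
        # mean of replicate means ~ true value within 3/sqrt(5*200)
        assert abs(np.mean(means) - true_z) < 3 * sigma / np.sqrt(n * 200) * 3

    def test_zero_sigma_returns_truth(self):
        values, _ = synth.make_zeta_replicates(44.0, 0.0, 5, seed=0)
        assert np.allclose(values, 44.0)

    def test_seeded_determinism(self):
        a, ra = synth.make_zeta_replicates(0.0, 3.0, 5, seed=4)
        b, rb = synth.make_zeta_replicates(0.0, 3.0, 5, seed=4)
        assert np.array_equal(a, b)
        assert ra.content_hash == rb.content_hash


class TestRecipeFixture:
    def test_fixture_reproduces_shell_report(self, tmp_path):
        path = tmp_path / "recipe.yaml"
        synth.make_recipe_fixture(path)
        data = read_recipe(path)
        rep = recipe_report(
            data["lines"],
            payload_monomer_umol=data["payload_monomer_umol"],
            counterion_umol=data["counterion_umol"],
            payload_nmol=data["payload_nmol"],
            final_volume_uL=data["final_volume_uL"],
            target_percent=data["target_percent"],
        )
        assert rep.report_percent == (60, 30, 1, 9)
        assert rep.warnings == ()

    def test_fixture_hash_stable(self, tmp_path):
        _, r1 = synth.make_recipe_fixture()
        _, r2 = synth.make_recipe_fixture(tmp_path / "r.yaml")
        assert r1.content_hash == r2.content_hash

    def test_fixture_round_trips_through_reader(self, tmp_path):
        path = tmp_path / "recipe.yaml"
        text, _ = synth.make_recipe_fixture(path)
        data = read_recipe(path)
        assert {line.reagent.name for line in data["lines"]} == {
            "POPC", "Chol", "DSPE-PEG", "DSPE-PEG-MAN"
        }
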