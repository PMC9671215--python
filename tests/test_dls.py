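"""DLS: scattering geometry, correlogram synthesis, cumulant analysis."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from lipoplex import dls
from lipoplex import synth
from lipoplex.physchem import SolventMedium, WATER


class TestScatteringVector:
    def test_standard_geometry(self):
        q = dls.scattering_vector(633, 1.33, 90)
        assert q == pytest.approx(1.87e7, rel=0.005)

    def test_small_angle_limit(self):
        q_ref = dls.scattering_vector(633, 1.33, 90)
        assert dls.scattering_vector(633, 1.33, 1e-4) < 1e-5 * q_ref

    def test_wavelength_proportionality(self):
        assert dls.scattering_vector(633, 1.33, 90) == pytest.approx(
            2 * dls.scattering_vector(1266, 1.33, 90), rel=1e-12
        )

    @pytest.mark.parametrize("angle", [0, 180, -10, 200])
    def test_out_of_range_angle(self, angle):
        with pytest.raises(ValueError):
            dls.scattering_vector(633, 1.33, angle)


class TestStokesEinstein:
    def test_172_nm_sphere_diffusivity(self):
        d = dls.diffusion_from_diameter(172.0, WATER)
        assert d == pytest.approx(2.85e-12, rel=0.005)

    def test_round_trip_identity(self):
        d = dls.diffusion_from_diameter(93.7, WATER)
        assert dls.hydrodynamic_size(d, WATER) == pytest.approx(93.7, rel=1e-12)

    def test_viscosity_scaling(self):
        thin = SolventMedium(80.0, viscosity=0.445e-3)
        assert dls.diffusion_from_diameter(172.0, thin) == pytest.approx(
            2 * dls.diffusion_from_diameter(172.0, WATER), rel=1e-12
        )

    def test_missing_viscosity_errors(self):
        with pytest.raises(ValueError):
            dls.diffusion_from_diameter(100.0, SolventMedium(80.0))


class TestSimulateG2:
    q = dls.scattering_vector()

    def test_monodisperse_closed_form(self):
        dist = dls.SizeDistribution.from_diameters([172.0])
        lags = np.geomspace(1e-6, 1e-2, 100)
        trace = dls.simulate_g2(dist, self.q, lags, beta=0.8)
        D = dist.diffusion_coefficients[0]
        expected = 1.0 + 0.8 * np.exp(-2 * D * self.q**2 * lags)
        assert np.allclose(trace.g2, expected, rtol=1e-12)

    def test_initial_slope_is_weighted_mean(self):
        dist = dls.SizeDistribution.from_diameters([100.0, 300.0], weights=[0.7, 0.3])
        mu1, _ = dist.moments(self.q)
        lags = np.array([1e-9, 2e-9])
        trace = dls.simulate_g2(dist, self.q, lags, beta=1.0)
        slope = (np.log(trace.g2[1] - 1) - np.log(trace.g2[0] - 1)) / (lags[1] - lags[0])
        assert slope == pytest.approx(-2 * mu1, rel=1e-4)

    def test_seeded_determinism(self):
        dist = dls.SizeDistribution.from_diameters([172.0])
        lags = np.geomspace(1e-6, 1e-2, 50)
        a = dls.simulate_g2(dist, self.q, lags, noise_sigma=0.01, seed=7)
        b = dls.simulate_g2(dist, self.q, lags, noise_sigma=0.01, seed=7)
        c = dls.simulate_g2(dist, self.q, lags, noise_sigma=0.01, seed=8)
        assert np.array_equal(a.g2, b.g2)
        assert not np.array_equal(a.g2, c.g2)


class TestCumulantFit:
    def test_noise_free_monodisperse_recovery(self):
        trace, _ = synth.make_dls_dataset([172.0], seed=0)
        res = dls.cumulant_fit(trace)
        truth = dls.diffusion_from_diameter(172.0)
        assert res.mean_diffusion == pytest.approx(truth, rel=1e-3)
        assert res.hydrodynamic_diameter == pytest.approx(172.0, rel=1e-3)
        assert res.pdi == pytest.approx(1.0, abs=1e-6)

    def test_two_component_moments_at_high_snr(self):
        """Fitted cumulants match the generating distribution's moments.

        The cumulant moments are the early-decay expansion of ln(g2-1),
        so the moment comparison restricts the fit to the initial decay
        (window threshold 0.5) where the quadratic form is exact to
        higher-order terms; mu1 is additionally checked on the default
        window under noise at SNR 100.
        """
        dist = dls.SizeDistribution.from_diameters([150.0, 210.0], weights=[0.6, 0.4])
        q = dls.scattering_vector()
        mu1_true, mu2_true = dist.moments(q)
        gamma = dist.mean_diffusion() * q**2
        lags = np.geomspace(1e-4 / gamma, 3.0 / gamma, 400)
        trace = dls.simulate_g2(dist, q, lags, beta=1.0)
        res = dls.cumulant_fit(trace, fit_threshold=0.5)
        assert res.mu1 == pytest.approx(mu1_true, rel=0.02)
        assert res.mu2 == pytest.approx(mu2_true, rel=0.02)
        noisy = dls.simulate_g2(dist, q, lags, beta=1.0, noise_sigma=0.01, seed=11)
        assert dls.cumulant_fit(noisy).mu1 == pytest.approx(mu1_true, rel=0.02)

    def test_agrees_with_brute_force_nonlinear_fit(self):
        """The closed-form weighted solve must coincide with a generic optimizer."""
        dist = dls.SizeDistribution.from_diameters([150.0, 210.0], weights=[0.6, 0.4])
        q = dls.scattering_vector()
        gamma = dist.mean_diffusion() * q**2
        lags = np.geomspace(1e-3 / gamma, 3.0 / gamma, 200)
        trace = dls.simulate_g2(dist, q, lags, beta=0.9)
        res = dls.cumulant_fit(trace)

        y = trace.g2 - 1.0
        mask = y / y.max() > 0.05
        tau, yv = lags[mask], y[mask]
        w = yv**2

        def objective(p):
            ln_beta, mu1, mu2 = p
            pred = ln_beta - 2 * mu1 * tau + mu2 * tau**2
            return float(np.sum(w * (np.log(yv) - pred) ** 2))

        x0 = np.array([0.0, gamma * 0.5, 0.0])
        opt = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-14, "fatol": 1e-18, "maxiter": 20000})
        assert res.mu1 == pytest.approx(opt.x[1], rel=1e-3)
        assert math.exp(opt.x[0]) == pytest.approx(res.beta, rel=1e-3)

    def test_pellet_preset_diameter_recovery_over_seeds(self):
        """Monodisperse pellet-size preset: diameter within 2% over 50 seeds."""
        diams = []
        for seed in range(50):
            trace, _ = synth.make_dls_dataset([172.0], noise_sigma=0.01, seed=seed)
            diams.append(dls.cumulant_fit(trace).hydrodynamic_diameter)
        errs = np.abs(np.array(diams) - 172.0) / 172.0
        assert np.median(errs) < 0.02
        assert abs(np.mean(diams) - 172.0) / 172.0 < 0.02
        assert errs.max() < 0.05

    def test_pdi_floor_and_clamp(self):
        trace, _ = synth.make_dls_dataset([172.0], noise_sigma=0.005, seed=3)
        res = dls.cumulant_fit(trace)
        assert res.pdi >= 1.0

    def test_no_signal_errors(self):
        lags = np.geomspace(1e-6, 1e-2, 50)
        trace = dls.CorrelogramTrace(lags=lags, g2=np.ones_like(lags),
                                     scattering_vector_q=dls.scattering_vector())
        with pytest.raises(ValueError):
            dls.cumulant_fit(trace)

    def test_lognormal_recovery_and_pdi_monotone_in_width(self):
        """CV 0.1-0.3 log-normals: sizes within 5%, PDI increasing with width."""
        rng_seeds = range(50)
        mean_pdis = []
        for cv in (0.10, 0.20, 0.30):
            pdi_target = 1.0 + cv**2
            sizes, pdis = [], []
            for seed in rng_seeds:
                trace, _ = synth.make_dls_dataset(
                    [172.0], pdi=pdi_target, noise_sigma=0.02, seed=seed
                )
                res = dls.cumulant_fit(trace)
                sizes.append(res.hydrodynamic_diameter)
                pdis.append(res.pdi)
            assert abs(np.mean(sizes) - 172.0) / 172.0 < 0.05
            mean_pdis.append(np.mean(pdis))
        assert mean_pdis[0] < mean_pdis[1] < mean_pdis[2]
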