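"""Unit tests of the rate-inference building blocks."""

import numpy as np
import pytest
from dataclasses import replace

from riboflux.detection import SCENARIOS
from riboflux.inference import (
    InferenceConfig,
    correct_error_sites,
    detect_error_sites,
    fit_initiation,
    mean_observed_speed,
    naive_rates,
    normalize_rates,
)
from riboflux.tasep import GeneModel, SimConfig, simulate


@pytest.fixture
def cfg():
    return InferenceConfig(sim=SimConfig(seed=1, n_samples=8000,
                                         sample_interval=30))


class TestNaiveRates:
    def test_uniform_counts_give_uniform_rates(self, cfg):
        lam = naive_rates(np.full(20, 50), cfg)
        np.testing.assert_allclose(lam, 10.0)

    def test_inverse_proportionality(self, cfg):
        lam = naive_rates(np.array([10, 20]), cfg)
        assert lam[0] / lam[1] == pytest.approx(2.0)
        assert lam.mean() == pytest.approx(10.0)

    def test_zero_count_site_capped(self, cfg):
        lam = naive_rates(np.array([10, 0, 10]), cfg)
        assert lam[1] == cfg.lambda_max

    def test_all_zero_rejected(self, cfg):
        with pytest.raises(ValueError):
            naive_rates(np.zeros(5), cfg)

    def test_interference_free_inversion_is_exact(self, cfg):
        """At low initiation, occupancy is proportional to 1/lambda, so
        inverting the exact stationary profile recovers the rates."""
        from riboflux.tasep import exact_steady_state

        rng = np.random.default_rng(0)
        lam_true = rng.uniform(4, 14, 8)
        m = GeneModel("g", ("NNN",) * 8, alpha=1e-4, lambdas=lam_true,
                      footprint=2)
        occ, _ = exact_steady_state(m)
        est = naive_rates(occ[1:] * 1e9, cfg)  # observable positions
        r = np.corrcoef(est, lam_true[1:])[0, 1]
        assert r > 0.9999
        np.testing.assert_allclose(
            est / est.mean() * np.mean(lam_true[1:]),
            lam_true[1:], rtol=2e-3,
        )


class TestFitInitiation:
    def test_zero_target_returns_lower_bound(self, cfg):
        m = GeneModel("g", ("NNN",) * 60, alpha=1.0,
                      lambdas=np.full(60, 10.0))
        alpha, ok = fit_initiation(m, 0.0, SCENARIOS["none"], cfg)
        assert ok
        assert alpha == cfg.alpha_bracket[0]

    def test_bracketing_contract(self, cfg):
        from riboflux.inference import _detected_density_per100

        m = GeneModel("g", ("NNN",) * 100, alpha=1.0,
                      lambdas=np.full(100, 10.0))
        target = 1.0  # per 100 codons
        alpha, ok = fit_initiation(m, target, SCENARIOS["none"], cfg)
        assert ok
        got = _detected_density_per100(
            replace(m, alpha=alpha), SCENARIOS["none"],
            replace(cfg.sim, n_samples=8000),
        )
        assert got == pytest.approx(target, rel=0.08)

    def test_unreachable_target_flagged(self, cfg):
        m = GeneModel("g", ("NNN",) * 60, alpha=1.0,
                      lambdas=np.full(60, 10.0))
        # under full censoring the detected density peaks well below 8/100
        alpha, ok = fit_initiation(m, 8.0, SCENARIOS["none"], cfg)
        assert not ok


class TestErrorSites:
    def test_identical_profiles_give_none(self, cfg):
        p = np.full(50, 20.0)
        assert detect_error_sites(p, p, cfg) == []

    def test_single_perturbed_site(self, cfg):
        p = np.full(50, 20.0)
        q = p.copy()
        q[24] = 60.0
        assert detect_error_sites(p, q, cfg) == [25]

    def test_length_mismatch_rejected(self, cfg):
        with pytest.raises(ValueError):
            detect_error_sites(np.ones(10), np.ones(11), cfg)

    def test_sites_sorted_5prime_to_3prime(self, cfg):
        p = np.full(50, 20.0)
        q = p.copy()
        q[40] = 80.0
        q[5] = 80.0
        assert detect_error_sites(p, q, cfg) == [6, 41]

    def test_min_position_filters_upstream(self, cfg):
        p = np.full(50, 20.0)
        q = p.copy()
        q[5] = 80.0
        assert detect_error_sites(p, q, cfg, min_position=7) == []


class TestCorrection:
    def test_no_error_sites_returns_model_unchanged(self, cfg):
        rng = np.random.default_rng(3)
        lam = rng.uniform(5, 15, 60)
        m = GeneModel("g", ("NNN",) * 60, alpha=0.05, lambdas=lam)
        s = simulate(m, cfg.sim)
        from riboflux.detection import expected_detected_profile

        prof = expected_detected_profile(
            s, SCENARIOS["none"], np.random.default_rng(cfg.sim.seed)
        )
        counts = (prof * 30_000).round()
        model2, diag = correct_error_sites(
            m, counts, SCENARIOS["none"], cfg
        )
        assert diag.n_error_sites == 0
        np.testing.assert_array_equal(model2.lambdas, m.lambdas)

    def test_planted_stall_is_repaired(self, cfg):
        """Start from rates missing a planted stall; the correction loop
        must localize it and reduce the profile error below threshold."""
        L = 60
        lam_true = np.full(L, 10.0)
        lam_true[34] = 1.0  # stall invisible to the starting model
        truth = GeneModel("g", ("NNN",) * L, alpha=0.3, lambdas=lam_true)
        s = simulate(truth, SimConfig(seed=7, n_samples=30_000,
                                      sample_interval=60))
        from riboflux.detection import expected_detected_profile

        exp_prof = (
            expected_detected_profile(
                s, SCENARIOS["none"], np.random.default_rng(0)
            )
            * 30_000
        ).round()
        start = GeneModel("g", ("NNN",) * L, alpha=0.3,
                          lambdas=np.full(L, 10.0))
        sites0 = detect_error_sites(
            _sim_profile(start, cfg), exp_prof, cfg
        )
        assert any(abs(s_ - 35) <= 1 for s_ in sites0)
        model2, diag = correct_error_sites(start, exp_prof,
                                           SCENARIOS["none"], cfg)
        assert diag.corrected_sites
        sites_after = detect_error_sites(
            _sim_profile(model2, cfg), exp_prof, cfg,
        )
        assert len(sites_after) < len(sites0)
        # the corrected model must have discovered a slowdown near 35
        assert model2.lambdas[32:37].min() < 5.0

    def test_impossible_peak_flagged_not_looped(self, cfg):
        """A density spike incompatible with queueing physics must leave
        an unresolved flag rather than loop forever."""
        L = 60
        exp = np.full(L, 10.0)
        exp[29] = 4000.0  # 87% of all reads on one codon
        m = GeneModel("g", ("NNN",) * L, alpha=0.5,
                      lambdas=np.full(L, 10.0))
        fast = replace(cfg, max_rounds=3, correction_maxiter=15)
        model2, diag = correct_error_sites(m, exp, SCENARIOS["none"], fast)
        assert diag.n_error_sites >= 1
        assert not diag.converged or diag.unresolved_sites


def _sim_profile(model, cfg):
    from riboflux.detection import expected_detected_profile

    s = simulate(model, cfg.sim)
    return expected_detected_profile(
        s, SCENARIOS["none"], np.random.default_rng(cfg.sim.seed)
    )


class TestNormalization:
    def test_scale_invariance_of_occupancy(self):
        rng = np.random.default_rng(11)
        lam = rng.uniform(5, 15, 80)
        m1 = GeneModel("g", ("NNN",) * 80, alpha=0.1, lambdas=lam)
        m2 = m1.scaled(2.0)
        c = SimConfig(seed=5, n_samples=10_000, sample_interval=40)
        s1, s2 = simulate(m1, c), simulate(m2, c)
        # doubling all rates halves time but leaves occupancies invariant
        np.testing.assert_allclose(
            s1.site_occupancy, s2.site_occupancy, atol=0.01
        )
        assert s2.flux == pytest.approx(2 * s1.flux, rel=0.1)
        ok = np.isfinite(s1.dwell_time)
        np.testing.assert_allclose(
            s1.dwell_time[ok], 2 * s2.dwell_time[ok], rtol=0.3
        )

    def test_calibrated_speed_hits_target(self, cfg):
        rng = np.random.default_rng(13)
        lam = rng.uniform(4, 14, 250)
        m = GeneModel("g", ("NNN",) * 250, alpha=0.02, lambdas=lam)
        m2, k = normalize_rates(m, cfg)
        s = simulate(m2, SimConfig(seed=99, n_samples=20_000,
                                   sample_interval=50))
        assert mean_observed_speed(s, cfg.speed_region_start) == (
            pytest.approx(cfg.target_speed, rel=0.02)
        )

    def test_short_gene_rejected(self, cfg):
        m = GeneModel("g", ("NNN",) * 100, alpha=0.1,
                      lambdas=np.full(100, 10.0))
        with pytest.raises(ValueError, match="shorter"):
            normalize_rates(m, cfg)

    def test_flux_scales_with_normalization(self, cfg):
        rng = np.random.default_rng(17)
        lam = rng.uniform(4, 14, 200)
        m = GeneModel("g", ("NNN",) * 200, alpha=0.05, lambdas=lam)
        m2, k = normalize_rates(m, cfg)
        c = SimConfig(seed=31, n_samples=10_000, sample_interval=40)
        f1 = simulate(m, c).flux
        f2 = simulate(m2, c).flux
        assert f2 == pytest.approx(k * f1, rel=0.1)
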