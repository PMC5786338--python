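"""Simulator against the exact master-equation oracle and its invariants."""

import numpy as np
import pytest

from riboflux.tasep import (
    GeneModel,
    SimConfig,
    exact_steady_state,
    observed_rates,
    read_gene_model,
    simulate,
    write_gene_model,
)


def occupancy_indicators(summary, position):
    """Per-snapshot indicator that an A-site sits at ``position``."""
    return (summary.snapshots == position).any(axis=1).astype(float)


class TestExactSteadyState:
    def test_single_site_orf_balance(self):
        # enter at rate alpha, leave at rate lam: occupancy alpha/(alpha+lam)
        m = GeneModel("g", ("ATG", "TAA"), alpha=1.0, lambdas=[1.0, 1.0],
                      footprint=1)
        occ, flux = exact_steady_state(m)
        assert occ[0] == 0.0  # A-site never sits on the start codon
        assert occ[1] == pytest.approx(0.5)
        assert flux == pytest.approx(0.5)

    def test_zero_initiation_empties_lattice(self):
        m = GeneModel("g", ("NNN",) * 5, alpha=1.0, lambdas=np.ones(5),
                      footprint=2)
        m = GeneModel("g", m.codons, alpha=1e-300, lambdas=m.lambdas,
                      footprint=2)
        occ, flux = exact_steady_state(m)
        assert np.all(occ < 1e-250)
        assert flux < 1e-250

    def test_against_independent_enumeration(self):
        # hand-rolled oracle: L=4, ell=1; a state is the set of occupied
        # A-site positions among {2, 3, 4}; transitions written out by hand
        alpha, lam = 0.7, np.array([1.3, 0.9, 1.1, 0.6])
        states = [(), (2,), (3,), (4,), (2, 3), (2, 4), (3, 4), (2, 3, 4)]
        idx = {s: i for i, s in enumerate(states)}
        Q = np.zeros((8, 8))

        def rate(src, dst, r):
            Q[idx[dst], idx[src]] += r
            Q[idx[src], idx[src]] -= r

        for s in states:
            if 2 not in s:
                rate(s, tuple(sorted(s + (2,))), alpha)
            if 2 in s and 3 not in s:
                rate(s, tuple(sorted(tuple(p for p in s if p != 2) + (3,))),
                     lam[1])
            if 3 in s and 4 not in s:
                rate(s, tuple(sorted(tuple(p for p in s if p != 3) + (4,))),
                     lam[2])
            if 4 in s:
                rate(s, tuple(p for p in s if p != 4), lam[3])
        A = Q.copy()
        A[0, :] = 1.0
        b = np.zeros(8)
        b[0] = 1.0
        pi = np.linalg.solve(A, b)
        occ_expected = np.zeros(4)
        for s, w in zip(states, pi):
            for p in s:
                occ_expected[p - 1] += w
        flux_expected = lam[3] * sum(
            w for s, w in zip(states, pi) if 4 in s
        )

        m = GeneModel("g", ("NNN",) * 4, alpha=alpha, lambdas=lam,
                      footprint=1)
        occ, flux = exact_steady_state(m)
        np.testing.assert_allclose(occ, occ_expected, rtol=1e-10)
        assert flux == pytest.approx(flux_expected, rel=1e-10)

    def test_state_guard(self):
        m = GeneModel("g", ("NNN",) * 400, alpha=0.1,
                      lambdas=np.ones(400), footprint=1)
        with pytest.raises(ValueError, match="exceeds"):
            exact_steady_state(m)


class TestSimulateAgainstOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_system_occupancies_and_flux(self, seed, se_estimator):
        rng = np.random.default_rng(100 + seed)
        L = int(rng.integers(4, 9))
        ell = int(rng.integers(1, 3))
        lam = rng.uniform(0.5, 2.5, L)
        alpha = float(rng.uniform(0.2, 1.5))
        m = GeneModel(f"g{seed}", ("NNN",) * L, alpha=alpha, lambdas=lam,
                      footprint=ell)
        occ, flux = exact_steady_state(m)
        s = simulate(m, SimConfig(seed=seed, n_samples=20_000,
                                  sample_interval=20))
        for i in range(1, L):
            se = se_estimator(occupancy_indicators(s, i + 1))
            assert abs(s.site_occupancy[i] - occ[i]) <= max(3 * se, 1e-3)
        assert s.flux == pytest.approx(flux, rel=0.1)

    def test_low_alpha_limit_density(self, uniform_model):
        # alpha << lambda: site occupancy ~ alpha / lambda_i
        s = simulate(
            uniform_model,
            SimConfig(seed=3, n_samples=40_000, sample_interval=50),
        )
        interior = s.site_occupancy[5:45]
        se = 1e-4 / np.sqrt(40_000 / 40)  # pooled Poisson-scale error
        assert abs(interior.mean() - 1e-4) < 3 * se

    def test_seed_determinism(self):
        m = GeneModel("g", ("NNN",) * 30, alpha=0.5, lambdas=np.ones(30) * 2,
                      footprint=5)
        cfg = SimConfig(seed=11, n_samples=2000, sample_interval=10)
        a = simulate(m, cfg)
        b = simulate(m, cfg)
        assert np.array_equal(a.snapshots, b.snapshots)
        assert a.flux == b.flux
        c = simulate(m, SimConfig(seed=12, n_samples=2000, sample_interval=10))
        assert not np.array_equal(a.snapshots, c.snapshots)

    def test_flux_conservation_at_stop(self):
        rng = np.random.default_rng(7)
        lam = rng.uniform(1.0, 3.0, 40)
        m = GeneModel("g", ("NNN",) * 40, alpha=0.8, lambdas=lam,
                      footprint=10)
        s = simulate(m, SimConfig(seed=5, n_samples=30_000,
                                  sample_interval=30))
        # stationarity: terminations/time == occupancy(L) * lambda_L
        assert s.flux == pytest.approx(
            s.site_occupancy[-1] * lam[-1], rel=0.1
        )

    def test_density_monotone_in_alpha(self):
        lam = np.full(60, 2.0)
        rhos = []
        for alpha in (0.05, 0.2, 0.8):
            m = GeneModel("g", ("NNN",) * 60, alpha=alpha, lambdas=lam)
            s = simulate(m, SimConfig(seed=9, n_samples=8000,
                                      sample_interval=30))
            rhos.append(s.rho_total)
        assert rhos[0] < rhos[1] < rhos[2]

    def test_dropoff_survival_profile(self):
        # alpha -> 0: P(reach position k) = (1 - r)^(k - 2)
        r = 0.02
        L = 80
        m = GeneModel("g", ("NNN",) * L, alpha=0.01, lambdas=np.ones(L))
        s = simulate(
            m,
            SimConfig(seed=21, n_samples=60_000, sample_interval=40,
                      dropoff_rate=r),
        )
        expected = (1 - r) ** (np.arange(2, L + 1) - 2)
        ratio = s.site_occupancy[1:] / s.site_occupancy[1]
        # compare decay over a coarse late window to damp noise
        assert ratio[50:70].mean() == pytest.approx(
            expected[50:70].mean(), rel=0.12
        )
        assert s.n_dropoffs > 0

    def test_default_config_matches_protocol(self):
        cfg = SimConfig()
        assert cfg.burn_in_steps == 10_000
        assert cfg.n_samples == 30_000


class TestObservedRates:
    def test_no_interference_observed_equals_unobstructed(self, uniform_model):
        s = simulate(
            uniform_model,
            SimConfig(seed=2, n_samples=30_000, sample_interval=50),
        )
        df = observed_rates(s)
        mid = df.iloc[10:40]
        assert np.nanmean(mid["observed_rate"]) == pytest.approx(1.0,
                                                                 rel=0.05)

    def test_queue_behind_slow_site_reduces_observed_rate(self):
        L = 40
        lam = np.full(L, 5.0)
        lam[29] = 0.2  # strong stall
        m = GeneModel("g", ("NNN",) * L, alpha=2.0, lambdas=lam, footprint=5)
        s = simulate(m, SimConfig(seed=4, n_samples=20_000,
                                  sample_interval=30))
        df = observed_rates(s)
        trailing = df.iloc[29 - 5]  # one footprint behind the stall
        assert trailing["observed_rate"] < 0.8 * trailing["unobstructed_rate"]
        assert trailing["gap"] > 0

    def test_unvisited_positions_are_missing_not_zero(self, uniform_model):
        s = simulate(uniform_model, SimConfig(seed=6, n_samples=200,
                                              sample_interval=5))
        df = observed_rates(s)
        assert df["observed_rate"].isna().iloc[0]  # position 1 never visited


class TestValidationAndIO:
    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            GeneModel("g", ("NNN",) * 3, alpha=1.0, lambdas=[1.0, 0.0, 1.0],
                      footprint=1)
        with pytest.raises(ValueError):
            GeneModel("g", ("NNN",) * 3, alpha=-1.0, lambdas=np.ones(3),
                      footprint=1)

    def test_rejects_zero_sample_interval(self):
        with pytest.raises(ValueError):
            SimConfig(sample_interval=0)

    def test_gene_model_roundtrip(self, tmp_path):
        m = GeneModel("YAL001C", ("ATG", "AAA", "TAA"), alpha=0.123,
                      lambdas=[8.0, 11.5, 3.0], footprint=2)
        path = tmp_path / "model.tsv"
        write_gene_model(m, path)
        back = read_gene_model(path)
        assert back.gene_id == m.gene_id
        assert back.codons == m.codons
        assert back.alpha == m.alpha
        assert back.footprint == m.footprint
        np.testing.assert_array_equal(back.lambdas, m.lambdas)
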