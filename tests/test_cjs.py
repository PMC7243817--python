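"""CJS likelihood exactness, MCMC recovery, and diagnostics."""

import math

import numpy as np
import pytest

import stopover as so
from stopover.cjs import (CJSConfig, HierarchicalCJSModel, _HistoryStats,
                          _loglik_stats, chi_vector, cjs_loglik, gelman_rubin,
                          stopover_from_phi)
from stopover.simulate import StopoverDetectParams, simulate_capture_histories

from conftest import all_continuation_histories, cjs_single_history_bruteforce


class TestLikelihood:
    def test_hand_computed_histories(self):
        assert math.exp(cjs_loglik(np.array([[1, 0, 1]]), 0.8, 0.5)) \
            == pytest.approx(0.16, abs=1e-12)
        assert math.exp(cjs_loglik(np.array([[1, 0, 0]]), 0.8, 0.5)) \
            == pytest.approx(0.44, abs=1e-12)

    def test_first_capture_at_last_occasion_contributes_zero(self):
        h = np.zeros((1, 5), dtype=int)
        h[0, 4] = 1
        assert cjs_loglik(h, 0.7, 0.3) == 0.0

    def test_chi_boundary_is_one(self):
        for k in (1, 3, 10):
            assert chi_vector(0.6, 0.4, k)[-1] == 1.0

    def test_chi_recursion_values(self):
        # chi_2 for k=3: (1-phi) + phi(1-p) * 1
        chi = chi_vector(0.8, 0.5, 3)
        assert chi[1] == pytest.approx(0.2 + 0.4 * 1.0)
        assert chi[0] == pytest.approx(0.2 + 0.4 * chi[1])

    @pytest.mark.parametrize("k,f", [(3, 0), (4, 1), (6, 0), (6, 4)])
    def test_normalization_over_continuation_histories(self, k, f):
        for phi in (0.2, 0.6, 0.9):
            for p in (0.1, 0.5, 0.9):
                total = sum(math.exp(cjs_loglik(h[None, :], phi, p))
                            for h in all_continuation_histories(k, f))
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_latent_departure_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            k = int(rng.integers(2, 11))
            f = int(rng.integers(0, k))
            h = np.zeros(k, dtype=int)
            h[f] = 1
            h[f + 1:] = rng.integers(0, 2, k - f - 1)
            phi, p = rng.uniform(0.05, 0.95, 2)
            brute = cjs_single_history_bruteforce(h, phi, p)
            assert math.exp(cjs_loglik(h[None, :], phi, p)) \
                == pytest.approx(brute, rel=1e-12)

    def test_additivity_over_individuals(self):
        rng = np.random.default_rng(3)
        m = (rng.uniform(size=(20, 8)) < 0.4).astype(np.uint8)
        m[:, 2] = 1
        total = cjs_loglik(m, 0.7, 0.3)
        parts = sum(cjs_loglik(m[i:i + 1], 0.7, 0.3) for i in range(20))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_rejects_empty_history_and_bad_params(self):
        with pytest.raises(ValueError, match="no detection"):
            cjs_loglik(np.zeros((1, 4), dtype=int), 0.5, 0.5)
        with pytest.raises(ValueError, match="strictly"):
            cjs_loglik(np.array([[1, 0]]), 1.0, 0.5)


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        c = np.vstack([np.linspace(0, 1, 500)] * 2)
        assert gelman_rubin(c) == pytest.approx(1.0, abs=0.01)

    def test_same_stationary_distribution(self):
        rng = np.random.default_rng(8)
        c = rng.normal(0, 1, size=(2, 10_000))
        assert gelman_rubin(c) < 1.01

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(9)
        c = np.vstack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert gelman_rubin(c) > 2.0

    def test_single_chain_error(self):
        with pytest.raises(ValueError, match="chains"):
            gelman_rubin(np.zeros((1, 100)))

    def test_agrees_with_arviz_identity_rhat(self):
        import arviz as az

        rng = np.random.default_rng(10)
        c = rng.normal(0, 1, size=(4, 2000)) + rng.normal(0, 0.05, size=(4, 1))
        mine = gelman_rubin(c)
        theirs = float(az.rhat(az.convert_to_dataset(c),
                               method="identity")["x"].values)
        assert mine == pytest.approx(theirs, rel=1e-10)


class TestStopoverTransform:
    def test_exact_values(self):
        assert stopover_from_phi(math.exp(-1.0)) == pytest.approx(1.0, rel=1e-12)
        assert stopover_from_phi(math.exp(-0.25)) == pytest.approx(4.0, rel=1e-12)
        assert stopover_from_phi(0.5) == pytest.approx(1.0 / math.log(2.0),
                                                       rel=1e-12)

    def test_monotone_in_phi(self):
        grid = np.linspace(0.01, 0.99, 99)
        s = stopover_from_phi(grid)
        assert np.all(np.diff(s) > 0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            stopover_from_phi(bad)


class TestConfig:
    def test_default_schedule_retains_a_third(self):
        cfg = CJSConfig()
        assert cfg.retained_per_chain == (30_000 - 10_000) // 3

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            CJSConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            CJSConfig(thin=0)
        with pytest.raises(ValueError):
            CJSConfig(rhat_threshold=0.9)


def _simulate_matrices(n_years, n_per_year, k, phi, p, seed, phi_sd=0.0):
    sd = StopoverDetectParams(phi_mean=phi, p_mean=p, phi_logit_sd=phi_sd)
    arrivals = [np.ones(n_per_year, dtype=int) for _ in range(n_years)]
    mats, truth = simulate_capture_histories(arrivals, sd, k=k, seed=seed)
    return mats, truth


@pytest.fixture(scope="module")
def fitted():
    mats, truth = _simulate_matrices(8, 300, 15, phi=0.6, p=0.4, seed=100)
    cfg = CJSConfig(chains=3, iterations=2500, burn_in=1000, thin=3)
    res = HierarchicalCJSModel(mats, cfg).fit(seed=101)
    return res, truth


class TestHierarchicalFit:
    def test_draw_counts_match_schedule(self, fitted):
        res, _ = fitted
        cfg = res.config
        c = res.chains("mu_phi")
        assert c.shape == (cfg.chains, cfg.retained_per_chain)

    def test_recovers_pooled_probabilities(self, fitted):
        from scipy.special import expit

        res, _ = fitted
        assert abs(res.posterior_mean("mu_phi", expit) - 0.6) < 0.05
        assert abs(res.posterior_mean("mu_p", expit) - 0.4) < 0.05

    def test_hypermeans_converged(self, fitted):
        res, _ = fitted
        rh = res.rhat()
        assert rh["mu_phi"] < 1.05 and rh["mu_p"] < 1.05

    def test_sigma_draws_respect_prior_support(self, fitted):
        res, _ = fitted
        for name in ("sigma_phi", "sigma_p"):
            d = res.flat(name)
            assert d.min() > 0.0 and d.max() < 5.0

    def test_annual_stopover_table(self, fitted):
        res, _ = fitted
        tab = res.annual_stopover()
        assert len(tab) == 8
        assert (tab["S_median"] > 0).all()
        assert (tab["lo"] <= tab["S_median"]).all()
        assert (tab["S_median"] <= tab["hi"]).all()
        # truth: discrete mean stay 1/(1-phi) = 2.5; continuous transform
        # -1/ln(0.6) ~ 1.96 — medians should sit near the transform of phi
        assert abs(tab["S_median"].median() - stopover_from_phi(0.6)) < 0.35

    def test_ess_reported_positive(self, fitted):
        res, _ = fitted
        es = res.ess()
        assert all(v > 0 for v in es.values())

    def test_seeded_fit_reproducible(self):
        mats, _ = _simulate_matrices(4, 80, 10, phi=0.6, p=0.4, seed=55)
        cfg = CJSConfig(chains=2, iterations=600, burn_in=200, thin=2)
        a = HierarchicalCJSModel(mats, cfg).fit(seed=7)
        b = HierarchicalCJSModel(mats, cfg).fit(seed=7)
        np.testing.assert_array_equal(a.chains("mu_phi"), b.chains("mu_phi"))
        np.testing.assert_array_equal(a.draws["logit_phi"], b.draws["logit_phi"])

    def test_no_year_effect_sigma_concentrates_near_zero(self):
        mats, _ = _simulate_matrices(10, 400, 15, phi=0.6, p=0.4, seed=200,
                                     phi_sd=0.0)
        cfg = CJSConfig(chains=2, iterations=2000, burn_in=800, thin=2)
        res = HierarchicalCJSModel(mats, cfg).fit(seed=201)
        assert np.median(res.flat("sigma_phi")) < 0.15

    def test_needs_two_years(self):
        mats, _ = _simulate_matrices(1, 50, 10, phi=0.6, p=0.4, seed=1)
        with pytest.raises(ValueError, match=">= 2 years"):
            HierarchicalCJSModel(mats)

    def test_empty_year_drawn_from_hyperdistribution(self):
        mats, _ = _simulate_matrices(4, 120, 12, phi=0.6, p=0.4, seed=300)
        years = sorted(mats)
        empty = so.CaptureHistoryMatrix("SYN", "spring", 1999, [],
                                        np.zeros((0, 12), dtype=np.uint8))
        mats[1999] = empty
        cfg = CJSConfig(chains=2, iterations=800, burn_in=300, thin=2)
        res = HierarchicalCJSModel(mats, cfg).fit(seed=301)
        d = res.phi_draws(1999)
        assert np.isfinite(d).all() and (0 < d).all() and (d < 1).all()
        # prior-driven year should have wider spread than a data-rich year
        assert d.std() > res.phi_draws(years[0]).std()


class TestShrinkage:
    def test_sparse_year_estimate_between_mle_and_pooled(self):
        from scipy.optimize import minimize_scalar
        from scipy.special import expit

        rng_seed = 400
        mats, _ = _simulate_matrices(6, 400, 15, phi=0.6, p=0.4, seed=rng_seed)
        # thin one year down to 12 individuals
        sparse_year = sorted(mats)[2]
        m = mats[sparse_year]
        mats[sparse_year] = so.CaptureHistoryMatrix(
            m.species, m.season, m.year, m.band_ids[:12], m.matrix[:12])
        cfg = CJSConfig(chains=2, iterations=2500, burn_in=1000, thin=3)
        res = HierarchicalCJSModel(mats, cfg).fit(seed=401)

        pooled = res.posterior_mean("mu_phi", expit)
        post = float(np.median(res.phi_draws(sparse_year)))
        # year-only MLE of phi at the pooled p estimate
        stats = _HistoryStats.from_matrix(mats[sparse_year].matrix)
        p_hat = res.posterior_mean("mu_p", expit)
        opt = minimize_scalar(lambda v: -_loglik_stats(stats, expit(v), p_hat),
                              bounds=(-4, 4), method="bounded")
        mle = float(expit(opt.x))
        lo, hi = sorted((pooled, mle))
        assert lo - 0.02 <= post <= hi + 0.02, (mle, post, pooled)
        # and the posterior is pulled toward the pooled mean
        assert abs(post - pooled) <= abs(mle - pooled) + 0.02


class TestCoverage:
    def test_hypermean_interval_coverage_across_replicates(self):
        # scaled-down replication study: 20 simulated datasets, nominal
        # 95% central intervals for inv-logit(mu_phi) should cover truth
        # at a rate consistent with binomial variation
        from scipy.special import expit

        cfg = CJSConfig(chains=2, iterations=1200, burn_in=500, thin=2)
        hits = 0
        reps = 20
        for rep in range(reps):
            mats, _ = _simulate_matrices(5, 120, 12, phi=0.6, p=0.4,
                                         seed=500 + rep, phi_sd=0.15)
            res = HierarchicalCJSModel(mats, cfg).fit(seed=600 + rep)
            lo, hi = np.quantile(expit(res.flat("mu_phi")), [0.025, 0.975])
            if lo <= 0.6 <= hi:
                hits += 1
        assert hits >= 16, f"covered truth in only {hits}/{reps} replicates"


class TestMedianCommutation:
    def test_median_of_transform_equals_transform_of_median(self):
        rng = np.random.default_rng(77)
        draws = rng.uniform(0.2, 0.9, 1001)  # odd count: medians are draws
        a = float(np.median(stopover_from_phi(draws)))
        b = stopover_from_phi(float(np.median(draws)))
        assert a == pytest.approx(b, rel=1e-12)

    def test_degenerate_draws_zero_width(self):
        draws = np.full(100, math.exp(-1.0))
        s = stopover_from_phi(draws)
        assert float(np.median(s)) == pytest.approx(1.0, rel=1e-12)
        lo, hi = np.quantile(s, [0.025, 0.975])
        assert hi - lo == pytest.approx(0.0, abs=1e-12)
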