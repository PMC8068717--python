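"""BYM model: ICAR primitives, conjugate updates, sampler correctness."""

import numpy as np
import pytest
import scipy.integrate
import scipy.stats

from smrmap.graph import AreaGraph
from smrmap.model import (
    BYMModel,
    BYMSpec,
    MCMCConfig,
    icar_precision,
    icar_quadratic,
    sample_tau,
)

from conftest import random_graph


class TestIcarQuadratic:
    def test_constant_field_is_null(self, path3):
        assert icar_quadratic(np.full(3, 2.7), path3) == 0.0

    def test_path_graph_hand_enumeration(self, path3):
        # (0-1)^2 + (1-3)^2 = 1 + 4
        assert icar_quadratic(np.array([0.0, 1.0, 3.0]), path3) == 5.0

    def test_no_edges_gives_zero(self):
        g = AreaGraph.from_edges(["a", "b"], [])
        assert icar_quadratic(np.array([4.0, -2.0]), g) == 0.0

    def test_matches_bruteforce_on_random_graphs(self):
        """Exact agreement with direct pairwise enumeration, n <= 50."""
        rng = np.random.default_rng(3)
        for n in (5, 20, 50):
            g = random_graph(rng, n, 0.2)
            u = rng.standard_normal(n)
            idx = g.index
            brute = sum(
                (u[idx[a]] - u[idx[b]]) ** 2 for a, b in g.edges()
            )
            assert icar_quadratic(u, g) == pytest.approx(brute, rel=1e-12)

    def test_equals_quadratic_form_with_precision_matrix(self):
        rng = np.random.default_rng(9)
        g = random_graph(rng, 30, 0.15)
        u = rng.standard_normal(30)
        q = icar_precision(g).toarray()
        assert icar_quadratic(u, g) == pytest.approx(u @ q @ u, rel=1e-10)


class TestIcarPrecision:
    def test_path_graph_hand_construction(self, path3):
        np.testing.assert_array_equal(
            icar_precision(path3).toarray(),
            [[1, -1, 0], [-1, 2, -1], [0, -1, 1]],
        )

    def test_rows_sum_to_zero(self, lattice20):
        q = icar_precision(lattice20)
        assert np.abs(np.asarray(q.sum(axis=1))).max() < 1e-12

    def test_rank_deficiency_equals_component_count(self):
        g = AreaGraph.from_edges(
            list("abcdefg"),
            [("a", "b"), ("b", "c"), ("d", "e"), ("e", "f"), ("f", "g")],
        )
        lam = np.linalg.eigvalsh(icar_precision(g).toarray())
        assert (np.abs(lam) < 1e-10).sum() == g.n_components == 2


class TestSampleTau:
    def test_conjugacy_hand_algebra(self):
        """u=(0,1,3,3) on a path: S=5, posterior Gamma(2.5, 2.50005)."""
        g = AreaGraph.from_edges(
            ["1", "2", "3", "4"], [("1", "2"), ("2", "3"), ("3", "4")]
        )
        u = np.array([0.0, 1.0, 3.0, 3.0])
        assert icar_quadratic(u, g) == 5.0
        draws = np.array(
            [
                sample_tau(u, g, (1.0, 5e-5), np.random.default_rng(s))
                for s in range(20_000)
            ]
        )
        shape, rate = 2.5, 5e-5 + 2.5
        se = np.sqrt(shape / rate**2 / draws.size)
        assert abs(draws.mean() - shape / rate) < 3 * se

    def test_zero_field_posterior_is_prior_shape_shifted(self):
        g = AreaGraph.from_edges(["1", "2"], [("1", "2")])
        rng = np.random.default_rng(0)
        draws = np.array([sample_tau(np.zeros(2), g, (1.0, 2.0), rng) for _ in range(30_000)])
        # Gamma(a + (n-c)/2, b) = Gamma(1.5, 2)
        assert abs(draws.mean() - 1.5 / 2.0) < 3 * np.sqrt(1.5 / 4.0 / draws.size)

    def test_gibbs_update_distribution_ks(self):
        """Kolmogorov-Smirnov vs the analytic Gamma full conditional."""
        rng = np.random.default_rng(12)
        v = rng.standard_normal(50) * 0.3
        s = np.sum(v**2)
        draws = np.array([sample_tau(v, None, (1.0, 5e-5), rng) for _ in range(100_000)])
        res = scipy.stats.kstest(
            draws, scipy.stats.gamma(a=1 + 25.0, scale=1.0 / (5e-5 + s / 2)).cdf
        )
        assert res.pvalue > 0.001


class TestLogPosterior:
    def _toy_model(self):
        g = AreaGraph.from_edges(["1", "2", "3"], [("1", "2"), ("2", "3")])
        return BYMModel(
            np.array([4.0, 6.0, 2.0]), np.array([5.0, 5.0, 5.0]), graph=g
        )

    def test_likelihood_monotone_in_observed_when_theta_above_one(self):
        g = AreaGraph.from_edges(["1", "2"], [("1", "2")])
        state = dict(alpha=0.5, u=np.zeros(2), v=np.zeros(2), tau_u=1.0, tau_v=1.0)
        lps = [
            BYMModel(np.array([o, 3.0]), np.array([2.0, 3.0]), graph=g).log_posterior(state)
            for o in (1.0, 2.0, 3.0, 4.0)
        ]
        assert np.all(np.diff(lps) > 0)

    def test_single_area_hand_expression(self):
        """Poisson-normal posterior for one area, v free, written by hand."""
        m = BYMModel(
            np.array([5.0]),
            np.array([10.0]),
            spec=BYMSpec(
                include_intercept=False, include_structured=False, fixed_tau_v=1.0
            ),
        )
        for v in (-1.0, 0.0, 0.7):
            got = m.log_posterior({"v": np.array([v]), "tau_v": 1.0})
            by_hand = 5 * v - 10 * np.exp(v) + 0.5 * np.log(1.0) - v**2 / 2
            assert got == pytest.approx(by_hand, rel=1e-12)

    def test_difference_matches_independent_bruteforce(self):
        """Second, straightforward implementation as an oracle."""
        m = self._toy_model()
        rng = np.random.default_rng(6)

        def brute(state):
            a, b = 1.0, 5e-5
            eta = state["alpha"] + state["u"] + state["v"]
            lp = 0.0
            for i in range(3):
                lp += m.observed[i] * eta[i] - m.expected[i] * np.exp(eta[i])
            s_u = (state["u"][0] - state["u"][1]) ** 2 + (
                state["u"][1] - state["u"][2]
            ) ** 2
            lp += (3 - 1) / 2 * np.log(state["tau_u"]) - state["tau_u"] * s_u / 2
            lp += (a - 1) * np.log(state["tau_u"]) - b * state["tau_u"]
            for i in range(3):
                lp += 0.5 * np.log(state["tau_v"]) - state["tau_v"] * state["v"][i] ** 2 / 2
            lp += (a - 1) * np.log(state["tau_v"]) - b * state["tau_v"]
            return lp

        s1 = dict(alpha=0.2, u=rng.standard_normal(3), v=rng.standard_normal(3),
                  tau_u=2.0, tau_v=3.0)
        s1["u"] -= s1["u"].mean()
        s2 = dict(alpha=-0.1, u=rng.standard_normal(3), v=rng.standard_normal(3),
                  tau_u=0.5, tau_v=1.5)
        s2["u"] -= s2["u"].mean()
        got = m.log_posterior(s1) - m.log_posterior(s2)
        want = brute(s1) - brute(s2)
        assert got == pytest.approx(want, rel=1e-10)

    def test_translation_invariance_within_component(self):
        """Shifting u by a constant, compensated in alpha, changes nothing."""
        m = self._toy_model()
        rng = np.random.default_rng(8)
        u = rng.standard_normal(3)
        s1 = dict(alpha=0.3, u=u, v=np.zeros(3), tau_u=2.0, tau_v=1.0)
        s2 = dict(alpha=0.3 - 0.9, u=u + 0.9, v=np.zeros(3), tau_u=2.0, tau_v=1.0)
        assert m.log_posterior(s1) == pytest.approx(m.log_posterior(s2), abs=1e-8)

    def test_non_finite_state_error(self):
        m = self._toy_model()
        with pytest.raises(ValueError, match="non-finite"):
            m.log_posterior(
                dict(alpha=np.nan, u=np.zeros(3), v=np.zeros(3), tau_u=1.0, tau_v=1.0)
            )


class TestMCMC:
    def test_single_area_posterior_mean_matches_quadrature(self):
        """Poisson-lognormal toy: MCMC vs adaptive quadrature within 3 SE."""
        m = BYMModel(
            np.array([5.0]),
            np.array([10.0]),
            spec=BYMSpec(
                include_intercept=False, include_structured=False, fixed_tau_v=1.0
            ),
        )
        res = m.fit(MCMCConfig(seed=4, chains=2, iterations=18_000, burn_in=2000))
        theta = np.exp(res.draws.stacked("v")[:, 0])

        def post(v):
            return np.exp(5 * v - 10 * np.exp(v) - v**2 / 2)

        z, _ = scipy.integrate.quad(post, -10, 5)
        mean_oracle = (
            scipy.integrate.quad(lambda v: np.exp(v) * post(v), -10, 5)[0] / z
        )
        import arviz as az

        n_eff = float(
            np.asarray(
                az.ess(az.convert_to_dataset(np.exp(res.draws.v[:, :, 0])))[
                    "x"
                ].values
            ).item()
        )
        se = theta.std() / np.sqrt(n_eff)
        assert abs(theta.mean() - mean_oracle) < 3 * se

    def test_null_model_recovery_large_information(self):
        """With beta=0 and huge expected counts, all RR medians are ~1."""
        from smrmap.covariates import build_design
        from smrmap.simulate import make_lattice
        import pandas as pd

        g = make_lattice(10, 10)
        rng = np.random.default_rng(5)
        e = np.full(100, 5e4)
        o = rng.poisson(e).astype(float)
        dec = pd.Series(np.repeat(np.arange(1, 11), 10), index=list(g.area_ids))
        x, names = build_design(dec)
        m = BYMModel(o, e, x, names, g)
        res = m.fit(MCMCConfig(seed=2, chains=1, iterations=2000, burn_in=800))
        rr = res.rate_ratios()
        assert (np.abs(rr["rr"] - 1.0) < 0.05).all()

    def test_fixed_seed_reproducible(self, small_dataset):
        ds = small_dataset
        tot = ds.counts.groupby("area_id", sort=False)["count"].sum()
        e = tot.reindex(list(ds.graph.area_ids)).astype(float) + 1.0
        cfg = MCMCConfig(seed=11, chains=2, iterations=300, burn_in=100)
        m = BYMModel.from_tables(tot, e, ds.graph)
        d1, d2 = m.fit(cfg).draws, m.fit(cfg).draws
        np.testing.assert_array_equal(d1.alpha, d2.alpha)
        np.testing.assert_array_equal(d1.u, d2.u)
        np.testing.assert_array_equal(d1.tau_v, d2.tau_v)

    def test_u_draws_sum_to_zero_per_component(self, small_dataset):
        ds = small_dataset
        tot = ds.counts.groupby("area_id", sort=False)["count"].sum()
        e = tot.reindex(list(ds.graph.area_ids)).astype(float) + 1.0
        m = BYMModel.from_tables(tot, e, ds.graph)
        res = m.fit(MCMCConfig(seed=3, chains=1, iterations=400, burn_in=100))
        sums = res.draws.u.sum(axis=2)
        assert np.abs(sums).max() < 1e-10

    def test_zero_expected_area_rejected_with_graph(self, path3):
        with pytest.raises(ValueError, match="zero-expected"):
            BYMModel(
                np.array([1.0, 2.0, 0.0]), np.array([1.0, 2.0, 0.0]), graph=path3
            )

    def test_zero_expected_area_dropped_without_graph(self, caplog):
        with caplog.at_level("WARNING"):
            m = BYMModel(
                np.array([1.0, 2.0, 0.0]),
                np.array([1.0, 2.0, 0.0]),
                spec=BYMSpec(include_structured=False),
            )
        assert m.n == 2 and m.dropped_areas == ("2",)


@pytest.fixture(scope="module")
def fitted(small_dataset):
    ds = small_dataset
    from smrmap.covariates import build_design

    tot = ds.counts.groupby("area_id", sort=False)["count"].sum()
    e = tot.reindex(list(ds.graph.area_ids)).astype(float).clip(lower=0.5)
    x, names = build_design(ds.deciles)
    m = BYMModel.from_tables(tot, e, ds.graph, x, names)
    return m.fit(MCMCConfig(seed=9, chains=2, iterations=1200, burn_in=400))


class TestSummaries:

    def test_interval_orders_and_flags_consistent(self, fitted):
        rr = fitted.rate_ratios()
        assert (rr["ci_low"] <= rr["rr"]).all() and (rr["rr"] <= rr["ci_high"]).all()
        flag = (rr["ci_low"] > 1) | (rr["ci_high"] < 1)
        assert (rr["significant"] == flag).all()

    def test_flag_logic_on_synthetic_intervals(self):
        # interval straddling 1 -> no star; excluding 1 -> star
        assert not ((0.95 > 1) or (1.04 < 1))
        assert (1.02 > 1) or (1.12 < 1)

    def test_smoothed_and_residual_smr_positive(self, fitted):
        assert (fitted.smoothed_smr() > 0).all()
        assert (fitted.residual_smr() > 0).all()

    def test_summary_text(self, fitted):
        s = fitted.summary()
        assert "rate ratios" in s and "areas: 100" in s


class TestDiagnostics:
    def _results_from_draws(self, alpha):
        """Wrap raw draws in a results object for diagnostics only."""
        from smrmap.model import BYMResults, PosteriorDraws

        chains, n = alpha.shape
        draws = PosteriorDraws(
            alpha=alpha,
            beta=np.zeros((chains, n, 0)),
            u=np.zeros((chains, n, 1)),
            v=np.zeros((chains, n, 1)),
            tau_u=np.ones((chains, n)),
            tau_v=np.ones((chains, n)),
        )
        m = BYMModel(
            np.array([1.0]),
            np.array([1.0]),
            spec=BYMSpec(include_structured=False, fixed_tau_v=1.0),
        )
        m.spec = BYMSpec(
            include_structured=False, include_unstructured=False
        )
        return BYMResults(m, draws, MCMCConfig(seed=0, chains=chains, iterations=n + 1, burn_in=1))

    def test_iid_chains_rhat_near_one(self):
        rng = np.random.default_rng(1)
        res = self._results_from_draws(rng.standard_normal((2, 4000)))
        diag = res.diagnostics().set_index("parameter")
        assert abs(diag.loc["alpha", "rhat"] - 1.0) < 0.01

    def test_divergent_constant_chains_flagged(self):
        alpha = np.stack([np.zeros(500), np.ones(500)])
        alpha += np.random.default_rng(0).standard_normal((2, 500)) * 1e-3
        diag = self._results_from_draws(alpha).diagnostics().set_index("parameter")
        assert diag.loc["alpha", "rhat"] > 1.05
        assert not diag.loc["alpha", "converged"]

    def test_ar1_ess_matches_closed_form(self):
        """AR(1) with rho=0.5 has ESS = n(1-rho)/(1+rho) = n/3."""
        rng = np.random.default_rng(3)
        n, rho = 40_000, 0.5
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        diag = self._results_from_draws(x[None, :]).diagnostics().set_index("parameter")
        assert diag.loc["alpha", "ess"] == pytest.approx(n / 3, rel=0.2)
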