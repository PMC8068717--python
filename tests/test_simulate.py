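"""Synthetic data generator: graphs, fields, populations, counts."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from smrmap.covariates import assign_deciles, transform_covariates
from smrmap.model import icar_precision
from smrmap.simulate import (
    SyntheticConfig,
    make_lattice,
    simulate_counts,
    simulate_dataset,
    simulate_icar_field,
    simulate_population,
)


class TestMakeLattice:
    def test_2x2(self):
        g = make_lattice(2, 2)
        assert g.n_areas == 4 and len(g.edges()) == 4

    def test_20x20_edge_count_formula(self):
        # 2nm - n - m edges in an n x m 4-neighbour grid
        g = make_lattice(20, 20)
        assert g.n_areas == 400
        assert len(g.edges()) == 2 * 20 * 20 - 20 - 20 == 760

    def test_islands_bridged_into_single_component(self):
        g = make_lattice(5, 5, islands=2, island_size=3,
                         rng=np.random.default_rng(0))
        assert g.n_areas == 25 + 6
        assert g.n_components == 1

    def test_too_small_error(self):
        with pytest.raises(ValueError):
            make_lattice(1, 2)


class TestIcarField:
    def test_sum_zero_per_component(self):
        g = make_lattice(4, 4, islands=1, island_size=5,
                         rng=np.random.default_rng(1))
        u = simulate_icar_field(g, 5.0, np.random.default_rng(2))
        labels = np.asarray(g.component_labels)
        for c in set(labels):
            assert abs(u[labels == c].sum()) < 1e-10

    def test_covariance_matches_pseudoinverse_oracle(self):
        """Empirical covariance of many draws vs pinv(Q)/tau on a 3x3 grid."""
        g = make_lattice(3, 3)
        tau = 2.0
        rng = np.random.default_rng(3)
        draws = np.array([simulate_icar_field(g, tau, rng) for _ in range(10_000)])
        emp = np.cov(draws.T)
        oracle = np.linalg.pinv(icar_precision(g).toarray()) / tau
        scale = np.abs(oracle).max()
        assert np.abs(emp - oracle).max() < 0.10 * scale

    def test_high_precision_limit_shrinks_field(self):
        g = make_lattice(5, 5)
        rng = np.random.default_rng(4)
        small = simulate_icar_field(g, 1e8, rng)
        assert np.linalg.norm(small) < 1e-2

    def test_invalid_tau_error(self):
        with pytest.raises(ValueError):
            simulate_icar_field(make_lattice(2, 2), 0.0, np.random.default_rng(0))

    def test_large_component_sparse_path_matches_constraint(self):
        g = make_lattice(46, 46)  # 2116 areas -> CG route
        u = simulate_icar_field(g, 10.0, np.random.default_rng(5))
        assert abs(u.sum()) < 1e-8
        assert np.isfinite(u).all()


class TestPopulation:
    def test_density_spans_orders_of_magnitude(self):
        cfg = SyntheticConfig(seed=6)
        g = make_lattice(cfg.nrows, cfg.ncols)
        _, density = simulate_population(g, cfg, np.random.default_rng(6))
        assert density.max() / density.min() >= 1e3

    def test_decile_assignment_balanced_on_generated_density(self):
        cfg = SyntheticConfig(seed=7)
        g = make_lattice(cfg.nrows, cfg.ncols)
        _, density = simulate_population(g, cfg, np.random.default_rng(7))
        sizes = assign_deciles(density).value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_person_years_scale_with_population_parameter(self):
        g = make_lattice(5, 5)
        base = SyntheticConfig(seed=8, nrows=5, ncols=5)
        double = SyntheticConfig(seed=8, nrows=5, ncols=5,
                                 median_population=60000.0)
        p1, _ = simulate_population(g, base, np.random.default_rng(8))
        p2, _ = simulate_population(g, double, np.random.default_rng(8))
        ratio = p2["person_years"].sum() / p1["person_years"].sum()
        assert ratio == pytest.approx(2.0, rel=1e-9)


class TestCounts:
    def test_null_model_mean_ratio_one(self):
        rng = np.random.default_rng(9)
        n = 2000
        e = np.full(n, 50.0)
        from smrmap.simulate import SyntheticTruth

        truth = SyntheticTruth(
            alpha=0.0, beta={}, tau_u=1.0, tau_v=1.0,
            u=np.zeros(n), v=np.zeros(n), seed=0,
        )
        o = simulate_counts(truth, e, np.ones((n, 1)), ("intercept",), rng)
        assert (o / e).mean() == pytest.approx(1.0, abs=0.01)

    def test_rural_rate_ratio_recovered_empirically(self):
        rng = np.random.default_rng(10)
        n = 20_000
        e = np.full(n, 30.0)
        rural = (np.arange(n) % 2).astype(float)  # half the areas rural
        from smrmap.simulate import SyntheticTruth

        truth = SyntheticTruth(
            alpha=0.0, beta={"rural": np.log(2.0)}, tau_u=1, tau_v=1,
            u=np.zeros(n), v=np.zeros(n), seed=0,
        )
        o = simulate_counts(truth, e, rural[:, None], ("rural",), rng)
        ratio = o[rural == 1].mean() / o[rural == 0].mean()
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_zero_expected_zero_counts(self):
        from smrmap.simulate import SyntheticTruth

        truth = SyntheticTruth(
            alpha=0.0, beta={}, tau_u=1, tau_v=1,
            u=np.zeros(4), v=np.zeros(4), seed=0,
        )
        o = simulate_counts(
            truth, np.zeros(4), np.ones((4, 1)), ("intercept",),
            np.random.default_rng(0),
        )
        assert (o == 0).all()


class TestDataset:
    def test_determinism(self):
        d1 = simulate_dataset(SyntheticConfig(seed=11, nrows=6, ncols=6))
        d2 = simulate_dataset(SyntheticConfig(seed=11, nrows=6, ncols=6))
        pd.testing.assert_frame_equal(d1.counts, d2.counts)
        pd.testing.assert_frame_equal(d1.covariates, d2.covariates)
        np.testing.assert_array_equal(d1.truth.u, d2.truth.u)

    def test_different_seeds_differ(self):
        d1 = simulate_dataset(SyntheticConfig(seed=1, nrows=6, ncols=6))
        d2 = simulate_dataset(SyntheticConfig(seed=2, nrows=6, ncols=6))
        assert not d1.counts["count"].equals(d2.counts["count"])

    def test_skewed_covariates_symmetrized_by_log(self):
        """Generated skewed columns have |g1| < 0.5 after log + z-score."""
        cfg = SyntheticConfig(seed=12, nrows=32, ncols=32)
        ds = simulate_dataset(cfg)
        raw = ds.covariates.set_index("area_id")
        for col in ("single_person_hh_pct", "college_pct"):
            assert scipy.stats.skew(raw[col]) > 0.5  # right-skewed raw
        z = transform_covariates(
            raw[["single_person_hh_pct", "college_pct"]],
            {"single_person_hh_pct", "college_pct"},
        )
        for col in z.columns:
            assert abs(scipy.stats.skew(z[col])) < 0.5

    def test_truth_sidecar_roundtrip(self, tmp_path):
        ds = simulate_dataset(SyntheticConfig(seed=13, nrows=5, ncols=5))
        ds.truth.to_json(tmp_path / "truth.json")
        import json

        loaded = json.loads((tmp_path / "truth.json").read_text())
        assert loaded["alpha"] == ds.truth.alpha
        np.testing.assert_allclose(loaded["u"], ds.truth.u)
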