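import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bayesnma as bn
from bayesnma.reporting import (league_layout, rank_statistics,
                                regression_profile, relative_effects)


def degenerate_samples(values, n=100):
    """Constant posterior draws: (n, T) with a leading zero column."""
    v = np.array([0.0, *values])
    return np.tile(v, (n, 1))


class TestRelativeEffects:
    def test_transitivity_arithmetic_on_degenerate_samples(self):
        d = degenerate_samples([0.5, 1.2])
        table = relative_effects(d, ["A", "B", "C"], link="logit")
        assert table.cell("B", "C")[0] == pytest.approx(0.7)
        orig = relative_effects(d, ["A", "B", "C"], link="logit",
                                scale="original")
        assert orig.cell("B", "C")[0] == pytest.approx(np.exp(0.7))
        assert orig.cell("B", "B")[0] == pytest.approx(1.0)

    def test_linear_antisymmetry(self):
        rng = np.random.default_rng(0)
        d = np.column_stack([np.zeros(500), rng.normal(0.5, 0.2, 500),
                             rng.normal(-0.3, 0.4, 500)])
        t = relative_effects(d, ["A", "B", "C"], link="logit")
        assert np.allclose(t.estimate + t.estimate.T, 0.0, atol=1e-12)
        assert np.allclose(np.diag(t.estimate), 0.0)

    def test_meta_regression_cell_at_x0(self):
        d = degenerate_samples([0.5])
        beta = degenerate_samples([0.2])
        t = relative_effects(d, ["A", "B"], link="logit",
                             beta_samples=beta, x0=67.0, xbar=57.0)
        assert t.cell("A", "B")[0] == pytest.approx(2.5)

    def test_x0_without_covariate_rejected(self):
        d = degenerate_samples([0.5])
        with pytest.raises(ValueError, match="covariate"):
            relative_effects(d, ["A", "B"], link="logit", x0=67.0)

    def test_original_scale_equals_exp_of_linear_quantiles(self):
        rng = np.random.default_rng(1)
        d = np.column_stack([np.zeros(2000), rng.normal(0.4, 0.3, 2000)])
        lin = relative_effects(d, ["A", "B"], link="logit")
        orig = relative_effects(d, ["A", "B"], link="logit",
                                scale="original")
        assert orig.estimate[0, 1] == pytest.approx(
            np.exp(lin.estimate[0, 1]))
        assert orig.lower[0, 1] == pytest.approx(np.exp(lin.lower[0, 1]))
        assert orig.upper[0, 1] == pytest.approx(np.exp(lin.upper[0, 1]))
        # monotone consistency of the significance direction
        assert np.sign(lin.estimate[0, 1]) == np.sign(
            orig.estimate[0, 1] - 1.0)

    def test_identity_link_original_scale_unchanged(self):
        d = degenerate_samples([0.5])
        lin = relative_effects(d, ["A", "B"], link="identity")
        orig = relative_effects(d, ["A", "B"], link="identity",
                                scale="original")
        assert orig.estimate[0, 1] == lin.estimate[0, 1]

    def test_significance_flag_tracks_interval(self):
        rng = np.random.default_rng(2)
        d = np.column_stack([np.zeros(4000), rng.normal(2.0, 0.1, 4000),
                             rng.normal(0.0, 1.0, 4000)])
        t = relative_effects(d, ["A", "B", "C"], link="logit")
        assert t.significant[0, 1]
        assert not t.significant[0, 2]


class TestLeagueLayout:
    def test_given_order_is_identity(self):
        t = relative_effects(degenerate_samples([0.5, 1.0]),
                             ["A", "B", "C"], link="logit")
        layout = league_layout(t, order="given")
        assert layout["treatments"] == ["A", "B", "C"]

    def test_sucra_order_sorts_descending(self):
        d = degenerate_samples([0.5, 1.0])
        t = relative_effects(d, ["A", "B", "C"], link="logit")
        rr = rank_statistics(d, ["A", "B", "C"],
                             direction="largest-is-best")
        layout = league_layout(t, order="sucra", rank=rr)
        assert layout["treatments"] == ["C", "B", "A"]

    def test_heat_values_antisymmetric(self):
        rng = np.random.default_rng(3)
        d = np.column_stack([np.zeros(200), rng.normal(0.5, 0.2, 200)])
        t = relative_effects(d, ["A", "B"], link="logit")
        layout = league_layout(t)
        assert np.allclose(layout["heat"] + layout["heat"].T, 0, atol=1e-12)


class TestRankStatistics:
    def test_always_best_treatment_sucra_one(self):
        d = degenerate_samples([0.8])
        rr = rank_statistics(d, ["A", "B"], direction="largest-is-best")
        assert rr.sucra["B"] == pytest.approx(1.0)
        assert rr.sucra["A"] == pytest.approx(0.0)

    def test_uniform_ranks_give_half(self):
        # cycle through the 3 rotations so each treatment is uniform on ranks
        d = np.array([[0.0, 1.0, 2.0], [2.0, 0.0, 1.0], [1.0, 2.0, 0.0]])
        d = d - d[:, [0]]  # re-express vs the reference (rank-preserving)
        rr = rank_statistics(d, ["A", "B", "C"],
                             direction="largest-is-best")
        assert np.allclose(rr.sucra.to_numpy(), 0.5)

    def test_hand_enumerated_four_iterations(self):
        # ranks per iteration: (1,2),(1,2),(2,1),(1,2) for (t1, t2)
        d = np.array([[0.0, -1.0], [0.0, -1.0], [0.0, 1.0], [0.0, -1.0]])
        rr = rank_statistics(d, ["t1", "t2"], direction="largest-is-best")
        assert rr.prob.loc["t1", 1] == pytest.approx(0.75)
        assert rr.sucra["t1"] == pytest.approx(0.75)
        assert rr.sucra["t2"] == pytest.approx(0.25)

    def test_direction_must_be_explicit(self):
        with pytest.raises(ValueError, match="direction"):
            rank_statistics(degenerate_samples([0.5]), ["A", "B"],
                            direction="best")

    def test_smallest_is_best_reverses(self):
        d = degenerate_samples([0.8])
        rr = rank_statistics(d, ["A", "B"], direction="smallest-is-best")
        assert rr.sucra["A"] == pytest.approx(1.0)

    @given(st.integers(0, 10_000), st.integers(2, 6))
    @settings(max_examples=40, deadline=None)
    def test_column_stochastic_and_sucra_sum(self, seed, T):
        rng = np.random.default_rng(seed)
        d = np.column_stack([np.zeros(200),
                             rng.normal(0, 1, (200, T - 1))])
        rr = rank_statistics(d, [f"T{i}" for i in range(T)],
                             direction="largest-is-best")
        P = rr.prob.to_numpy()
        assert np.allclose(P.sum(axis=0), 1.0, atol=1e-12)  # per rank
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)  # per treatment
        assert rr.sucra.sum() == pytest.approx(T / 2, abs=1e-9)


class TestForestAndProfiles:
    def test_forest_rows_match_league_column(self, small_re_fit):
        _, _, res = small_re_fit
        table = res.relative_effects()
        rows = res.forest(comparator=res.treatments[0])
        for _, row in rows.iterrows():
            est, lo, hi = table.cell(res.treatments[0], row.treatment)
            assert row.estimate == pytest.approx(est)
            assert row.lower == pytest.approx(lo)

    def test_flat_profile_without_slope(self):
        d = degenerate_samples([0.5])
        beta = degenerate_samples([0.0])
        prof = regression_profile(d, beta, ["A", "B"], "A",
                                  x_grid=[40, 57, 80], xbar=57.0)
        assert np.allclose(prof["estimate"], 0.5)

    def test_profile_slope_and_intercept(self):
        d = degenerate_samples([0.5])
        beta = degenerate_samples([0.2])
        prof = regression_profile(d, beta, ["A", "B"], "A",
                                  x_grid=[57.0, 62.0], xbar=57.0)
        est = prof.set_index("x")["estimate"]
        assert est[57.0] == pytest.approx(0.5)
        assert (est[62.0] - est[57.0]) / 5.0 == pytest.approx(0.2)

    def test_lines_cross_where_algebra_says(self):
        # x* = xbar + (d_b - d_c)/(beta_c - beta_b) for degenerate draws
        d = degenerate_samples([0.5, 1.0])
        beta = degenerate_samples([0.3, 0.1])
        xbar = 57.0
        x_star = xbar + (1.0 - 0.5) / (0.3 - 0.1)
        prof = regression_profile(d, beta, ["A", "B", "C"], "A",
                                  x_grid=[x_star], xbar=xbar)
        vals = prof.set_index("treatment")["estimate"]
        assert vals["B"] == pytest.approx(vals["C"])
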