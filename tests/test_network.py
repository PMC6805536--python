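import numpy as np
import pytest

import bayesnma as bn
from conftest import make_disconnected_network, random_small_network


class TestConnectivity:
    def test_single_study_is_connected(self):
        nd = bn.prepare_network(
            [dict(study="S1", treatment="A", events=1, sample_size=10),
             dict(study="S1", treatment="B", events=2, sample_size=10)],
            "dichotomous")
        connected, comps = bn.connectivity(nd)
        assert connected and comps == [{"A", "B"}]

    def test_two_components(self):
        rows = []
        for s, pair in [("S1", "AB"), ("S2", "BC"), ("S3", "DE")]:
            for t in pair:
                rows.append(dict(study=s, treatment=t, events=1,
                                 sample_size=10))
        nd = bn.prepare_network(rows, "dichotomous")
        connected, comps = bn.connectivity(nd)
        assert not connected
        assert sorted(map(frozenset, comps)) in (
            [frozenset("ABC"), frozenset("DE")],
            [frozenset("DE"), frozenset("ABC")])
        assert {frozenset(c) for c in comps} == {frozenset("ABC"),
                                                 frozenset("DE")}

    def test_agrees_with_brute_force_reachability(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            nd = random_small_network(rng, T=6, M=5)
            connected, comps = bn.connectivity(nd)
            # oracle: transitive closure over co-occurrence adjacency
            T = nd.n_treatments
            adj = np.eye(T, dtype=bool)
            for s in nd.studies:
                idx = [nd.treatment_index(a.treatment)
                       for a in nd.study_arms(s)]
                for i in idx:
                    for j in idx:
                        adj[i, j] = True
            for k in range(T):
                adj |= adj[:, [k]] & adj[[k], :]
            oracle_comps = {frozenset(np.flatnonzero(row)) for row in adj}
            assert connected == (len(oracle_comps) == 1)
            got = {frozenset(nd.treatment_index(t) for t in c)
                   for c in comps}
            assert got == oracle_comps


class TestSummarizeNetwork:
    def test_disconnected_pair_counts(self):
        summ = bn.summarize_network(make_disconnected_network())
        assert summ.possible_pairwise == 6
        assert summ.direct_pairwise == 2
        assert not summ.connected

    def test_six_treatment_possible_pairs(self):
        cfg = bn.FixtureConfig(T=6, M=15, d=(0.0,) * 6, seed=3)
        nd, _ = bn.generate_synthetic_network(cfg)
        assert bn.summarize_network(nd).possible_pairwise == 15

    def test_toy_counts_by_hand(self, toy_network):
        summ = bn.summarize_network(toy_network)
        assert summ.n_interventions == 5
        assert summ.n_studies == 3
        assert summ.total_patients == 1081 + 2213 + 1102 + 416 + 424 + 5074 + 5087
        assert summ.total_events == 43 + 34 + 37 + 29 + 20 + 845 + 690
        assert summ.direct_pairwise == 4   # 3 MRC-E pairs + 1 VALUE pair
        assert summ.n_two_arm == 2 and summ.n_multi_arm == 1
        assert summ.n_studies_no_zero_events == 3
        assert summ.n_studies_any_zero_event == 0
        assert not summ.connected          # the excerpt has two components
        assert summ.mean_follow_up is None

    def test_continuous_network_has_no_event_fields(self):
        rows = [dict(study="S1", treatment="A", mean=1.0, std_err=0.1),
                dict(study="S1", treatment="B", mean=1.5, std_err=0.1)]
        summ = bn.summarize_network(bn.prepare_network(rows, "continuous"))
        assert summ.total_events is None
        assert summ.n_studies_any_zero_event is None

    def test_mean_follow_up_is_unweighted_study_mean(self):
        rows = []
        for s, f, n in [("S1", 2.0, 10), ("S2", 6.0, 1000)]:
            for t in "AB":
                rows.append(dict(study=s, treatment=t, events=1,
                                 sample_size=n, follow_up=f))
        summ = bn.summarize_network(bn.prepare_network(rows, "dichotomous"))
        assert summ.mean_follow_up == pytest.approx(4.0)

    def test_generator_planted_geometry(self):
        cfg = bn.FixtureConfig(T=4, M=20, d=(0, 0.2, 0.4, 0.6),
                               arms_per_study=2, seed=9)
        nd, _ = bn.generate_synthetic_network(cfg)
        summ = bn.summarize_network(nd)
        assert summ.n_studies == 20
        assert summ.n_two_arm == 20 and summ.n_multi_arm == 0
        assert summ.total_patients == 20 * 2 * cfg.n_per_arm


class TestComparisonMatrix:
    def test_three_arm_study_contributes_each_pair(self):
        rows = [dict(study="S1", treatment=t, events=1, sample_size=10)
                for t in "ABC"]
        cm = bn.comparison_matrix(bn.prepare_network(rows, "dichotomous"))
        off = cm.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off == 1).all()
        assert (np.diag(cm.to_numpy()) == 1).all()

    def test_repeated_pair_counts(self):
        rows = []
        for s in ("S1", "S2"):
            for t in "AB":
                rows.append(dict(study=s, treatment=t, events=1,
                                 sample_size=10))
        cm = bn.comparison_matrix(bn.prepare_network(rows, "dichotomous"))
        assert cm.loc["A", "B"] == 2
        assert cm.loc["A", "A"] == 2 and cm.loc["B", "B"] == 2

    def test_upper_triangle_sum_bounds_direct_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            nd = random_small_network(rng)
            cm = bn.comparison_matrix(nd).to_numpy()
            summ = bn.summarize_network(nd)
            total = int(np.triu(cm, k=1).sum())
            assert total >= summ.direct_pairwise
            if (np.triu(cm, k=1) <= 1).all():
                assert total == summ.direct_pairwise


class TestCovariateTable:
    def test_by_study_rows_and_grand_mean(self, toy_network):
        rows, grand = bn.covariate_table(toy_network, "age",
                                         group_by="study")
        assert len(rows) == 7
        mrce = rows[rows.study == "MRC-E"]
        assert sorted(mrce["mean"]) == [59.2, 60.2, 60.7]
        assert grand == pytest.approx(
            np.mean([60.7, 59.2, 60.2, 59.0, 57.0, 56.4, 57.8]))

    def test_unknown_covariate_raises(self, toy_network):
        with pytest.raises(ValueError, match="bmi"):
            bn.covariate_table(toy_network, "bmi")

    def test_equal_n_pooling_is_plain_mean(self):
        rows = [dict(study="S1", treatment="A", events=1, sample_size=100,
                     age=50.0),
                dict(study="S1", treatment="B", events=1, sample_size=100,
                     age=55.0),
                dict(study="S2", treatment="A", events=1, sample_size=100,
                     age=70.0),
                dict(study="S2", treatment="B", events=1, sample_size=100,
                     age=60.0)]
        nd = bn.prepare_network(rows, "dichotomous", covariate_cols=("age",))
        pooled, _ = bn.covariate_table(nd, "age", group_by="treatment")
        assert float(pooled[pooled.treatment == "A"]["mean"].iloc[0]) == 60.0

    def test_missing_spread_stays_missing(self, toy_network):
        rows, _ = bn.covariate_table(toy_network, "age", group_by="study")
        assert rows["spread"].notna().all()  # toy rows all report SDs
        # drop one SD and confirm it is carried as absent, not zero
        nd = bn.prepare_network(
            [dict(study="S1", treatment="A", events=1, sample_size=10,
                  age=50.0),
             dict(study="S1", treatment="B", events=1, sample_size=10,
                  age=55.0, age_sd=4.0)],
            "dichotomous", covariate_cols=("age", "age_sd"))
        rows, _ = bn.covariate_table(nd, "age", group_by="study")
        spread = rows.set_index("treatment")["spread"]
        assert np.isnan(spread["A"]) and spread["B"] == 4.0
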