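import numpy as np
import pandas as pd
import pytest

from netwalk import (
    DataVector,
    WalkConfig,
    build_ef_matrix,
    cluster_ef,
    coherence_report,
    expansion_transform,
    extract_subnetwork,
    robustness_experiment,
    run_netwalk,
)
from netwalk.flux import EdgeFluxTable


def small_ef_table(scores):
    rows = [(f"A{i}", f"B{i}", False, "PPI", 0.1, 0.1, s) for i, s in enumerate(scores)]
    df = pd.DataFrame(
        rows, columns=["source", "target", "directed", "itype", "e_fwd", "e_rev", "e"]
    )
    df["e_r"] = 0.1
    df["s"] = scores
    return EdgeFluxTable(table=df)


class TestExtractSubnetwork:
    def test_top_zero_is_empty(self):
        sub = extract_subnetwork(small_ef_table([1.0, 2.0]), "top_k", 0)
        assert len(sub) == 0 and sub.nodes == frozenset()

    def test_top_k_takes_highest_scores(self):
        sub = extract_subnetwork(small_ef_table([0.5, 2.0, -1.0, 1.5]), "top_k", 2)
        assert list(sub.edges["s"]) == [2.0, 1.5]

    def test_threshold_at_max_keeps_exactly_the_argmax(self):
        ef = small_ef_table([0.5, 2.0, -1.0])
        sub = extract_subnetwork(ef, "s_ge", 2.0)
        assert list(sub.edges["s"]) == [2.0]

    def test_oversized_k_returns_all_with_warning(self):
        ef = small_ef_table([1.0, 2.0])
        with pytest.warns(UserWarning, match="exceeds"):
            sub = extract_subnetwork(ef, "top_k", 10)
        assert len(sub) == 2

    def test_selection_is_stable_under_row_shuffling(self):
        ef = small_ef_table([0.5, 2.0, 2.0, -1.0, 1.5, 0.0])
        rng = np.random.default_rng(0)
        shuffled = EdgeFluxTable(
            table=ef.table.sample(frac=1.0, random_state=rng.integers(1000)).reset_index(
                drop=True
            )
        )
        a = extract_subnetwork(ef, "top_k", 3).edges
        b = extract_subnetwork(shuffled, "top_k", 3).edges
        pd.testing.assert_frame_equal(a, b)

    def test_tied_boundary_broken_lexicographically(self):
        ef = small_ef_table([1.0, 1.0, 1.0])
        sub = extract_subnetwork(ef, "top_k", 2)
        assert list(sub.edges["source"]) == ["A0", "A1"]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown extraction rule"):
            extract_subnetwork(small_ef_table([1.0]), "median_k", 1)


class TestCoherenceReport:
    def test_constant_values_have_zero_iqr(self):
        sub = extract_subnetwork(small_ef_table([1.0, 2.0]), "top_k", 2)
        w = DataVector("c", {g: 2.0 for g in sub.nodes})
        rep = coherence_report(sub, w)
        assert rep["median"] == 2.0 and rep["q3"] - rep["q1"] == 0.0
        assert rep["frac_above_1"] == 1.0

    def test_empty_subnetwork_gives_empty_report(self):
        sub = extract_subnetwork(small_ef_table([1.0]), "top_k", 0)
        assert coherence_report(sub, DataVector("c", {})) == {"n_nodes": 0}

    def test_single_edge_statistics_over_its_two_nodes(self):
        sub = extract_subnetwork(small_ef_table([5.0, 1.0]), "top_k", 1)
        w = DataVector("c", {"A0": 2.0, "B0": 4.0})
        rep = coherence_report(sub, w)
        assert rep["n_nodes"] == 2 and rep["median"] == 3.0

    def test_planted_fixture_extremes_are_coherent(self, small_planted):
        fx = small_planted
        _, ef = run_netwalk(fx.network, fx.single, WalkConfig())
        top = coherence_report(extract_subnetwork(ef, "top_k", 40), fx.single)
        bottom = coherence_report(extract_subnetwork(ef, "bottom_k", 40), fx.single)
        assert top["median"] > 1.0 > bottom["median"]


class TestEfMatrix:
    def test_single_condition_single_column(self):
        ef = small_ef_table([1.0, 2.0])
        efm = build_ef_matrix([("c1", ef)])
        assert efm.shape == (2, 1) and list(efm.columns) == ["c1"]

    def test_duplicated_condition_gives_identical_columns(self):
        ef = small_ef_table([1.0, 2.0, 3.0])
        efm = build_ef_matrix([("a", ef), ("b", ef)])
        assert (efm["a"] == efm["b"]).all()

    def test_columns_match_per_run_scores(self):
        efs = [small_ef_table([1.0, 2.0]), small_ef_table([0.5, -1.0])]
        efm = build_ef_matrix([("a", efs[0]), ("b", efs[1])])
        expected = np.column_stack([[1.0, 2.0], [0.5, -1.0]])
        assert np.array_equal(efm.to_numpy(), expected)

    def test_mismatched_edge_sets_rejected(self):
        with pytest.raises(ValueError, match="different edge set"):
            build_ef_matrix([("a", small_ef_table([1.0, 2.0])), ("b", small_ef_table([1.0]))])


class TestClusterEf:
    @staticmethod
    def two_block_matrix():
        idx = pd.MultiIndex.from_tuples(
            [(f"A{i}", f"B{i}", "PPI") for i in range(6)],
            names=["source", "target", "itype"],
        )
        data = np.array(
            [[3.0, 3.1, 0.0, 0.1]] * 3 + [[0.0, -0.1, 3.0, 2.9]] * 3
        )
        return pd.DataFrame(data, index=idx, columns=list("wxyz"))

    def test_two_block_matrix_splits_cleanly(self):
        efm = self.two_block_matrix()
        cl = cluster_ef(efm, k=3, n_clusters=2)
        labels = cl.labels.to_numpy()
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_row_permutation_only_relabels(self):
        efm = self.two_block_matrix()
        perm = efm.iloc[[3, 0, 4, 1, 5, 2]]
        a = cluster_ef(efm, k=3, n_clusters=2).labels
        b = cluster_ef(perm, k=3, n_clusters=2).labels
        joined = pd.concat([a.rename("a"), b.rename("b")], axis=1)
        # same partition: the label pairing is a bijection
        assert joined.groupby("a")["b"].nunique().max() == 1
        assert joined.groupby("b")["a"].nunique().max() == 1

    def test_degenerate_matrix_warns_single_cluster(self):
        idx = pd.MultiIndex.from_tuples(
            [(f"A{i}", f"B{i}", "PPI") for i in range(4)],
            names=["source", "target", "itype"],
        )
        efm = pd.DataFrame(np.ones((4, 3)), index=idx, columns=list("abc"))
        with pytest.warns(UserWarning, match="degenerate"):
            cl = cluster_ef(efm, k=2, n_clusters=2)
        assert set(cl.labels) == {1}

    def test_fewer_than_two_conditions_rejected(self):
        efm = self.two_block_matrix()[["w"]]
        with pytest.raises(ValueError, match="2 conditions"):
            cluster_ef(efm, k=2)


class TestRobustness:
    def test_zero_perturbation_has_perfect_correlation(self, small_planted):
        fx = small_planted
        table = robustness_experiment(
            fx.network, fx.single, WalkConfig(), "data_deletion", [0.0], n_reps=2, seed=0
        )
        assert (table["metric"] == 1.0).all()

    def test_expansion_factor_two_is_identity(self, small_planted):
        fx = small_planted
        table = robustness_experiment(
            fx.network, fx.single, WalkConfig(), "expansion_factor", [2.0],
            n_reps=1, seed=0, top_k=30,
        )
        assert (table["metric"] == 1.0).all()
        # and the transform itself reproduces the data
        t = expansion_transform(fx.single, 2.0)
        assert t.values == pytest.approx(fx.single.values)

    def test_heavier_data_deletion_degrades_agreement(self, small_planted):
        fx = small_planted
        table = robustness_experiment(
            fx.network, fx.single, WalkConfig(), "data_deletion", [0.0, 0.9],
            n_reps=3, seed=1,
        )
        means = table.groupby("level")["metric"].mean()
        assert means[0.0] == 1.0
        assert means[0.9] < means[0.0]

    def test_results_are_reproducible_for_a_seed(self, small_planted):
        fx = small_planted
        kw = dict(kind="edge_deletion", levels=[0.3], n_reps=2, seed=7)
        a = robustness_experiment(fx.network, fx.single, WalkConfig(), **kw)
        b = robustness_experiment(fx.network, fx.single, WalkConfig(), **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_level_rejected(self, small_planted):
        fx = small_planted
        with pytest.raises(ValueError, match="fraction"):
            robustness_experiment(
                fx.network, fx.single, WalkConfig(), "node_deletion", [1.7]
            )
        with pytest.raises(ValueError, match="expansion factor"):
            robustness_experiment(
                fx.network, fx.single, WalkConfig(), "expansion_factor", [0.5]
            )
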