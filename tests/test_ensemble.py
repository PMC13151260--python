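"""Bootstrap aggregation, bidirectional resolution, cycle repair, reporting."""

import numpy as np
import pytest

from gaitcausal.direct_lingam import fit_direct_lingam
from gaitcausal.ensemble import (EnsembleConfig, WeightedDigraph, aggregate,
                                 bootstrap_adjacencies, build_ensemble_graph,
                                 make_acyclic, resolve_bidirectional,
                                 select_outcome_parents, stability_report)
from gaitcausal.simulate import SEMSpec, simulate_sem


def graph(nodes, **edges):
    return WeightedDigraph(list(nodes),
                           {tuple(k.split("_to_")): v for k, v in edges.items()})


class TestBootstrap:
    def test_single_iteration_equals_thresholded_learner(self):
        X = np.random.default_rng(0).uniform(size=(40, 3))
        cfg = EnsembleConfig(n_boot=1, edge_threshold=0.05, seed=9)
        rng = np.random.default_rng(np.random.SeedSequence([9, 0]))
        idx = rng.integers(0, 40, 40)
        expected = fit_direct_lingam(X[idx])[1]
        expected[np.abs(expected) <= 0.05] = 0.0
        mats, failures = bootstrap_adjacencies(
            X, lambda Xb: fit_direct_lingam(Xb)[1], cfg)
        assert failures == 0
        assert np.allclose(mats[0], expected)

    def test_constant_learner_passthrough(self):
        M = np.array([[0.0, 0.3], [0.02, 0.0]])
        X = np.zeros((10, 2))
        cfg = EnsembleConfig(n_boot=5, edge_threshold=0.05, seed=0)
        mats, _ = bootstrap_adjacencies(X, lambda Xb: M, cfg)
        expected = np.array([[0.0, 0.3], [0.0, 0.0]])  # 0.02 thresholded away
        assert all(np.allclose(m, expected) for m in mats)

    def test_learner_failures_counted_and_skipped(self):
        calls = {"n": 0}

        def flaky(Xb):
            calls["n"] += 1
            if calls["n"] % 2 == 0:
                raise RuntimeError("boom")
            return np.zeros((2, 2))

        cfg = EnsembleConfig(n_boot=6, seed=1)
        mats, failures = bootstrap_adjacencies(np.zeros((5, 2)), flaky, cfg)
        assert failures == 3
        assert len(mats) == 3

    def test_true_edges_retained_on_sem_data(self):
        B = np.zeros((3, 3))
        B[1, 0] = 0.7
        B[2, 1] = 0.6
        X = simulate_sem(SEMSpec(["a", "b", "c"], B), 500, seed=12)
        cfg = EnsembleConfig(n_boot=200, seed=12)
        eg, _ = build_ensemble_graph(
            X, lambda Xb: fit_direct_lingam(Xb)[1], cfg, ["a", "b", "c"])
        assert eg.retention_freq[1, 0] > 0.9
        assert eg.retention_freq[2, 1] > 0.9
        assert eg.retention_freq[2, 0] < 0.2 or eg.mean_weight[2, 0] < 0.1
        # absent reverse edges
        assert eg.retention_freq[0, 1] < 0.2
        assert eg.retention_freq[0, 2] < 0.2


class TestAggregate:
    def test_two_iteration_arithmetic(self):
        m1 = np.array([[0.0, 0.2], [0.0, 0.0]])
        m2 = np.zeros((2, 2))
        eg = aggregate([m1, m2], EnsembleConfig(n_boot=2))
        assert eg.mean_weight[0, 1] == pytest.approx(0.1)
        assert eg.retention_freq[0, 1] == pytest.approx(0.5)
        assert eg.sign_stability[0, 1] == pytest.approx(0.5)

    def test_identical_matrices(self):
        m = np.array([[0.0, -0.4], [0.0, 0.0]])
        eg = aggregate([m, m, m], EnsembleConfig(n_boot=3))
        assert set(np.unique(eg.retention_freq)) <= {0.0, 1.0}
        assert np.allclose(eg.sign_stability, eg.retention_freq)

    def test_cancellation_drops_edge(self):
        m1 = np.array([[0.0, 0.2], [0.0, 0.0]])
        m2 = np.array([[0.0, -0.2], [0.0, 0.0]])
        cfg = EnsembleConfig(n_boot=2)
        eg = aggregate([m1, m2], cfg)
        assert eg.mean_weight[0, 1] == 0.0
        W = eg.mean_weight.copy()
        W[np.abs(W) <= cfg.edge_threshold] = 0.0
        g = WeightedDigraph.from_matrix(W, eg.names)
        assert g.edges == {}

    def test_retained_mode_averages_survivors_only(self):
        m1 = np.array([[0.0, 0.2], [0.0, 0.0]])
        m2 = np.zeros((2, 2))
        eg = aggregate([m1, m2], EnsembleConfig(n_boot=2, mean_mode="retained"))
        assert eg.mean_weight[0, 1] == pytest.approx(0.2)

    def test_sign_stability_bounded_by_retention(self):
        rng = np.random.default_rng(3)
        mats = [np.triu(rng.normal(size=(4, 4)), 1) *
                (rng.uniform(size=(4, 4)) > 0.5) for _ in range(30)]
        eg = aggregate(mats, EnsembleConfig(n_boot=30))
        assert (eg.sign_stability <= eg.retention_freq + 1e-12).all()
        assert ((0 <= eg.retention_freq) & (eg.retention_freq <= 1)).all()


class TestResolveBidirectional:
    def test_stronger_direction_kept(self):
        g = graph("ab", a_to_b=0.3, b_to_a=0.2)
        out = resolve_bidirectional(g)
        assert out.edges == {("a", "b"): 0.3}

    def test_no_pairs_unchanged(self):
        g = graph("abc", a_to_b=0.3, b_to_c=-0.2)
        assert resolve_bidirectional(g).edges == g.edges

    def test_exact_tie_lexicographic_with_warning(self):
        g = graph("ab", a_to_b=0.2, b_to_a=-0.2)
        with pytest.warns(UserWarning, match="tie"):
            out = resolve_bidirectional(g)
        assert out.edges == {("a", "b"): 0.2}


class TestMakeAcyclic:
    def test_three_cycle_drops_weakest(self):
        g = graph("abc", a_to_b=0.3, b_to_c=0.2, c_to_a=0.1)
        dag, log = make_acyclic(g)
        assert ("c", "a") not in dag.edges
        assert len(dag.edges) == 2
        assert dag.is_acyclic()
        assert log[0]["edge"] == ["c", "a"]

    def test_already_acyclic_unchanged(self):
        g = graph("abc", a_to_b=0.3, a_to_c=0.2)
        dag, log = make_acyclic(g)
        assert dag.edges == g.edges
        assert log == []

    def test_two_disjoint_two_cycles(self):
        # enumerate-all-cycles oracle on the 4-node instance: each 2-cycle
        # must lose exactly its weaker edge
        g = graph("abcd", a_to_b=0.5, b_to_a=0.2, c_to_d=-0.4, d_to_c=0.3)
        dag, log = make_acyclic(g)
        assert len(log) == 2
        assert dag.edges == {("a", "b"): 0.5, ("c", "d"): -0.4}

    def test_random_digraphs_always_acyclic(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            p = int(rng.integers(3, 7))
            W = rng.normal(size=(p, p)) * (rng.uniform(size=(p, p)) < 0.4)
            np.fill_diagonal(W, 0.0)
            g = WeightedDigraph.from_matrix(W, [f"n{i}" for i in range(p)])
            dag, _ = make_acyclic(resolve_bidirectional(g))
            assert dag.is_acyclic()


class TestSelectionAndReport:
    def test_parents_sorted_by_strength(self):
        g = graph("xyo", x_to_o=0.1, y_to_o=0.4)
        assert select_outcome_parents(g, "o") == ["y", "x"]

    def test_no_inedges_empty(self):
        g = graph("xyo", o_to_x=0.4)
        assert select_outcome_parents(g, "o") == []

    def test_missing_outcome_errors(self):
        with pytest.raises(KeyError):
            select_outcome_parents(graph("ab", a_to_b=0.1), "z")

    @pytest.mark.parametrize("mean_w, stab, expect_rows, expect_style", [
        (0.06, 0.19, 0, None),       # fails stability
        (0.25, 0.90, 1, "solid"),    # passes, strong
        (0.05, 0.90, 0, None),       # boundary: strict > on |mean|
        (0.10, 0.20, 1, "dashed"),   # boundary: >= on stability
    ])
    def test_reporting_criteria(self, mean_w, stab, expect_rows, expect_style):
        from gaitcausal.ensemble import EnsembleGraph
        names = ["a", "b"]
        mw = np.array([[0.0, mean_w], [0.0, 0.0]])
        ret = np.array([[0.0, max(stab, 0.5)], [0.0, 0.0]])
        ss = np.array([[0.0, stab], [0.0, 0.0]])
        eg = EnsembleGraph(names, mw, ret, ss, 100)
        rep = stability_report(eg, EnsembleConfig())
        assert len(rep) == expect_rows
        if expect_rows:
            assert rep.iloc[0]["style"] == expect_style


class TestPipelineProperties:
    def test_threshold_monotonicity(self):
        B = np.zeros((4, 4))
        B[1, 0], B[2, 0], B[3, 2] = 0.6, 0.4, 0.5
        X = simulate_sem(SEMSpec(list("abcd"), B), 300, seed=5)
        learner = lambda Xb: fit_direct_lingam(Xb)[1]  # noqa: E731
        edge_sets = []
        for thr in (0.05, 0.15, 0.3):
            cfg = EnsembleConfig(n_boot=50, edge_threshold=thr, seed=77)
            eg, _ = build_ensemble_graph(X, learner, cfg, list("abcd"))
            edge_sets.append(set(eg.final_dag.edges))
        assert edge_sets[2] <= edge_sets[1] <= edge_sets[0]

    def test_identical_input_matches_single_run(self):
        # deterministic learner + resampling-proof data: bootstrap of a
        # constant matrix equals resolve+repair of the thresholded single run
        M = np.array([[0.0, 0.3, 0.0],
                      [0.4, 0.0, 0.0],
                      [0.2, 0.04, 0.0]])
        cfg = EnsembleConfig(n_boot=25, seed=0)
        eg, _ = build_ensemble_graph(np.zeros((10, 3)), lambda Xb: M, cfg,
                                     list("abc"))
        W = M.copy()
        W[np.abs(W) <= cfg.edge_threshold] = 0.0
        expected, _ = make_acyclic(
            resolve_bidirectional(WeightedDigraph.from_matrix(W, list("abc"))))
        assert set(eg.final_dag.edges) == set(expected.edges)
        for e, w in expected.edges.items():
            assert eg.final_dag.edges[e] == pytest.approx(w)

    def test_true_edges_survive_pipeline(self):
        # planted edges >= 0.3 should reach the final DAG across seeds
        hits = 0
        B = np.zeros((5, 5))
        B[1, 0], B[2, 1], B[3, 1], B[4, 3] = 0.5, 0.6, 0.4, 0.5
        true_edges = {("x0", "x1"), ("x1", "x2"), ("x1", "x3"), ("x3", "x4")}
        names = [f"x{i}" for i in range(5)]
        learner = lambda Xb: fit_direct_lingam(Xb)[1]  # noqa: E731
        n_seeds = 3
        for s in range(n_seeds):
            X = simulate_sem(SEMSpec(names, B), 1000, seed=300 + s)
            cfg = EnsembleConfig(n_boot=100, seed=s)
            eg, _ = build_ensemble_graph(X, learner, cfg, names)
            hits += true_edges <= set(eg.final_dag.edges)
        assert hits == n_seeds
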