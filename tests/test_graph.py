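"""Unit and property tests for cohort graphs and position metrics."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_connected_undirected, random_digraph
from netfa import (
    betweenness_centrality,
    build_graph,
    constraint,
    constraint_all,
    eigenvector_centrality,
    in_degree,
    network_summary,
    out_degree,
    position_profiles,
    transform_metrics,
)
from oracles import betweenness_enumeration, constraint_enumeration, \
    leading_eigvec_dense


class TestBuildGraph:
    def test_direct_construction(self):
        g = build_graph([("a", "b"), ("b", "a"), ("a", "c")], cohort="c1")
        assert g.n == 3 and len(g.edges) == 3

    def test_duplicate_nominations_collapse(self):
        g = build_graph([("a", "b"), ("a", "b")], cohort="c1")
        assert len(g.edges) == 1

    def test_roster_isolates_retained(self):
        roster = list("abcde")
        g = build_graph([], cohort="c1", roster=roster)
        assert g.n == 5 and len(g.edges) == 0

    def test_self_nomination_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="self-nomination"):
            g = build_graph([("a", "a"), ("a", "b")], cohort="c1")
        assert ("a", "a") not in g.edges and len(g.edges) == 1

    def test_unknown_cohort_errors(self):
        with pytest.raises(KeyError, match="unknown cohort"):
            build_graph([("a", "b", "c1")], cohort="c9")


class TestDegrees:
    def test_star_center_and_isolate(self):
        g = build_graph([("hub", f"s{i}") for i in range(4)], cohort="c",
                        roster=["hub", "s0", "s1", "s2", "s3", "iso"])
        assert out_degree(g, "hub") == 4
        assert in_degree(g, "s0") == 1
        assert out_degree(g, "iso") == 0 and in_degree(g, "iso") == 0

    def test_matches_adjacency_row_and_column_sums(self, rng):
        g = random_digraph(6, 0.4, rng)
        a = g.adjacency()
        for k, v in enumerate(g.nodes):
            assert out_degree(g, v) == a[k].sum()
            assert in_degree(g, v) == a[:, k].sum()

    def test_unknown_node_errors(self):
        g = build_graph([("a", "b")], cohort="c")
        with pytest.raises(KeyError):
            out_degree(g, "zz")


class TestEigenvector:
    def test_mutual_dyad_with_isolate(self):
        g = build_graph([("a", "b"), ("b", "a")], cohort="c",
                        roster=["a", "b", "z"])
        scores = eigenvector_centrality(g)
        assert scores["a"] == pytest.approx(1.0)
        assert scores["b"] == pytest.approx(1.0)
        assert scores["z"] == pytest.approx(0.0, abs=1e-9)

    def test_complete_mutual_graph_uniform(self):
        nodes = list("abcd")
        recs = [(u, v) for u in nodes for v in nodes if u != v]
        scores = eigenvector_centrality(build_graph(recs, cohort="c"))
        assert all(s == pytest.approx(1.0) for s in scores.values())

    def test_matches_dense_eigendecomposition(self, rng):
        for _ in range(25):
            g = random_digraph(8, 0.45, rng)
            if not g.edges:
                continue
            at = g.adjacency().T
            import igraph as ig
            if ig.Graph.Adjacency(at.T.tolist()).is_dag():
                continue
            scores = eigenvector_centrality(g)
            x = np.array([scores[v] for v in g.nodes])
            lam, v_oracle = leading_eigvec_dense(at)
            # eigen-residual and (up to scale) agreement with the oracle
            assert np.linalg.norm(at @ x - lam * x) < 1e-8
            np.testing.assert_allclose(x, v_oracle, atol=1e-6)

    def test_relabeling_equivariance(self, rng):
        g = random_digraph(9, 0.35, rng)
        mapping = {v: f"x{k}" for k, v in enumerate(rng.permutation(g.nodes))}
        relabeled = build_graph([(mapping[e], mapping[a]) for e, a in g.edges],
                                cohort="c", roster=[mapping[v] for v in g.nodes])
        if not g.edges:
            pytest.skip("empty draw")
        try:
            s1 = eigenvector_centrality(g)
        except ValueError:
            return
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s2 = eigenvector_centrality(relabeled)
        for v in g.nodes:
            assert s2[mapping[v]] == pytest.approx(s1[v], abs=1e-7)

    def test_edgeless_errors_and_dag_degenerate(self):
        g = build_graph([], cohort="c", roster=["a", "b"])
        with pytest.raises(ValueError, match="undefined"):
            eigenvector_centrality(g)
        dag = build_graph([("a", "b"), ("b", "c")], cohort="c")
        with pytest.warns(UserWarning, match="nilpotent"):
            scores = eigenvector_centrality(dag)
        assert set(scores.values()) == {0.0}


class TestBetweenness:
    def test_path_and_complete_graph(self):
        path = build_graph([("a", "b"), ("b", "a"), ("b", "c"), ("c", "b")],
                           cohort="c")
        bc = betweenness_centrality(path)
        assert bc["b"] == pytest.approx(1.0)
        assert bc["a"] == bc["c"] == 0.0
        nodes = list("abcde")
        k5 = build_graph([(u, v) for u in nodes for v in nodes if u != v],
                         cohort="c")
        assert all(v == 0.0 for v in betweenness_centrality(k5).values())

    def test_symmetrization_uses_any_tie_direction(self):
        # one-way chain still yields a path on the symmetrized graph
        g = build_graph([("a", "b"), ("c", "b")], cohort="c")
        assert betweenness_centrality(g)["b"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(30):
            g = random_digraph(8, 0.3, rng)
            bc = betweenness_centrality(g)
            oracle = betweenness_enumeration(g.symmetrized_adjacency())
            got = np.array([bc[v] for v in g.nodes])
            np.testing.assert_allclose(got, oracle, atol=1e-10)


class TestConstraint:
    def test_hand_checkable_values(self):
        pendant = build_graph([("a", "b"), ("b", "a")], cohort="c")
        assert constraint(pendant, "a") == pytest.approx(1.0)
        star = build_graph([("c", "l1"), ("l1", "c"), ("c", "l2"), ("l2", "c")],
                           cohort="c")
        assert constraint(star, "c") == pytest.approx(0.5)
        tri_nodes = list("abc")
        tri = build_graph([(u, v) for u in tri_nodes for v in tri_nodes
                           if u != v], cohort="c")
        for v in tri_nodes:
            assert constraint(tri, v) == pytest.approx(1.125)

    def test_matches_enumeration_and_igraph(self, rng):
        import igraph as ig

        for _ in range(40):
            n = int(rng.integers(3, 11))
            g = random_connected_undirected(n, rng)
            adj = g.symmetrized_adjacency()
            ours = constraint_all(g)
            ig_g = ig.Graph.Adjacency(adj.tolist(), mode="undirected")
            ig_vals = ig_g.constraint()
            for k, v in enumerate(g.nodes):
                oracle = constraint_enumeration(adj, k)
                assert ours[v] == pytest.approx(oracle, abs=1e-10)
                assert ours[v] == pytest.approx(ig_vals[k], abs=1e-8)

    def test_isolate_undefined_with_warning(self):
        g = build_graph([("a", "b")], cohort="c", roster=["a", "b", "iso"])
        with pytest.warns(UserWarning, match="isolate"):
            val = constraint(g, "iso")
        assert np.isnan(val)

    def test_brokerage_is_negated_constraint(self, rng):
        g = random_connected_undirected(7, rng)
        prof = position_profiles(g)
        np.testing.assert_allclose(prof["brokerage"], -prof["constraint"])


class TestNetworkSummary:
    def test_reciprocity_limits_and_fraction(self):
        dyad = build_graph([("a", "b"), ("b", "a")], cohort="c")
        assert network_summary(dyad)["reciprocity"] == 1.0
        oneway = build_graph([("a", "b")], cohort="c")
        assert network_summary(oneway)["reciprocity"] == 0.0
        mixed = build_graph([("a", "b"), ("b", "a"), ("a", "c")], cohort="c")
        assert network_summary(mixed)["reciprocity"] == pytest.approx(2 / 3)

    def test_total_degree_counts_both_directions(self):
        g = build_graph([("a", "b"), ("a", "c")], cohort="c")
        s = network_summary(g)
        assert s["mean_total_degree"] == pytest.approx(4 / 3)

    def test_edgeless_reciprocity_undefined(self):
        g = build_graph([], cohort="c", roster=["a", "b"])
        assert np.isnan(network_summary(g)["reciprocity"])


class TestMetricEquivariance:
    def test_relabeling_permutes_all_metrics(self, rng):
        g = random_digraph(8, 0.4, rng)
        if not g.edges:
            pytest.skip("empty draw")
        prof = position_profiles(g)
        mapping = {v: f"y{k}" for k, v in enumerate(rng.permutation(g.nodes))}
        g2 = build_graph([(mapping[e], mapping[a]) for e, a in g.edges],
                         cohort=g.cohort_id,
                         roster=[mapping[v] for v in g.nodes])
        prof2 = position_profiles(g2)
        for metric in ("out_degree", "in_degree", "betweenness", "constraint"):
            for v in g.nodes:
                a, b = prof.loc[v, metric], prof2.loc[mapping[v], metric]
                assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


class TestTransformMetrics:
    def test_hand_computed_sqrt_then_z(self):
        raw = pd.DataFrame({"cohort": ["c1"] * 3, "m": [0.0, 1.0, 4.0]},
                           index=["s1", "s2", "s3"])
        out = transform_metrics(raw)
        np.testing.assert_allclose(out["m"], [-1.224744871, 0.0, 1.224744871],
                                   atol=1e-8)

    def test_cohorts_transform_independently(self, rng):
        raw1 = pd.DataFrame({"cohort": ["c1"] * 6,
                             "m": rng.uniform(0, 5, 6)},
                            index=[f"a{i}" for i in range(6)])
        both = pd.concat([
            raw1,
            raw1.assign(cohort="c2").set_axis([f"b{i}" for i in range(6)]),
        ])
        out = transform_metrics(both)
        np.testing.assert_allclose(out.loc[[f"a{i}" for i in range(6)], "m"],
                                   transform_metrics(raw1)["m"])

    def test_within_cohort_moments(self, rng):
        raw = pd.DataFrame({
            "cohort": ["c1"] * 20 + ["c2"] * 15,
            "m": rng.uniform(0, 9, 35),
        })
        out = transform_metrics(raw)
        for _, grp in out.groupby("cohort"):
            assert abs(grp["m"].mean()) < 1e-10
            assert abs(grp["m"].to_numpy().std() - 1) < 1e-10

    def test_brokerage_transform_negates_constraint_transform(self, rng):
        con = rng.uniform(0.2, 1.5, 12)
        raw = pd.DataFrame({"cohort": ["c"] * 12, "constraint": con,
                            "brokerage": -con})
        out = transform_metrics(raw)
        np.testing.assert_allclose(out["brokerage"], -out["constraint"],
                                   atol=1e-12)

    def test_literal_order_variant_runs(self, rng):
        raw = pd.DataFrame({"cohort": ["c"] * 10, "m": rng.uniform(0, 4, 10)})
        out = transform_metrics(raw, order="z_then_signed_sqrt")
        assert abs(out["m"].mean()) < 0.5  # roughly centered, not unit-sd

    def test_constant_metric_rejected(self):
        raw = pd.DataFrame({"cohort": ["c"] * 4, "m": [2.0] * 4})
        with pytest.raises(ValueError, match="constant"):
            transform_metrics(raw)
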