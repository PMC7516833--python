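"""Graph model: parent sets, history partition, condition sets V/W/F."""

import networkx as nx
import numpy as np
import pytest

import bundleflow as bf
from bundleflow.tsdag import GraphError

from conftest import random_tsdag


class TestParents:
    @pytest.mark.parametrize(
        "node, expected",
        [
            (("Z", 0), {("Y", 1)}),
            (("Y", 3), {("X", 4)}),
            (("X", 0), set()),
        ],
    )
    def test_template_shift(self, chain_dag, node, expected):
        got = bf.parents(chain_dag, bf.LaggedNode(*node))
        assert got == {bf.LaggedNode(*e) for e in expected}

    def test_unknown_variable_rejected(self, chain_dag):
        with pytest.raises(GraphError):
            bf.parents(chain_dag, bf.LaggedNode("Q", 0))

    def test_stationarity_equivariance(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            dag = random_tsdag(rng)
            v = dag.variables[int(rng.integers(len(dag.variables)))]
            tau = int(rng.integers(0, 6))
            base = bf.parents(dag, bf.LaggedNode(v, 0))
            shifted = bf.parents(dag, bf.LaggedNode(v, tau))
            assert shifted == {bf.LaggedNode(p.variable, p.lag + tau) for p in base}


class TestBundledHistory:
    def test_enumeration(self):
        spec = bf.BundleSpec("T", ["A"], ["B"])
        imm, dist = bf.bundled_history_nodes(spec, tau_c=2, horizon=4)
        assert imm == {bf.LaggedNode(v, l) for v in "AB" for l in (1, 2)}
        assert dist == {bf.LaggedNode(v, l) for v in "AB" for l in (3, 4)}

    def test_partition_is_disjoint(self):
        spec = bf.BundleSpec("T", ["A"], ["B"])
        for tau_c, horizon in [(1, 2), (3, 9), (5, 6)]:
            imm, dist = bf.bundled_history_nodes(spec, tau_c, horizon)
            assert not imm & dist
            assert len(imm) == 2 * tau_c and len(dist) == 2 * (horizon - tau_c)

    def test_bad_horizon_rejected(self):
        spec = bf.BundleSpec("T", ["A"], ["B"])
        with pytest.raises(ValueError):
            bf.bundled_history_nodes(spec, 3, 3)


class TestConditionSets:
    def test_hand_enumerated_example(self):
        dag = bf.TimeSeriesDAG.from_edges(
            ["M", "N", "R", "T"],
            [("M", "T", 1), ("N", "T", 2), ("R", "T", 1), ("M", "M", 1)],
        )
        spec = bf.BundleSpec("T", ["M"], ["N"])
        sets = bf.condition_sets(dag, spec, tau_c=1, order=1)
        assert sets.V == {bf.LaggedNode("M", 1)}
        # (N,2) is a parent of the target, not of the immediate history
        assert sets.W == {bf.LaggedNode("M", 2)}
        assert sets.F == {bf.LaggedNode("R", 1)}

    def test_order0_condition_empty(self, seven_var):
        var_spec, bundles, _ = seven_var
        for tau_c in (1, 3, 7):
            assert bf.condition_sets(var_spec.dag, bundles, tau_c, 0).F == frozenset()

    def test_no_bundle_parent_within_tau_c(self):
        dag = bf.TimeSeriesDAG.from_edges(
            ["A", "B", "T"], [("A", "T", 3), ("B", "B", 1)]
        )
        spec = bf.BundleSpec("T", ["A"], ["B"])
        assert bf.condition_sets(dag, spec, tau_c=2, order=0).V == frozenset()

    def test_sets_respect_history_partition(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            dag = random_tsdag(rng)
            names = list(dag.variables)
            if len(names) < 3:
                continue
            target, m, n = names[0], names[1], names[2]
            spec = bf.BundleSpec(target, [m], [n])
            tau_c = int(rng.integers(1, 6))
            sets = bf.condition_sets(dag, spec, tau_c, order=1)
            imm, dist = bf.bundled_history_nodes(
                spec, tau_c, tau_c + max(dag.max_lag, 1)
            )
            assert sets.V <= imm
            assert sets.W <= dist
            assert all(f.variable not in spec.bundled for f in sets.F)

    def test_agrees_with_unrolled_bruteforce(self):
        """V, W, F match explicit intersections on the unrolled window."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 100:
            dag = random_tsdag(rng, max_lag=4)
            names = list(dag.variables)
            if len(names) < 3:
                continue
            perm = rng.permutation(len(names))
            target = names[perm[0]]
            m = {names[perm[1]]}
            n = {names[perm[2]]}
            spec = bf.BundleSpec(target, m, n)
            tau_c = int(rng.integers(1, 5))
            window = tau_c + dag.max_lag

            # independent unrolling via explicit template instantiation
            unrolled_parents = {}
            for v in names:
                for lag in range(window + 1):
                    node = (v, lag)
                    unrolled_parents[node] = {
                        (e.source, lag + e.lag_gap)
                        for e in dag.edges
                        if e.target == v and lag + e.lag_gap <= window + dag.max_lag
                    }
            bundled = m | n
            immediate = {(v, l) for v in bundled for l in range(1, tau_c + 1)}
            distant = {
                (v, l) for v in bundled for l in range(tau_c + 1, window + dag.max_lag + 1)
            }
            V_bf = unrolled_parents[(target, 0)] & immediate
            W_bf = set()
            for u in immediate:
                W_bf |= unrolled_parents[u] & distant
            F_bf = {
                p for p in unrolled_parents[(target, 0)] if p[0] not in bundled
            }

            sets = bf.condition_sets(dag, spec, tau_c, order=1)
            as_tuples = lambda s: {(x.variable, x.lag) for x in s}
            assert as_tuples(sets.V) == V_bf
            assert as_tuples(sets.W) == W_bf
            assert as_tuples(sets.F) == F_bf
            checked += 1


class TestGraphStructure:
    def test_unrolled_graph_is_acyclic(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            dag = random_tsdag(rng)
            nodes, edges = bf.unroll(dag, window=8)
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            assert nx.is_directed_acyclic_graph(g)

    def test_contemporaneous_edge_rejected(self):
        with pytest.raises(GraphError):
            bf.TimeSeriesDAG.from_edges(["A", "B"], [("A", "B", 0)])

    def test_bundles_must_be_disjoint_and_nonempty(self):
        with pytest.raises(ValueError):
            bf.BundleSpec("T", ["A"], ["A"])
        with pytest.raises(ValueError):
            bf.BundleSpec("T", [], ["A"])


class TestGraphFile:
    def test_round_trip(self, tmp_path, seven_var):
        var_spec, _, _ = seven_var
        path = tmp_path / "graph.csv"
        bf.write_graph(var_spec.dag, path)
        loaded = bf.load_graph(path, variables=var_spec.dag.variables)
        assert loaded.edges == var_spec.dag.edges

    def test_header_and_comments_skipped(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("# comment\nsource,target,lag\nA,B,2\n")
        dag = bf.load_graph(path)
        assert dag.edges == frozenset({bf.EdgeTemplate("A", "B", 2)})

    @pytest.mark.parametrize(
        "body", ["A,B,0\n", "A,B\n", "A,B,x\n"], ids=["zero-lag", "short", "non-int"]
    )
    def test_malformed_edges_rejected(self, tmp_path, body):
        path = tmp_path / "g.csv"
        path.write_text("source,target,lag\n" + body)
        with pytest.raises(GraphError):
            bf.load_graph(path)

    def test_unknown_variable_vs_header(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("source,target,lag\nA,Q,1\n")
        with pytest.raises(GraphError):
            bf.load_graph(path, variables=["A", "B"])
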