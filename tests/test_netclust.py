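"""Correlation graphs, Markov clustering, SOM, and network modules."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import cx3sig as cx
from cx3sig import netclust
from cx3sig.io_formats import ALL_POPULATIONS

from conftest import five_group_labels


def _frame(rows, prefix="g"):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(rows, index=[f"{prefix}{i}" for i in range(len(rows))],
                        columns=[f"s{j}" for j in range(rows.shape[1])])


class TestCorrelationGraph:
    def test_identical_rows_edge_weight_one(self):
        m = _frame([[1, 2, 3, 4], [1, 2, 3, 4]])
        g = cx.correlation_graph(m, min_r=0.85)
        assert g.has_edge("g0", "g1")
        assert g["g0"]["g1"]["weight"] == pytest.approx(1.0)

    def test_anticorrelated_rows_no_edge(self):
        m = _frame([[1, 2, 3], [3, 2, 1]])
        g = cx.correlation_graph(m, min_r=0.85)
        assert g.number_of_edges() == 0

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(4)
        m = _frame(rng.normal(size=(50, 8)))
        g = cx.correlation_graph(m, min_r=0.3)
        expected = set()
        for i, j in itertools.combinations(range(50), 2):
            r = np.corrcoef(m.iloc[i], m.iloc[j])[0, 1]
            if r >= 0.3:
                expected.add(frozenset({f"g{i}", f"g{j}"}))
        got = {frozenset(e) for e in g.edges}
        assert got == expected

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(5)
        m = _frame(rng.normal(size=(30, 6)))
        lo = {frozenset(e) for e in cx.correlation_graph(m, 0.2).edges}
        hi = {frozenset(e) for e in cx.correlation_graph(m, 0.5).edges}
        assert hi <= lo


# -- independent dense reference MCL (textbook implementation) --------------

def reference_mcl(graph: nx.Graph, inflation: float, max_iter: int = 200,
                  tol: float = 1e-6):
    nodes = sorted(graph.nodes)
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        i, j = nodes.index(u), nodes.index(v)
        a[i, j] = a[j, i] = w
    m = a + np.eye(n)
    m = m / m.sum(axis=0)
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        m[m < 1e-9] = 0.0
        colsum = m.sum(axis=0)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < tol:
            break
    support = nx.Graph()
    support.add_nodes_from(range(n))
    support.add_edges_from(zip(*np.nonzero((m + m.T) > 0)))
    partition = set()
    singles = set()
    for comp in nx.connected_components(support):
        names = frozenset(nodes[i] for i in comp)
        if len(names) > 1:
            partition.add(names)
        else:
            singles |= names
    return partition, frozenset(singles)


class TestMCL:
    def test_two_disconnected_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        cs = cx.mcl(g)
        assert sorted(map(len, cs.clusters)) == [3, 3]
        assert {frozenset(c) for c in cs.clusters} == \
            {frozenset("abc"), frozenset("xyz")}

    def test_single_edge_pair(self):
        g = nx.Graph([("a", "b")])
        cs = cx.mcl(g)
        assert cs.clusters == [frozenset({"a", "b"})]
        assert not cs.unassigned

    def test_isolated_node_unassigned(self):
        g = nx.Graph([("a", "b")])
        g.add_node("lonely")
        cs = cx.mcl(g)
        assert "lonely" in cs.unassigned

    def test_union_covers_nodes_and_refines_components(self):
        rng = np.random.default_rng(6)
        g = nx.gnp_random_graph(40, 0.08, seed=3)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(40)})
        cs = cx.mcl(g)
        assert cs.all_nodes() == frozenset(g.nodes)
        # every cluster lies inside one connected component
        for c in cs.clusters:
            comp = nx.node_connected_component(g, next(iter(c)))
            assert c <= comp

    @pytest.mark.parametrize("inflation", [2.0, 2.2])
    def test_matches_reference_implementation(self, inflation):
        """Partitions equal an independently written dense MCL on 20 random
        graphs of up to 30 nodes."""
        rng = np.random.default_rng(12)
        for trial in range(20):
            n = int(rng.integers(5, 31))
            p = float(rng.uniform(0.1, 0.35))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.5, 1.0))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in range(n)})
            cs = cx.mcl(g, inflation=inflation)
            ref_clusters, ref_singles = reference_mcl(g, inflation)
            assert {frozenset(c) for c in cs.clusters} == ref_clusters, \
                f"trial {trial}"
            assert cs.unassigned == ref_singles


class TestSOM:
    def _data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        proto = rng.normal(0, 1, size=(6, 25))
        x = proto[rng.integers(0, 6, n)] + rng.normal(0, 0.3, size=(n, 25))
        labels = five_group_labels(5)
        return pd.DataFrame(x, index=[f"g{i}" for i in range(n)],
                            columns=list(labels)), labels

    def test_identical_genes_share_a_unit(self):
        labels = five_group_labels(5)
        df = pd.DataFrame(np.tile(np.arange(25.0), (30, 1)),
                          index=[f"g{i}" for i in range(30)],
                          columns=list(labels))
        grid = cx.som_train(df, labels, iterations=500, seed=1)
        assert grid.assignment.nunique() == 1

    def test_quantization_error_decreases_with_training(self):
        """Mean distance to the best-matching unit shrinks as training
        proceeds, measured at 10 checkpoints of one run."""
        df, labels = self._data()
        grid = cx.som_train(df, labels, iterations=20000, seed=3,
                            n_checkpoints=10)
        qes = grid.qe_history
        assert len(qes) == 10
        assert all(b <= a + 1e-9 for a, b in zip(qes, qes[1:]))

    def test_same_seed_same_assignment(self):
        df, labels = self._data(n=60)
        a = cx.som_train(df, labels, iterations=1000, seed=9)
        b = cx.som_train(df, labels, iterations=1000, seed=9)
        pd.testing.assert_series_equal(a.assignment, b.assignment)

    def test_every_gene_assigned_once(self):
        df, labels = self._data(n=80)
        grid = cx.som_train(df, labels, iterations=1000, seed=2)
        assert set(grid.assignment.index) == set(df.index)
        assert grid.assignment.between(0, 24).all()
        assert grid.codebook.shape == (25, 25)


def rand_index(part_a: dict[str, int], part_b: dict[str, int]) -> float:
    items = sorted(part_a)
    agree = total = 0
    for x, y in itertools.combinations(items, 2):
        total += 1
        same_a = part_a[x] == part_a[y]
        same_b = part_b[x] == part_b[y]
        agree += same_a == same_b
    return agree / total


class TestWCNA:
    def _two_block(self):
        t = np.linspace(0, 1, 12)
        f1, f2 = np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)
        rows = [f1 * (i + 1) for i in range(60)] + \
               [f2 * (i + 1) for i in range(60)]
        idx = [f"a{i}" for i in range(60)] + [f"b{i}" for i in range(60)]
        return pd.DataFrame(rows, index=idx,
                            columns=[f"s{j}" for j in range(12)])

    def test_recovers_noiseless_two_block_partition(self):
        m = self._two_block()
        ms = cx.wcna(m, power=7, min_module=30, mediss=0.3)
        assert len(ms.modules) == 2
        truth = {g: g[0] for g in m.index}
        got = {}
        for k, mod in enumerate(ms.modules):
            for g in mod.genes:
                got[g] = k
        assert rand_index(truth, {g: got[g] for g in truth}) == 1.0

    def test_eigengene_of_identical_genes_correlates_with_members(self):
        base = np.sin(np.linspace(0, 3, 10))
        m = pd.DataFrame([base * (i + 1) for i in range(32)],
                         index=[f"g{i}" for i in range(32)],
                         columns=[f"s{j}" for j in range(10)])
        ms = cx.wcna(m, power=7, min_module=30, mediss=0.01)
        assert len(ms.modules) == 1
        e = ms.modules[0].eigengene
        for g in list(ms.modules[0].genes)[:5]:
            r = np.corrcoef(m.loc[g], e)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-8)

    def test_mediss_zero_is_a_merge_noop(self):
        m = self._two_block()
        a = cx.wcna(m, power=7, min_module=30, mediss=1e-12)
        b = cx.wcna(m, power=7, min_module=30, mediss=0.3)
        assert {fs for fs in map(frozenset, (mod.genes for mod in a.modules))} \
            == {fs for fs in map(frozenset, (mod.genes for mod in b.modules))}

    def test_modules_disjoint_and_min_sized(self, small_present):
        sub = small_present.subset(small_present.gene_ids[:400])
        ms = cx.wcna(sub.values, power=7, min_module=30, mediss=0.3)
        seen = set()
        for mod in ms.modules:
            assert len(mod.genes) >= 30
            assert not (mod.genes & seen)
            seen |= mod.genes
        assert seen | ms.unassigned == set(sub.values.index)

    def test_zero_variance_gene_is_reported(self):
        m = self._two_block()
        m.loc["a0"] = 5.0
        with pytest.raises(ValueError, match="a0"):
            cx.wcna(m, power=7, min_module=30, mediss=0.3)


class TestSelectEffectorCluster:
    def _gmz(self, profiles):
        return pd.DataFrame(
            profiles, columns=[p.value for p in ALL_POPULATIONS]
        )

    def test_score_prefers_cx3cr1_high_cluster(self):
        gmz = pd.DataFrame(
            [[1.2, 1.1, -0.2, -0.3, -1.5],
             [0.5, 0.5, 0.5, -0.5, -1.0]],
            index=["a1", "b1"],
            columns=[p.value for p in ALL_POPULATIONS],
        )
        chosen, score = cx.select_effector_cluster(
            [frozenset({"a1"}), frozenset({"b1"})], gmz)
        assert chosen == frozenset({"a1"})
        assert score == pytest.approx(1.1 - (-0.2))

    def test_single_cluster_returned(self):
        gmz = pd.DataFrame([[0.0, 0.0, 0.0, 0.0, 0.0]], index=["g"],
                           columns=[p.value for p in ALL_POPULATIONS])
        chosen, _ = cx.select_effector_cluster([frozenset({"g"})], gmz)
        assert chosen == frozenset({"g"})

    def test_tie_broken_by_size_then_lexicographic(self):
        gmz = pd.DataFrame(
            [[1.0, 1.0, 0.0, 0.0, 0.0]] * 3, index=["a", "b", "c"],
            columns=[p.value for p in ALL_POPULATIONS])
        chosen, _ = cx.select_effector_cluster(
            [frozenset({"c"}), frozenset({"a", "b"})], gmz)
        assert chosen == frozenset({"a", "b"})
        chosen2, _ = cx.select_effector_cluster(
            [frozenset({"c"}), frozenset({"a"})], gmz)
        assert chosen2 == frozenset({"a"})

    def test_planted_effector_module_selected(self, small_synth,
                                              small_present):
        cm, truth = small_synth
        z = cx.z_transform(small_present)
        zem = cx.ExpressionMatrix(z, small_present.labels, scale="log2")
        gmz = zem.group_means()
        graph = cx.correlation_graph(small_present.values, min_r=0.85)
        cs = cx.mcl(graph)
        chosen, _ = cx.select_effector_cluster(cs.clusters, gmz)
        planted = truth.signature_genes & set(small_present.gene_ids)
        assert len(chosen & planted) / len(planted) > 0.9
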