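"""Fold changes, responsive-gene selection, network weighting, and module
detection/filtering, each checked against independent brute-force oracles."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynsig.core_io import InteractionNetwork, ValidationError
from dynsig.module_discovery import (
    DiscoveryParams,
    FoldChangeMatrix,
    WeightedModule,
    compute_log_fold_changes,
    detect_modules,
    filter_modules,
    pooled_expression,
    select_responsive_genes,
    weight_network,
)

from conftest import make_cohort


def fcm_from(values):
    values = np.asarray(values, dtype=float)
    g, t = values.shape
    return FoldChangeMatrix([f"G{i}" for i in range(g)], [f"T{j}" for j in range(t)], values)


class TestFoldChanges:
    def test_log2_arithmetic(self):
        fcm = compute_log_fold_changes(make_cohort([[8.0, 8.0]], [[9.0, 8.0]]))
        assert fcm.values[0, 0] == pytest.approx(1.0)  # a 2-fold increase
        assert fcm.values[0, 1] == pytest.approx(0.0)

    def test_equal_matrices_give_zero(self, rng):
        x = rng.normal(8, 1, size=(5, 4))
        assert np.all(compute_log_fold_changes(make_cohort(x, x)).values == 0)

    def test_matches_elementwise_subtraction_oracle(self, rng):
        pre = rng.normal(8, 1, size=(50, 10))
        post = rng.normal(8, 1, size=(50, 10))
        fcm = compute_log_fold_changes(make_cohort(pre, post))
        oracle = np.array([[post[i, j] - pre[i, j] for j in range(10)] for i in range(50)])
        np.testing.assert_allclose(fcm.values, oracle)


class TestResponsiveGenes:
    def test_boundary_is_inclusive(self):
        # mean |FC| exactly 1.0 in every tumor: kept ("at least" 2-fold)
        fcm = fcm_from([[1.0, 1.0, 1.0], [0.99, 0.99, 0.99]])
        assert select_responsive_genes(fcm, DiscoveryParams()) == ["G0"]

    def test_all_zero_matrix_selects_nothing(self):
        assert select_responsive_genes(fcm_from(np.zeros((5, 4))), DiscoveryParams()) == []

    def test_sign_cancelling_gene_retained_under_abs_mean(self):
        # +1 in half the tumors, -1 in the rest: mean |FC| = 1, signed mean = 0
        fcm = fcm_from([[1.0, 1.0, -1.0, -1.0]])
        assert select_responsive_genes(fcm, DiscoveryParams()) == ["G0"]
        assert select_responsive_genes(fcm, DiscoveryParams(fc_summary="signed_mean")) == []

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=2.0), st.floats(min_value=0.0, max_value=2.0))
    def test_threshold_monotonicity(self, t1, t2):
        rng = np.random.default_rng(7)
        fcm = fcm_from(rng.normal(0, 1, size=(40, 6)))
        lo, hi = sorted([t1, t2])
        a = set(select_responsive_genes(fcm, DiscoveryParams(fc_threshold=hi)))
        b = set(select_responsive_genes(fcm, DiscoveryParams(fc_threshold=lo)))
        assert a <= b


class TestWeightNetwork:
    def _net(self, *pairs):
        nodes = sorted({n for p in pairs for n in p})
        return InteractionNetwork(nodes, sorted(tuple(sorted(p)) for p in pairs))

    def test_identical_vectors_weight_one(self):
        cohort = make_cohort([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        g = weight_network(self._net(("G0", "G1")), cohort, ["G0", "G1"], DiscoveryParams())
        assert g["G0"]["G1"]["weight"] == pytest.approx(1.0)

    def test_anticorrelated_edge_dropped_at_zero_floor(self):
        cohort = make_cohort([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        g = weight_network(self._net(("G0", "G1")), cohort, ["G0", "G1"], DiscoveryParams())
        assert g.number_of_edges() == 0

    def test_missing_genes_reported_not_dropped_silently(self, rng):
        cohort = make_cohort(rng.normal(size=(3, 4)), rng.normal(size=(3, 4)))
        g = weight_network(self._net(("G0", "G1")), cohort, ["G0", "G1", "G2"], DiscoveryParams())
        assert g.graph["missing_genes"] == ["G2"]

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_weights_match_direct_correlation_oracle(self, method, rng):
        pre = rng.normal(size=(6, 8))
        post = rng.normal(size=(6, 8))
        cohort = make_cohort(pre, post)
        pairs = [("G0", "G1"), ("G1", "G2"), ("G3", "G4"), ("G0", "G5")]
        params = DiscoveryParams(correlation_method=method, edge_weight_floor=-1.0)
        g = weight_network(self._net(*pairs), cohort, [f"G{i}" for i in range(6)], params)
        pooled = np.hstack([pre, post])
        for a, b in pairs:
            i, j = int(a[1]), int(b[1])
            if method == "pearson":
                expected = np.corrcoef(pooled[i], pooled[j])[0, 1]
            else:
                from scipy.stats import spearmanr

                expected = spearmanr(pooled[i], pooled[j]).statistic
            assert g[a][b]["weight"] == pytest.approx(expected, abs=1e-10)


def _clique_graph(cliques, weight=0.9):
    g = nx.Graph()
    for members in cliques:
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                g.add_edge(a, b, weight=weight)
    return g


class TestDetectModules:
    def test_two_disconnected_cliques_split_exactly(self):
        a = [f"A{i:02d}" for i in range(12)]
        b = [f"B{i:02d}" for i in range(12)]
        mods = detect_modules(_clique_graph([a, b]), DiscoveryParams())
        assert sorted(m.genes for m in mods) == [a, b]

    def test_empty_edge_set_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["X", "Y", "Z"])
        mods = detect_modules(g, DiscoveryParams())
        assert [m.genes for m in mods] == [["X"], ["Y"], ["Z"]]
        assert filter_modules(mods, DiscoveryParams()) == []

    def test_partition_property(self, rng):
        g = nx.Graph()
        nodes = [f"N{i}" for i in range(30)]
        g.add_nodes_from(nodes)
        for _ in range(60):
            a, b = rng.choice(nodes, 2, replace=False)
            g.add_edge(a, b, weight=float(rng.random()))
        mods = detect_modules(g, DiscoveryParams())
        flat = [x for m in mods for x in m.genes]
        assert sorted(flat) == sorted(nodes)  # disjoint cover

    def test_clique_components_equal_connected_components_oracle(self):
        # graphs whose components are uniform-weight cliques must come back
        # exactly as their components
        rng = np.random.default_rng(99)
        for _ in range(50):
            n_cliques = rng.integers(2, 5)
            cliques, start = [], 0
            for _ in range(n_cliques):
                size = int(rng.integers(3, 9))
                cliques.append([f"C{start + i:03d}" for i in range(size)])
                start += size
            g = _clique_graph(cliques, weight=0.8)
            mods = detect_modules(g, DiscoveryParams())
            oracle = sorted(sorted(c) for c in nx.connected_components(g))
            assert sorted(m.genes for m in mods) == oracle

    def test_determinism(self, rng):
        g = nx.Graph()
        nodes = [f"N{i}" for i in range(25)]
        for _ in range(80):
            a, b = rng.choice(nodes, 2, replace=False)
            g.add_edge(a, b, weight=0.5)
        runs = [detect_modules(g, DiscoveryParams()) for _ in range(2)]
        assert [m.genes for m in runs[0]] == [m.genes for m in runs[1]]

    def test_annotation_uses_all_pairs_when_expression_given(self, rng):
        import pandas as pd

        genes = ["G0", "G1", "G2"]
        expr = pd.DataFrame(rng.normal(size=(3, 10)), index=genes)
        g = _clique_graph([genes])
        mods = detect_modules(g, DiscoveryParams(), expression=expr)
        corr = np.corrcoef(expr.to_numpy())
        expected = corr[np.triu_indices(3, k=1)].mean()
        assert mods[0].mean_correlation == pytest.approx(expected)


class TestFilterModules:
    @pytest.mark.parametrize(
        "size,corr,kept",
        [
            (9, 0.9, False),  # below the 10-gene floor
            (12, 0.5, False),  # correlation must strictly exceed 0.5
            (12, 0.9, True),
        ],
    )
    def test_size_and_correlation_rules(self, size, corr, kept):
        m = WeightedModule([f"G{i}" for i in range(size)], corr, size)
        assert (filter_modules([m], DiscoveryParams()) == [m]) is kept
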