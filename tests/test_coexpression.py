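from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cladescope import coexpression as cx


def oracle_hrr_edges(matrix: pd.DataFrame, cutoff: int, transform: str = "log2p1"):
    """Brute-force HRR edge set straight from the definition."""
    values = matrix.to_numpy(dtype=float)
    if transform == "log2p1":
        values = np.log2(values + 1.0)
    genes = list(matrix.index)
    n = len(genes)

    def rank_of(i, j):
        ci = [
            (-np.corrcoef(values[i], values[k])[0, 1], genes[k])
            for k in range(n)
            if k != i
        ]
        ci.sort()
        target = next(r for r, (_, g) in enumerate(ci, start=1) if g == genes[j])
        return target

    edges = set()
    for i, j in combinations(range(n), 2):
        hrr = max(rank_of(i, j), rank_of(j, i))
        if hrr <= cutoff:
            edges.add((min(genes[i], genes[j]), max(genes[i], genes[j]), hrr))
    return edges


class TestCorrelationRanks:
    def test_identical_profiles_rank_one(self):
        base = np.array([1.0, 2.0, 5.0, 3.0, 8.0])
        matrix = pd.DataFrame(
            [base, base, base[::-1]], index=["a", "b", "c"], columns=list("vwxyz")
        )
        genes, rank = cx.correlation_ranks(matrix, transform="none")
        ia, ib = genes.index("a"), genes.index("b")
        assert rank[ia, ib] == 1 and rank[ib, ia] == 1

    def test_constant_gene_excluded_with_warning(self):
        matrix = pd.DataFrame(
            [[1, 2, 3], [4, 4, 4], [3, 1, 2]], index=["a", "flat", "c"], columns=list("xyz")
        )
        with pytest.warns(UserWarning, match="constant"):
            genes, _ = cx.correlation_ranks(matrix, transform="none")
        assert "flat" not in genes

    def test_too_few_samples(self):
        matrix = pd.DataFrame([[1, 2], [3, 4]], index=["a", "b"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="3 samples"):
            cx.correlation_ranks(matrix)

    def test_five_gene_toy_matches_oracle(self):
        rng = np.random.default_rng(9)
        matrix = pd.DataFrame(
            rng.random((5, 10)) * 10,
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(10)],
        )
        genes, rank = cx.correlation_ranks(matrix)
        G = cx.build_hrr_network(genes, rank, cutoff=4)
        got = {(min(u, v), max(u, v), d["hrr"]) for u, v, d in G.edges(data=True)}
        assert got == oracle_hrr_edges(matrix, 4)


class TestHRRNetwork:
    def test_mutual_rank_one_edge(self):
        base = np.array([1.0, 5.0, 2.0, 9.0, 4.0, 7.0])
        noise = np.array([3.0, 1.0, 8.0, 2.0, 9.0, 1.0])
        matrix = pd.DataFrame(
            [base, base + 0.01, noise], index=["a", "b", "n"], columns=list("uvwxyz")
        )
        genes, rank = cx.correlation_ranks(matrix, transform="none")
        G = cx.build_hrr_network(genes, rank, cutoff=1)
        assert G.has_edge("a", "b") and G.edges["a", "b"]["hrr"] == 1

    def test_one_sided_rank_insufficient(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(
            rng.random((12, 15)), index=[f"g{i:02d}" for i in range(12)],
            columns=[f"s{j}" for j in range(15)],
        )
        genes, rank = cx.correlation_ranks(matrix)
        cutoff = 3
        G = cx.build_hrr_network(genes, rank, cutoff)
        for u, v, d in G.edges(data=True):
            i, j = genes.index(u), genes.index(v)
            assert d["hrr"] == max(rank[i, j], rank[j, i]) <= cutoff
        # non-edges violate the cutoff
        for i, j in combinations(range(len(genes)), 2):
            if not G.has_edge(genes[i], genes[j]):
                assert max(rank[i, j], rank[j, i]) > cutoff

    def test_random_30_gene_matrix_matches_oracle(self):
        rng = np.random.default_rng(30)
        matrix = pd.DataFrame(
            rng.random((30, 20)) * 5,
            index=[f"g{i:02d}" for i in range(30)],
            columns=[f"s{j}" for j in range(20)],
        )
        genes, rank = cx.correlation_ranks(matrix)
        G = cx.build_hrr_network(genes, rank, cutoff=10)
        got = {(min(u, v), max(u, v), d["hrr"]) for u, v, d in G.edges(data=True)}
        assert got == oracle_hrr_edges(matrix, 10)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(8)
        matrix = pd.DataFrame(
            rng.random((15, 12)), index=[f"g{i:02d}" for i in range(15)],
            columns=[f"s{j}" for j in range(12)],
        )
        genes, rank = cx.correlation_ranks(matrix)
        G = cx.build_hrr_network(genes, rank, cutoff=5)
        for _, _, d in G.edges(data=True):
            assert 1 <= d["hrr"] <= 5

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            cx.build_hrr_network(["a"], np.zeros((1, 1), dtype=np.int32), cutoff=0)


class TestHCCA:
    def test_two_disjoint_triangles(self):
        G = nx.Graph()
        G.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")])
        ms = cx.hcca_cluster(G)
        assert sorted(map(tuple, ms.clusters)) == [("a", "b", "c"), ("x", "y", "z")]
        assert ms.unassigned == []

    def test_clique_single_cluster(self):
        G = nx.complete_graph(8)
        ms = cx.hcca_cluster(G)
        assert len(ms.clusters) == 1 and len(ms.clusters[0]) == 8

    def test_isolated_node_unassigned(self):
        G = nx.complete_graph(5)
        G.add_node("lonely")
        ms = cx.hcca_cluster(G)
        assert "lonely" in ms.unassigned

    def test_bad_step_size(self):
        with pytest.raises(ValueError):
            cx.hcca_cluster(nx.Graph(), step_size=0)

    def test_determinism(self, two_module_expression):
        matrix, _, _ = two_module_expression
        genes, rank = cx.correlation_ranks(matrix)
        G = cx.build_hrr_network(genes, rank, 30)
        m1 = cx.hcca_cluster(G, seed=1)
        m2 = cx.hcca_cluster(G, seed=1)
        assert m1.clusters == m2.clusters and m1.unassigned == m2.unassigned

    def test_clusters_disjoint_and_bounded(self, two_module_expression):
        matrix, _, _ = two_module_expression
        genes, rank = cx.correlation_ranks(matrix)
        G = cx.build_hrr_network(genes, rank, 30)
        ms = cx.hcca_cluster(G, max_cluster_size=100)
        seen = set()
        for cluster in ms.clusters:
            assert 3 <= len(cluster) <= 100
            assert not (seen & set(cluster))
            seen |= set(cluster)
        assert seen | set(ms.unassigned) == set(G.nodes)

    def test_planted_modules_recovered(self, two_module_expression):
        from sklearn.metrics import adjusted_rand_score

        matrix, _, truth = two_module_expression
        genes, rank = cx.correlation_ranks(matrix)
        G = cx.build_hrr_network(genes, rank, 30)
        ms = cx.hcca_cluster(G)
        recovered = ms.assignment()
        planted = dict(zip(truth["gene"], truth["module"]))
        module_genes = [g for g in genes if planted[g] >= 0]
        ari = adjusted_rand_score(
            [planted[g] for g in module_genes], [recovered[g] for g in module_genes]
        )
        assert ari >= 0.9


class TestCategories:
    def make_modules(self):
        return cx.ModuleSet(
            clusters=[["g1", "g2", "g3"], ["g4", "g5"], ["g6", "g7"]],
            unassigned=["g8"],
        )

    def test_category_sets(self):
        cats = pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3", "g4", "g6", "g7"],
                "category": [
                    "stress_response",
                    "stress_response",
                    "calcium_signaling",
                    "transporters",
                    "multicellularity",
                    "phytohormones",
                ],
            }
        )
        counts = cx.module_category_matrix(self.make_modules(), cats)
        assert counts.loc[0, "stress_response"] == 2
        assert counts.loc[0, "calcium_signaling"] == 1
        assert (counts.loc[1] > 0).sum() == 1

    def test_unlabeled_module_empty(self):
        cats = pd.DataFrame({"gene": ["g1"], "category": ["stress_response"]})
        counts = cx.module_category_matrix(self.make_modules(), cats)
        assert (counts.loc[2] == 0).all()

    def test_unknown_label_errors(self):
        cats = pd.DataFrame({"gene": ["g1"], "category": ["mystery"]})
        with pytest.raises(ValueError, match="mystery"):
            cx.module_category_matrix(
                self.make_modules(), cats, categories=["stress_response"]
            )

    def test_fixture_modules_match_planted_labels(self, two_module_expression):
        matrix, cats, truth = two_module_expression
        genes, rank = cx.correlation_ranks(matrix)
        G = cx.build_hrr_network(genes, rank, 30)
        ms = cx.hcca_cluster(G)
        counts = cx.module_category_matrix(ms, cats)
        # each planted module is dominated by its planted label
        planted = dict(zip(truth["gene"], truth["module"]))
        label_of = {0: "stress_response", 1: "calcium_signaling"}
        for mid, cluster in enumerate(ms.clusters):
            majority = pd.Series([planted[g] for g in cluster]).mode()[0]
            if majority >= 0:
                assert counts.loc[mid].idxmax() == label_of[majority]


class TestCooccurrence:
    def frame(self, rows, cats=("A", "B", "C")):
        return pd.DataFrame(rows, columns=list(cats))

    def test_spec_enumeration_example(self):
        counts = self.frame([[1, 1, 0], [2, 0, 0], [0, 1, 3]])
        n_multi, pairs = cx.cooccurrence_frequencies(counts)
        assert n_multi == 2
        lut = {(r.category_a, r.category_b): r.count for r in pairs.itertuples(index=False)}
        assert lut == {("A", "B"): 1, ("A", "C"): 0, ("B", "C"): 1}

    def test_all_single_category(self):
        n_multi, pairs = cx.cooccurrence_frequencies(self.frame([[1, 0, 0], [0, 2, 0]]))
        assert n_multi == 0 and pairs.empty

    def test_all_categories_everywhere(self):
        counts = self.frame([[1, 1, 1]] * 4)
        n_multi, pairs = cx.cooccurrence_frequencies(counts)
        assert n_multi == 4
        assert (pairs["count"] == 4).all()
        assert (pairs["fraction"] == 1.0).all()

    def test_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(6)
        counts = self.frame(rng.integers(0, 3, size=(10, 3)))
        mat = cx.cooccurrence_matrix(counts)
        assert (mat.values == mat.values.T).all()
        assert (np.diag(mat.values) == 0).all()

    def test_exhaustive_enumeration_oracle(self):
        from itertools import product

        cats = ["A", "B", "C"]
        for bits in product([0, 1], repeat=6):  # two modules x three categories
            counts = self.frame([bits[:3], bits[3:]], cats)
            n_multi, pairs = cx.cooccurrence_frequencies(counts)
            multi_rows = [r for r in (bits[:3], bits[3:]) if sum(r) >= 2]
            assert n_multi == len(multi_rows)
            for r in pairs.itertuples(index=False):
                ia, ib = cats.index(r.category_a), cats.index(r.category_b)
                assert r.count == sum(1 for row in multi_rows if row[ia] and row[ib])

    def test_empty_module_set_rejected(self):
        with pytest.raises(ValueError):
            cx.cooccurrence_frequencies(pd.DataFrame(columns=["A"]))
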