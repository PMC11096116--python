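"""Highest-reciprocal-rank co-expression network and module analysis.

For each gene, other genes are ranked by descending Pearson correlation
(rank 1 = most correlated, ties broken lexicographically by gene id). The
HRR of a pair is max(rank_i(j), rank_j(i)); an edge exists iff that value is
at or below the cutoff, and lower is stronger. Modules are found by
neighborhood chiseling: grow each node's k-step neighborhood, iteratively
shave off nodes with more edges leaving the neighborhood than inside it,
score the survivors by internal-edge fraction, and greedily accept the
best-scoring non-overlapping candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_HRR_CUTOFF = 30
DEFAULT_STEP_SIZE = 3
DEFAULT_MAX_CLUSTER_SIZE = 100
DEFAULT_MIN_CLUSTER_SIZE = 3


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix (first column gene ids, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return df


def correlation_ranks(matrix: pd.DataFrame, transform: str = "log2p1"):
    """Per-gene correlation rank lists.

    Returns ``(genes, rank)`` where ``rank`` is an n x n integer array with
    rank[i, j] = position of gene j in gene i's descending-correlation list
    (1 = best, self excluded; ties broken by gene id). Constant-profile genes
    are excluded with a warning.
    """
    if transform not in ("log2p1", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    if matrix.shape[1] < 3:
        raise ValueError("at least 3 samples required")
    values = matrix.to_numpy(dtype=float)
    if transform == "log2p1":
        if (values < 0).any():
            raise ValueError("log2p1 transform requires non-negative values")
        values = np.log2(values + 1.0)
    constant = values.std(axis=1) == 0
    if constant.any():
        dropped = list(matrix.index[constant])
        warnings.warn(f"excluding {len(dropped)} constant-profile gene(s): {dropped[:5]}...")
    genes = list(matrix.index[~constant])
    values = values[~constant]
    n = len(genes)
    corr = np.corrcoef(values) if n > 1 else np.ones((n, n))

    rank = np.zeros((n, n), dtype=np.int32)
    order_ids = np.arange(n)
    for i in range(n):
        c = corr[i].copy()
        c[i] = np.inf  # sentinel so self sorts first and is skipped
        # descending correlation, ties by gene id (genes list is the id order)
        order = np.lexsort((order_ids, -c))
        r = 0
        for j in order:
            if j == i:
                continue
            r += 1
            rank[i, j] = r
    return genes, rank


def build_hrr_network(genes: list, rank: np.ndarray, cutoff: int = DEFAULT_HRR_CUTOFF) -> nx.Graph:
    """Undirected graph with edge (i, j) iff max(rank_i(j), rank_j(i)) <= cutoff."""
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    G = nx.Graph()
    G.add_nodes_from(genes)
    G.graph["hrr_cutoff"] = int(cutoff)
    n = len(genes)
    hrr = np.maximum(rank, rank.T)
    for i in range(n):
        for j in range(i + 1, n):
            if hrr[i, j] <= cutoff:
                G.add_edge(genes[i], genes[j], hrr=int(hrr[i, j]))
    return G


@dataclass
class ModuleSet:
    """Disjoint gene clusters plus the genes left unassigned."""

    clusters: list = field(default_factory=list)  # list of sorted gene lists
    unassigned: list = field(default_factory=list)

    def assignment(self) -> dict:
        out = {}
        for mid, cluster in enumerate(self.clusters):
            for gene in cluster:
                out[gene] = mid
        for gene in self.unassigned:
            out[gene] = -1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, m) for g, m in sorted(self.assignment().items())]
        return pd.DataFrame(rows, columns=["gene", "module"])


def _chisel(G: nx.Graph, nbhd: set) -> set:
    """Iteratively remove nodes with more edges leaving the set than inside it."""
    nbhd = set(nbhd)
    while True:
        doomed = []
        for v in nbhd:
            inside = sum(1 for u in G.neighbors(v) if u in nbhd)
            outside = G.degree(v) - inside
            if outside > inside:
                doomed.append(v)
        if not doomed:
            return nbhd
        nbhd -= set(doomed)


def _score(G: nx.Graph, cluster: set) -> float:
    """Density-weighted internal-edge fraction.

    Internal / (internal + boundary) edges, multiplied by internal edge
    density. The density factor resolves the merge degeneracy of the plain
    edge fraction: two tight clusters joined by a few bridge nodes have a
    slightly higher edge fraction than either cluster alone but a much lower
    density, so the individual clusters win.
    """
    internal = boundary = 0
    for v in cluster:
        for u in G.neighbors(v):
            if u in cluster:
                internal += 1
            else:
                boundary += 1
    internal //= 2
    total = internal + boundary
    fraction = internal / total if total else 0.0
    n = len(cluster)
    density = internal / (n * (n - 1) / 2) if n > 1 else 0.0
    return fraction * density


def hcca_cluster(
    G: nx.Graph,
    step_size: int = DEFAULT_STEP_SIZE,
    max_cluster_size: int = DEFAULT_MAX_CLUSTER_SIZE,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    seed: int = 0,
) -> ModuleSet:
    """Neighborhood-chiseling clustering of an HRR network.

    Deterministic: candidate generation iterates nodes in sorted order and
    ties in candidate score are broken by seed-node id. ``seed`` is accepted
    for interface stability; the algorithm itself is deterministic.
    """
    if step_size < 1:
        raise ValueError("step_size must be >= 1")
    candidates = []
    for node in sorted(G.nodes, key=str):
        # best chiseled neighborhood over radii 1..step_size; a smaller radius
        # wins ties so tight clusters are not swallowed by their surroundings
        best = None
        for radius in range(1, step_size + 1):
            nbhd = set(nx.single_source_shortest_path_length(G, node, cutoff=radius))
            cluster = _chisel(G, nbhd)
            if node not in cluster:
                continue
            if not (min_cluster_size <= len(cluster) <= max_cluster_size):
                continue
            score = _score(G, cluster)
            if best is None or score > best[0]:
                best = (score, node, frozenset(cluster))
        if best is not None:
            candidates.append(best)

    candidates.sort(key=lambda t: (-t[0], str(t[1])))
    assigned: set = set()
    clusters = []
    for score, node, cluster in candidates:
        if cluster & assigned:
            continue
        clusters.append(sorted(cluster, key=str))
        assigned |= cluster
    unassigned = sorted(set(G.nodes) - assigned, key=str)
    return ModuleSet(clusters=clusters, unassigned=unassigned)


def module_category_matrix(
    modules: ModuleSet, gene_categories: pd.DataFrame, categories=None
) -> pd.DataFrame:
    """Per-module category counts (module x category DataFrame).

    ``gene_categories`` has columns (gene, category). Unknown category labels
    raise; genes without a label simply contribute nothing.
    """
    labels = dict(zip(gene_categories.iloc[:, 0], gene_categories.iloc[:, 1]))
    if categories is not None:
        unknown = sorted(set(labels.values()) - set(categories))
        if unknown:
            raise ValueError(f"unknown category labels: {unknown}")
        cols = list(categories)
    else:
        cols = sorted(set(labels.values()))
    counts = pd.DataFrame(0, index=range(len(modules.clusters)), columns=cols, dtype=int)
    for mid, cluster in enumerate(modules.clusters):
        for gene in cluster:
            cat = labels.get(gene)
            if cat is not None:
                counts.loc[mid, cat] += 1
    counts.index.name = "module"
    return counts


def cooccurrence_frequencies(category_counts: pd.DataFrame):
    """Multi-category module count and pairwise category co-occurrence.

    Returns ``(n_multi, pairs)`` where ``pairs`` has one row per unordered
    category pair with the number of multi-category modules containing both
    and that number as a fraction of multi-category modules.
    """
    if len(category_counts) < 1:
        raise ValueError("at least one module required")
    present = category_counts > 0
    multi = present.sum(axis=1) >= 2
    n_multi = int(multi.sum())
    cats = list(category_counts.columns)
    rows = []
    for a, b in combinations(cats, 2):
        both = int((present.loc[multi, a] & present.loc[multi, b]).sum()) if n_multi else 0
        frac = both / n_multi if n_multi else 0.0
        rows.append((a, b, both, frac))
    pairs = pd.DataFrame(rows, columns=["category_a", "category_b", "count", "fraction"])
    if n_multi == 0:
        pairs = pairs.iloc[0:0]
    return n_multi, pairs


def cooccurrence_matrix(category_counts: pd.DataFrame) -> pd.DataFrame:
    """Symmetric co-occurrence count matrix with zero diagonal."""
    n_multi, pairs = cooccurrence_frequencies(category_counts)
    cats = list(category_counts.columns)
    mat = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    for r in pairs.itertuples(index=False):
        mat.loc[r.category_a, r.category_b] = r.count
        mat.loc[r.category_b, r.category_a] = r.count
    return mat
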