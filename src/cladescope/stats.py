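"""Two-group abundance tests, foreground enrichment and FDR control.

The expansion test is an exact Wilcoxon rank-sum (permutation enumeration of
all rank splits, midranks for ties) when both groups are small, with a
tie-corrected normal approximation beyond that. Enrichment is the one-sided
hypergeometric tail. Adjustment is Benjamini-Hochberg.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cladesets import CladePartition, check_partition_covers

EXACT_MAX_GROUP = 10


@lru_cache(maxsize=32)
def _split_indices(n_total: int, n_second: int) -> np.ndarray:
    """All C(n_total, n_second) index subsets, as a 2-D array."""
    return np.array(list(combinations(range(n_total), n_second)), dtype=np.intp)


def rank_sum_test(a, b, alternative: str = "two_sided") -> float:
    """P-value for the rank-sum test of ``b`` against ``a``.

    ``greater`` tests whether values in ``b`` tend to exceed those in ``a``.
    Exact permutation enumeration (ties handled by midranks, observed value
    included in the tail) when both groups have <= 10 observations; otherwise
    the tie-corrected normal approximation.
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    obs = ranks[len(a):].sum()

    if len(a) <= EXACT_MAX_GROUP and len(b) <= EXACT_MAX_GROUP:
        idx = _split_indices(len(pooled), len(b))
        sums = ranks[idx].sum(axis=1)
        eps = 1e-9
        p_greater = np.mean(sums >= obs - eps)
        p_less = np.mean(sums <= obs + eps)
        if alternative == "greater":
            return float(p_greater)
        if alternative == "less":
            return float(p_less)
        return float(min(1.0, 2.0 * min(p_greater, p_less)))

    alt = {"greater": "greater", "less": "less", "two_sided": "two-sided"}[alternative]
    return float(sps.mannwhitneyu(b, a, alternative=alt, method="asymptotic").pvalue)


def rank_biserial(a, b) -> float:
    """Rank-biserial correlation of b vs a; positive when b tends larger."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u = sps.mannwhitneyu(b, a, alternative="two-sided", method="asymptotic").statistic
    return float(2.0 * u / (len(a) * len(b)) - 1.0)


def abundance_test_two_groups(
    matrix: pd.DataFrame,
    partition: CladePartition,
    alternative: str = "two_sided",
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature rank-sum expansion test between the two partition groups.

    ``alternative='greater'`` tests expansion in the second group of the
    partition's group order. Features with all-zero counts in both groups are
    flagged and receive no p-value. Returns a DataFrame indexed by feature
    with p, BH-adjusted q, rank-biserial effect, median difference, direction
    and significance at ``fdr_alpha``.
    """
    if len(partition.groups) != 2:
        raise ValueError("exactly two groups required")
    check_partition_covers(matrix, partition)
    g1, g2 = partition.groups
    cols1 = [g for g in partition.genomes_of(g1) if g in matrix.columns]
    cols2 = [g for g in partition.genomes_of(g2) if g in matrix.columns]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each group needs at least 2 genomes")
    values = matrix[cols1 + cols2].to_numpy()
    if not np.allclose(values, np.round(values)):
        raise ValueError("counts must be integers")

    rows = []
    for feature in matrix.index:
        a = matrix.loc[feature, cols1].to_numpy(dtype=float)
        b = matrix.loc[feature, cols2].to_numpy(dtype=float)
        if not a.any() and not b.any():
            rows.append((feature, np.nan, np.nan, np.nan, "all_zero"))
            continue
        p = rank_sum_test(a, b, alternative)
        effect = rank_biserial(a, b)
        med_diff = float(np.median(b) - np.median(a))
        rows.append((feature, p, effect, med_diff, ""))
    out = pd.DataFrame(
        rows, columns=["feature", "p", "effect", "median_diff", "flag"]
    ).set_index("feature")
    tested = out["p"].notna()
    q = pd.Series(np.nan, index=out.index)
    if tested.any():
        q[tested] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    out["direction"] = np.where(out["effect"] > 0, "expanded", np.where(out["effect"] < 0, "contracted", "none"))
    out.loc[~tested, "direction"] = ""
    out["significant"] = (out["q"] <= fdr_alpha).fillna(False)
    return out[["p", "q", "effect", "median_diff", "direction", "significant", "flag"]]


def fisher_enrichment(
    foreground,
    universe,
    gene_features: dict,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of features in a foreground set.

    ``gene_features`` maps gene -> iterable of feature/term ids. Only
    features with at least one foreground gene are tested. The odds ratio
    (a*d)/(b*c) is reported as inf (or 0) when a zero cell makes it so.
    """
    foreground = set(foreground)
    universe = set(universe)
    if not foreground:
        raise ValueError("empty foreground")
    if not foreground <= universe:
        raise ValueError("foreground must be a subset of the universe")
    background = universe - foreground
    n_fg, n_bg = len(foreground), len(background)
    N = n_fg + n_bg

    feature_genes: dict[str, set] = {}
    for gene, feats in gene_features.items():
        if gene not in universe:
            continue
        for f in feats:
            feature_genes.setdefault(f, set()).add(gene)

    rows = []
    for feature in sorted(feature_genes):
        genes = feature_genes[feature]
        a = len(genes & foreground)
        if a == 0:
            continue
        K = len(genes)
        b = n_fg - a
        c = K - a
        d = n_bg - c
        p = float(sps.hypergeom.sf(a - 1, N, K, n_fg))
        if b * c == 0:
            odds = np.inf if a * d > 0 else 0.0
        else:
            odds = (a * d) / (b * c)
        rows.append((feature, a, b, c, d, p, odds))
    out = pd.DataFrame(
        rows, columns=["feature", "a", "b", "c", "d", "p", "odds_ratio"]
    ).set_index("feature")
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["direction"] = np.where(out["odds_ratio"] > 1, "enriched", "depleted")
        out["significant"] = out["q"] <= fdr_alpha
    else:
        out["q"] = pd.Series(dtype=float)
        out["direction"] = pd.Series(dtype=str)
        out["significant"] = pd.Series(dtype=bool)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values rejected")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
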