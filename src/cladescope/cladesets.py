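"""Presence/absence algebra over genomes grouped into clades.

Venn-style partitioning of features (domains, domain combinations or
orthogroups) over the regions of a clade partition, clade-exclusive feature
extraction under two universality rules, and pairwise repertoire similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class CladePartition:
    """Genome -> group mapping with a stable group order."""

    assignment: dict
    group_order: tuple[str, ...]

    def __post_init__(self):
        groups = set(self.assignment.values())
        if groups - set(self.group_order):
            raise ValueError("assignment uses groups missing from group_order")

    @classmethod
    def from_mapping(cls, assignment: dict) -> "CladePartition":
        order = tuple(sorted(set(assignment.values())))
        return cls(dict(assignment), order)

    @classmethod
    def read_tsv(cls, path) -> "CladePartition":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("partition file needs two columns: genome, group")
        genome_col, group_col = df.columns[:2]
        assignment = dict(zip(df[genome_col], df[group_col]))
        if len(assignment) != len(df):
            raise ValueError("duplicate genome ids in partition file")
        return cls.from_mapping(assignment)

    def genomes_of(self, group: str) -> list[str]:
        return sorted(g for g, grp in self.assignment.items() if grp == group)

    @property
    def groups(self) -> tuple[str, ...]:
        return self.group_order


def check_partition_covers(matrix: pd.DataFrame, partition: CladePartition):
    missing = sorted(set(matrix.columns) - set(partition.assignment))
    if missing:
        raise ValueError(f"genomes absent from partition: {missing}")


def presence_from_orthogroups(table: pd.DataFrame, partition: CladePartition) -> pd.DataFrame:
    """Orthogroup table (comma-separated gene lists per genome) -> count matrix.

    Count is the number of genes of that genome in that orthogroup.
    """
    counts = table.map(
        lambda cell: 0
        if pd.isna(cell) or str(cell).strip() == ""
        else len([g for g in str(cell).replace(", ", ",").split(",") if g])
    ).astype(int)
    check_partition_covers(counts, partition)
    return counts


def read_orthogroups(path) -> pd.DataFrame:
    """Read a tab-separated orthogroup table (first column = orthogroup id)."""
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def group_presence(matrix: pd.DataFrame, partition: CladePartition) -> pd.DataFrame:
    """Feature x group boolean table; present iff present in >=1 genome of the group."""
    check_partition_covers(matrix, partition)
    present = matrix > 0
    cols = {}
    for group in partition.groups:
        genomes = [g for g in partition.genomes_of(group) if g in matrix.columns]
        cols[group] = present[genomes].any(axis=1) if genomes else pd.Series(False, index=matrix.index)
    return pd.DataFrame(cols)[list(partition.groups)]


def venn_partition(group_table: pd.DataFrame):
    """Assign each group-present feature to its exact presence region.

    Returns ``(regions, nowhere)``: a dict mapping frozenset-of-groups ->
    sorted feature list over the 2^k - 1 non-empty regions that are occupied,
    and the sorted list of features present in no group.
    """
    regions: dict[frozenset, list] = {}
    nowhere = []
    for feature, row in group_table.iterrows():
        present = frozenset(group_table.columns[row.values.astype(bool)])
        if not present:
            nowhere.append(feature)
        else:
            regions.setdefault(present, []).append(feature)
    return {k: sorted(v) for k, v in regions.items()}, sorted(nowhere)


def exclusive_features(
    matrix: pd.DataFrame,
    partition: CladePartition,
    region,
    universality: str = "any_genome",
) -> list:
    """Features present in the region's groups and absent outside it.

    any_genome: present in >=1 genome of every in-region group, 0 genomes of
    out-region groups. all_genomes: additionally present in every genome of
    every in-region group.
    """
    region = frozenset(region)
    unknown = region - set(partition.groups)
    if unknown:
        raise ValueError(f"unknown group names: {sorted(unknown)}")
    if not region:
        raise ValueError("region must be non-empty")
    if universality not in ("any_genome", "all_genomes"):
        raise ValueError(f"unknown universality {universality!r}")
    check_partition_covers(matrix, partition)
    present = matrix > 0
    keep = pd.Series(True, index=matrix.index)
    for group in partition.groups:
        genomes = [g for g in partition.genomes_of(group) if g in matrix.columns]
        if not genomes:
            in_group = pd.Series(False, index=matrix.index)
            all_group = pd.Series(False, index=matrix.index)
        else:
            in_group = present[genomes].any(axis=1)
            all_group = present[genomes].all(axis=1)
        if group in region:
            keep &= all_group if universality == "all_genomes" else in_group
        else:
            keep &= ~in_group
    return sorted(matrix.index[keep])


def repertoire_similarity(
    matrix: pd.DataFrame, partition: CladePartition, metric: str = "jaccard"
) -> pd.DataFrame:
    """Pairwise group similarity of group-present feature sets (Jaccard)."""
    if metric != "jaccard":
        raise ValueError(f"unknown metric {metric!r}")
    gp = group_presence(matrix, partition)
    sets = {g: set(gp.index[gp[g]]) for g in partition.groups}
    out = pd.DataFrame(1.0, index=list(partition.groups), columns=list(partition.groups))
    for a in partition.groups:
        for b in partition.groups:
            union = sets[a] | sets[b]
            if not union:
                warnings.warn(f"groups {a} and {b} both have empty repertoires; similarity set to 1")
                out.loc[a, b] = 1.0
            else:
                out.loc[a, b] = len(sets[a] & sets[b]) / len(union)
    return out


def region_table(group_table: pd.DataFrame) -> pd.DataFrame:
    """Flat TSV-friendly view of venn_partition: feature, region, n_groups."""
    regions, nowhere = venn_partition(group_table)
    rows = []
    for region in sorted(regions, key=lambda r: (len(r), ";".join(sorted(r)))):
        for feature in regions[region]:
            rows.append((feature, ";".join(sorted(region)), len(region)))
    for feature in nowhere:
        rows.append((feature, "", 0))
    return pd.DataFrame(rows, columns=["feature", "region", "n_groups"])
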