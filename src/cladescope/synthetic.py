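"""Synthetic input generation with planted ground truth.

Every downstream stage of the pipeline can be exercised on data produced here:
per-genome domain hit tables with planted clade-exclusive families and planted
abundance expansions, orthogroup tables mirroring the same presence pattern,
expression matrices with planted co-expressed modules carrying functional
category labels, and paralog CDS pairs evolved to a known synonymous
divergence.

All generators take an explicit seed and use one private numpy Generator per
scenario; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._codon import SENSE_CODONS, codon_site_counts, iter_codons, synonymous_changes

#: The seven functional categories used for module labelling.
CATEGORIES = (
    "cell_division_development",
    "multicellularity",
    "stress_response",
    "transporters",
    "phytohormones",
    "calcium_signaling",
    "plant_microbe_interaction",
)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladeScenario:
    """Design of a multi-genome domain-annotation simulation.

    ``planted_exclusives`` maps a region (frozenset of group names) to the
    families planted as exclusive to that region; ``planted_expansions`` maps
    a family name to its per-group mean copy count. Families named in neither
    mapping are filled in as background families present in every group.
    """

    groups: tuple[str, ...]
    genomes_per_group: int
    n_families: int
    planted_exclusives: dict[frozenset, list[str]] = field(default_factory=dict)
    planted_expansions: dict[str, dict[str, float]] = field(default_factory=dict)
    dropout_rate: float = 0.0
    base_copy_mean: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if len(self.groups) < 1:
            raise ValueError("at least one group required")
        if self.genomes_per_group < 1:
            raise ValueError("zero genomes in a group")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError(f"dropout_rate {self.dropout_rate} outside [0, 1]")
        seen: set[str] = set()
        for region, fams in self.planted_exclusives.items():
            region = frozenset(region)
            if not region or not region <= set(self.groups):
                raise ValueError(f"region {set(region)} is not a non-empty subset of groups")
            overlap = seen & set(fams)
            if overlap:
                raise ValueError(f"families planted in multiple regions: {sorted(overlap)}")
            seen |= set(fams)
        for fam, means in self.planted_expansions.items():
            if set(means) != set(self.groups):
                raise ValueError(f"expansion for {fam} must give a mean for every group")
        n_planted = len(seen | set(self.planted_expansions))
        if n_planted > self.n_families:
            raise ValueError("more planted families than n_families")

    @property
    def genomes(self) -> list[str]:
        return [f"{g}_g{i + 1}" for g in self.groups for i in range(self.genomes_per_group)]

    def group_of(self, genome: str) -> str:
        return genome.rsplit("_g", 1)[0]


@dataclass(frozen=True)
class ExpressionScenario:
    """Design of an expression-matrix simulation with planted modules.

    ``modules`` is a list of (gene count, category labels, within-module
    Pearson correlation in (0, 1]) tuples.
    """

    n_genes: int
    n_samples: int
    modules: tuple = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        total = 0
        for size, labels, corr in self.modules:
            if not 0.0 < corr <= 1.0:
                raise ValueError(f"within-module correlation {corr} outside (0, 1]")
            unknown = set(labels) - set(CATEGORIES)
            if unknown:
                raise ValueError(f"unknown categories: {sorted(unknown)}")
            total += size
        if total > self.n_genes:
            raise ValueError("module gene counts exceed n_genes")


@dataclass(frozen=True)
class ParalogScenario:
    """Design of a paralog-pair simulation at known synonymous divergence.

    ``ks_distribution`` is a mixture of (mean, sd, weight) normal components;
    a high-mean component models a duplication burst. Negative draws are
    truncated to 0.
    """

    n_pairs: int
    n_codons: int
    ks_distribution: tuple = ((0.5, 0.1, 1.0),)
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 50:
            raise ValueError("n_codons must be >= 50")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        w = sum(c[2] for c in self.ks_distribution)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {w}, expected 1")


# ---------------------------------------------------------------------------
# clade annotations
# ---------------------------------------------------------------------------


def _family_layout(scenario: CladeScenario):
    """Assign every family a presence region and per-group mean copy count."""
    layout = {}
    for region, fams in scenario.planted_exclusives.items():
        for fam in fams:
            layout[fam] = (frozenset(region), {g: scenario.base_copy_mean for g in scenario.groups})
    for fam, means in scenario.planted_expansions.items():
        region = layout[fam][0] if fam in layout else frozenset(scenario.groups)
        layout[fam] = (region, dict(means))
    n_background = scenario.n_families - len(layout)
    width = max(4, len(str(scenario.n_families)))
    i = 0
    while len(layout) < scenario.n_families:
        i += 1
        fam = f"FAM{i:0{width}d}"
        if fam in layout:
            continue
        layout[fam] = (
            frozenset(scenario.groups),
            {g: scenario.base_copy_mean for g in scenario.groups},
        )
    assert n_background >= 0
    return layout


def simulate_clade_annotations(scenario: CladeScenario):
    """Simulate per-genome domain hit tables realizing the planted pattern.

    Returns ``(hits, truth)`` where ``hits`` maps genome id to a DataFrame
    with columns (protein_id, family, start, end, evalue, score) and ``truth``
    is a DataFrame indexed by family with a ``region`` column (semicolon-joined
    group names) and one true copy-count column per genome. Dropout zeroes a
    genome-family pair in the hit tables but never in the truth table.
    """
    rng = np.random.default_rng(scenario.seed)
    layout = _family_layout(scenario)
    genomes = scenario.genomes
    families = sorted(layout)

    counts = pd.DataFrame(0, index=families, columns=genomes, dtype=int)
    for fam in families:
        region, means = layout[fam]
        for genome in genomes:
            group = scenario.group_of(genome)
            if group not in region:
                continue
            c = int(rng.poisson(means[group]))
            counts.loc[fam, genome] = max(c, 1)  # presence is planted

    hits = {}
    for genome in genomes:
        rows = []
        p = 0
        for fam in families:
            n_copies = counts.loc[fam, genome]
            if n_copies and scenario.dropout_rate and rng.random() < scenario.dropout_rate:
                n_copies = 0  # annotation failure for this genome-family pair
            for _ in range(n_copies):
                p += 1
                start = int(rng.integers(1, 40))
                length = int(rng.integers(60, 300))
                evalue = float(10.0 ** -rng.uniform(10, 60))
                score = float(np.round(rng.uniform(40, 300), 1))
                rows.append((f"{genome}_p{p:05d}", fam, start, start + length, evalue, score))
        hits[genome] = pd.DataFrame(
            rows, columns=["protein_id", "family", "start", "end", "evalue", "score"]
        )

    truth = counts.copy()
    truth.insert(0, "region", [";".join(sorted(layout[f][0])) for f in families])
    truth.index.name = "family"
    return hits, truth


def orthogroups_from_annotations(hits: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Derive an orthogroup table from simulated hit tables (family = orthogroup).

    Columns are genome ids; cells hold comma-separated gene lists. The planted
    clade-exclusivity of a family therefore carries over to its orthogroup.
    """
    families = sorted({f for df in hits.values() for f in df["family"]})
    genomes = sorted(hits)
    table = pd.DataFrame("", index=families, columns=genomes, dtype=object)
    for genome in genomes:
        grouped = hits[genome].groupby("family")["protein_id"].unique()
        for fam, genes in grouped.items():
            table.loc[fam, genome] = ",".join(sorted(genes))
    table.index = [f"OG_{f}" for f in table.index]
    table.index.name = "orthogroup"
    return table


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(scenario: ExpressionScenario):
    """Simulate an expression matrix with planted co-expressed modules.

    Genes of a planted module share a latent sample factor mixed to the
    requested within-module Pearson correlation (gene = sqrt(r)*factor +
    sqrt(1-r)*noise); remaining genes are independent noise. The matrix is
    shifted to be non-negative.

    Returns ``(matrix, categories, truth)``: a genes x samples DataFrame, a
    gene->category DataFrame (module genes only), and a gene->module truth
    DataFrame where background genes carry module id -1.
    """
    rng = np.random.default_rng(scenario.seed)
    genes = [f"gene{i + 1:05d}" for i in range(scenario.n_genes)]
    data = rng.normal(0.0, 1.0, size=(scenario.n_genes, scenario.n_samples))

    assignment = np.full(scenario.n_genes, -1, dtype=int)
    cat_rows = []
    cursor = 0
    for module_id, (size, labels, corr) in enumerate(scenario.modules):
        factor = rng.normal(0.0, 1.0, size=scenario.n_samples)
        block = np.sqrt(corr) * factor + np.sqrt(1.0 - corr) * data[cursor : cursor + size]
        data[cursor : cursor + size] = block
        assignment[cursor : cursor + size] = module_id
        labels = list(labels) or [CATEGORIES[module_id % len(CATEGORIES)]]
        for k in range(size):
            cat_rows.append((genes[cursor + k], labels[k % len(labels)]))
        cursor += size

    # background genes are pure noise at the requested scale
    data[assignment < 0] *= scenario.noise_sd
    if data.size:
        data -= data.min()  # shift to non-negative

    matrix = pd.DataFrame(
        data, index=genes, columns=[f"sample{j + 1:03d}" for j in range(scenario.n_samples)]
    )
    matrix.index.name = "gene"
    categories = pd.DataFrame(cat_rows, columns=["gene", "category"])
    truth = pd.DataFrame({"gene": genes, "module": assignment})
    return matrix, categories, truth


# ---------------------------------------------------------------------------
# paralog pairs
# ---------------------------------------------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in codons)


def _evolve_synonymous(rng: np.random.Generator, cds: str, branch_ks: float, kappa: float) -> str:
    """Apply synonymous-only substitutions totalling ~branch_ks per synonymous site.

    The number of events is Poisson(branch_ks * S) with S the NG86 synonymous
    site count of the starting sequence; an event picks a codon proportionally
    to its synonymous site count, then a synonymous change within the codon
    with transition:transversion weight kappa:1.
    """
    codons = list(iter_codons(cds))
    site_counts = np.array([codon_site_counts(c)[0] for c in codons])
    total_sites = site_counts.sum()
    n_events = rng.poisson(branch_ks * total_sites) if branch_ks > 0 else 0
    for _ in range(n_events):
        weights = site_counts / site_counts.sum()
        idx = rng.choice(len(codons), p=weights)
        changes = synonymous_changes(codons[idx])
        if not changes:  # codon drifted to a family with no synonymous exits
            continue
        w = np.array([kappa if ts else 1.0 for _, _, ts in changes])
        pos, base, _ = changes[rng.choice(len(changes), p=w / w.sum())]
        codon = codons[idx]
        codons[idx] = codon[:pos] + base + codon[pos + 1 :]
        site_counts[idx] = codon_site_counts(codons[idx])[0]
    return "".join(codons)


def simulate_paralog_pairs(scenario: ParalogScenario):
    """Simulate CDS paralog pairs at known synonymous divergence.

    Each pair descends from a random ancestral CDS; both copies receive
    synonymous-only substitutions so the pairwise synonymous divergence
    targets a Ks drawn from the scenario's mixture. Returns ``(pairs,
    truth)``: a list of (pair_id, cds_a, cds_b) and a DataFrame with the
    drawn Ks and mixture component per pair.
    """
    rng = np.random.default_rng(scenario.seed)
    means = np.array([c[0] for c in scenario.ks_distribution])
    sds = np.array([c[1] for c in scenario.ks_distribution])
    weights = np.array([c[2] for c in scenario.ks_distribution])

    pairs = []
    rows = []
    for i in range(scenario.n_pairs):
        comp = int(rng.choice(len(weights), p=weights))
        ks = max(float(rng.normal(means[comp], sds[comp])) if sds[comp] > 0 else float(means[comp]), 0.0)
        ancestor = _random_cds(rng, scenario.n_codons)
        a = _evolve_synonymous(rng, ancestor, ks / 2.0, scenario.kappa)
        b = _evolve_synonymous(rng, ancestor, ks / 2.0, scenario.kappa)
        pair_id = f"pair{i + 1:05d}"
        pairs.append((pair_id, a, b))
        rows.append((pair_id, ks, comp))
    truth = pd.DataFrame(rows, columns=["pair_id", "ks_true", "component"])
    return pairs, truth


# ---------------------------------------------------------------------------
# fixture sets
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path, index: bool):
    df.to_csv(path, sep="\t", index=index, float_format="%.10g", lineterminator="\n")


def _write_domtblout(df: pd.DataFrame, path: Path):
    """Write hits in the hmmscan --domtblout column layout (23 columns)."""
    with open(path, "w") as fh:
        fh.write("# target name accession tlen query name accession qlen E-value score bias "
                 "# of c-Evalue i-Evalue score bias hmm_from hmm_to ali_from ali_to "
                 "env_from env_to acc description\n")
        for r in df.itertuples(index=False):
            tlen = r.end - r.start + 1
            fh.write(
                f"{r.family} - {tlen} {r.protein_id} - {r.end + 20} "
                f"{r.evalue:.2g} {r.score:.1f} 0.0 1 1 {r.evalue:.2g} {r.evalue:.2g} "
                f"{r.score:.1f} 0.0 1 {tlen} {r.start} {r.end} {r.start} {r.end} 0.95 -\n"
            )


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_set(
    out_dir,
    clade: CladeScenario | None = None,
    expression: ExpressionScenario | None = None,
    paralogs: ParalogScenario | None = None,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Materialize every file format the pipeline consumes; return the manifest.

    The manifest (also written to ``manifest.tsv``) lists each emitted file
    with its scenario kind, seed and sha256 checksum.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.tsv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace it")

    entries = []

    def record(path: Path, kind: str, seed: int):
        entries.append((str(path.relative_to(out_dir)), kind, seed, sha256_file(path)))

    if clade is not None:
        hits, truth = simulate_clade_annotations(clade)
        for genome, df in hits.items():
            p = out_dir / f"hits_{genome}.tsv"
            with open(p, "w") as fh:
                fh.write("#" + "\t".join(df.columns) + "\n")
                df.to_csv(fh, sep="\t", index=False, header=False,
                          float_format="%.10g", lineterminator="\n")
            record(p, "domain_hits_tsv", clade.seed)
            p = out_dir / f"hits_{genome}.domtblout"
            _write_domtblout(df, p)
            record(p, "domain_hits_domtblout", clade.seed)
        p = out_dir / "clade_truth.tsv"
        _write_tsv(truth, p, index=True)
        record(p, "clade_truth", clade.seed)
        p = out_dir / "orthogroups.tsv"
        _write_tsv(orthogroups_from_annotations(hits), p, index=True)
        record(p, "orthogroups", clade.seed)
        p = out_dir / "partition.tsv"
        part = pd.DataFrame(
            {"genome": clade.genomes, "group": [clade.group_of(g) for g in clade.genomes]}
        )
        _write_tsv(part, p, index=False)
        record(p, "partition", clade.seed)

    if expression is not None:
        matrix, categories, truth = simulate_expression(expression)
        p = out_dir / "expression.tsv"
        _write_tsv(matrix, p, index=True)
        record(p, "expression_matrix", expression.seed)
        p = out_dir / "gene_categories.tsv"
        _write_tsv(categories, p, index=False)
        record(p, "gene_categories", expression.seed)
        p = out_dir / "expression_truth.tsv"
        _write_tsv(truth, p, index=False)
        record(p, "expression_truth", expression.seed)

    if paralogs is not None:
        pairs, truth = simulate_paralog_pairs(paralogs)
        p = out_dir / "paralog_pairs.fasta"
        with open(p, "w") as fh:
            for pair_id, a, b in pairs:
                fh.write(f">{pair_id}_a\n{a}\n>{pair_id}_b\n{b}\n")
        record(p, "paralog_cds", paralogs.seed)
        p = out_dir / "paralog_truth.tsv"
        _write_tsv(truth, p, index=False)
        record(p, "paralog_truth", paralogs.seed)

    manifest = pd.DataFrame(entries, columns=["path", "kind", "seed", "sha256"])
    _write_tsv(manifest, manifest_path, index=False)
    return manifest
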