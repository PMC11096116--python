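"""Protein domain hit parsing, overlap resolution and architecture building.

A protein's architecture is its start-ordered list of retained domain
families; its combination is the unordered set of distinct families when at
least two are present. Combinations, not ordered architectures, are the unit
of the downstream presence/exclusivity algebra.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

DEFAULT_EVALUE_CUTOFF = 1e-5
DEFAULT_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class DomainHit:
    """A scored domain interval on a protein (1-based inclusive coordinates)."""

    protein_id: str
    family: str
    start: int
    end: int
    evalue: float
    score: float | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end} for {self.protein_id}")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinArchitecture:
    protein_id: str
    ordered_domains: tuple[str, ...]

    @property
    def combination(self) -> frozenset | None:
        """Unordered set of distinct families; None for 0-1 distinct families."""
        distinct = frozenset(self.ordered_domains)
        return distinct if len(distinct) >= 2 else None


class ParseError(ValueError):
    pass


def read_domain_hits(path, dialect: str = "tsv") -> list[DomainHit]:
    """Read domain hits from a 6-column TSV or an hmmscan domtblout file.

    TSV columns: protein_id, family, start, end, evalue, score (score
    optional). Lines starting with '#' are skipped. For domtblout, envelope
    coordinates (columns 20-21) and the independent E-value are used.
    """
    if dialect not in ("tsv", "domtblout"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split() if dialect == "domtblout" else line.split("\t")
            try:
                if dialect == "tsv":
                    if len(fields) not in (5, 6):
                        raise ValueError(f"expected 5-6 columns, got {len(fields)}")
                    protein, family = fields[0], fields[1]
                    start, end = int(fields[2]), int(fields[3])
                    evalue = float(fields[4])
                    score = float(fields[5]) if len(fields) == 6 else None
                else:
                    if len(fields) < 22:
                        raise ValueError(f"expected >=22 columns, got {len(fields)}")
                    family, protein = fields[0], fields[3]
                    evalue = float(fields[12])  # i-Evalue
                    score = float(fields[13])
                    start, end = int(fields[19]), int(fields[20])  # envelope
                hits.append(DomainHit(protein, family, start, end, evalue, score))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed row ({exc})") from exc
    return hits


def group_hits_by_protein(hits) -> dict[str, list[DomainHit]]:
    grouped: dict[str, list[DomainHit]] = {}
    for h in hits:
        grouped.setdefault(h.protein_id, []).append(h)
    return grouped


def resolve_overlaps(
    hits,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> list[DomainHit]:
    """Greedy overlap resolution for the hits of one protein.

    Hits above the E-value cutoff are removed; survivors are considered in
    ascending E-value order (ties by start, family) and a hit is dropped when
    it overlaps an already retained hit by more than ``overlap_fraction`` of
    the shorter hit's length. Result sorted by start coordinate.
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError(f"overlap_fraction {overlap_fraction} outside (0, 1]")
    proteins = {h.protein_id for h in hits}
    if len(proteins) > 1:
        raise ValueError(f"hits from multiple proteins: {sorted(proteins)}")
    survivors = [h for h in hits if h.evalue <= evalue_cutoff]
    survivors.sort(key=lambda h: (h.evalue, h.start, h.family))
    retained: list[DomainHit] = []
    for cand in survivors:
        ok = True
        for kept in retained:
            overlap = min(cand.end, kept.end) - max(cand.start, kept.start) + 1
            if overlap <= 0:
                continue
            if overlap / min(cand.length, kept.length) > overlap_fraction:
                ok = False
                break
        if ok:
            retained.append(cand)
    retained.sort(key=lambda h: (h.start, h.end, h.family))
    return retained


def build_architectures(
    hits,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> dict[str, ProteinArchitecture]:
    """Resolve overlaps per protein and build ordered architectures."""
    out = {}
    for protein, phits in sorted(group_hits_by_protein(hits).items()):
        retained = resolve_overlaps(phits, evalue_cutoff, overlap_fraction)
        if retained:
            out[protein] = ProteinArchitecture(protein, tuple(h.family for h in retained))
    return out


def genome_feature_tables(architectures_per_genome: dict[str, dict]) -> dict[str, pd.DataFrame]:
    """Per-genome counts of domains and combinations.

    A domain's count is the number of retained hits of that family; a
    combination's count is the number of proteins carrying exactly that
    combination. Returns ``{"domain": ..., "combination": ...}``, feature x
    genome count DataFrames.
    """
    genomes = sorted(architectures_per_genome)
    dom_counts: dict[str, Counter] = {g: Counter() for g in genomes}
    combo_counts: dict[str, Counter] = {g: Counter() for g in genomes}
    for genome, archs in architectures_per_genome.items():
        for arch in archs.values():
            for fam in arch.ordered_domains:
                dom_counts[genome][fam] += 1
            combo = arch.combination
            if combo is not None:
                combo_counts[genome]["+".join(sorted(combo))] += 1

    def to_frame(counters, kind):
        features = sorted({f for c in counters.values() for f in c})
        df = pd.DataFrame(
            {g: [counters[g].get(f, 0) for f in features] for g in genomes},
            index=features,
            dtype=int,
        )
        df.index.name = kind
        return df

    return {"domain": to_frame(dom_counts, "domain"), "combination": to_frame(combo_counts, "combination")}
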