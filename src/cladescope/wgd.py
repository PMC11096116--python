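"""Paralog-based whole-genome-duplication screening.

Reciprocal best-hit pairing, codon-level alignment handling, NG86 Ks (with
Ka as a by-product), fourfold-degenerate transversion rates (raw and
distance-corrected), and Gaussian-KDE summaries of the resulting divergence
distributions with peak calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._codon import (
    FOURFOLD_PREFIXES,
    GENETIC_CODE,
    codon_pair_differences,
    codon_site_counts,
    is_transition,
    iter_codons,
    translate,
)

DEFAULT_EVALUE_CUTOFF = 1e-6
DEFAULT_KS_CEILING = 5.0
KDE_GRID_POINTS = 512
PEAK_MIN_DENSITY_FRACTION = 0.05
MIN_ALIGNMENT_CODONS = 30


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------


def rbbh_pairs(scores: pd.DataFrame, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> list[tuple]:
    """Reciprocal best hits from a directed score table.

    ``scores`` needs columns (query, subject, score) and optionally evalue.
    Self-hits are ignored; hits failing the E-value cutoff are ignored. A
    protein's best hit maximizes score, with ties broken by ascending evalue
    then subject id. Returns sorted unordered pairs (a, b), a < b.
    """
    if len(scores) == 0:
        raise ValueError("empty score table")
    df = scores.copy()
    if "evalue" not in df.columns:
        df["evalue"] = 0.0
    df = df[(df["query"] != df["subject"]) & (df["evalue"] <= evalue_cutoff)]
    best: dict[str, str] = {}
    for query, sub in df.groupby("query"):
        ordered = sub.sort_values(["score", "evalue", "subject"], ascending=[False, True, True])
        best[query] = ordered.iloc[0]["subject"]
    pairs = set()
    for a, b in best.items():
        if best.get(b) == a:
            pairs.add((min(a, b), max(a, b)))
    return sorted(pairs)


def score_table_from_proteins(proteins: dict[str, str]) -> pd.DataFrame:
    """All-vs-all global alignment scores for small protein sets (BLOSUM62)."""
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    ids = sorted(proteins)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            s = float(aligner.score(proteins[a], proteins[b]))
            rows.append((a, b, s, 0.0))
            rows.append((b, a, s, 0.0))
    return pd.DataFrame(rows, columns=["query", "subject", "score", "evalue"])


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonAlignment:
    """Two gap-free codon-aligned CDS strings of equal length (multiple of 3)."""

    seq1: str
    seq2: str

    def __post_init__(self):
        if len(self.seq1) != len(self.seq2):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq1) % 3:
            raise ValueError("alignment length not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq1) // 3

    def codon_pairs(self):
        for c1, c2 in zip(iter_codons(self.seq1), iter_codons(self.seq2)):
            yield c1, c2


def backtranslate_alignment(
    prot_aln1: str,
    prot_aln2: str,
    cds1: str,
    cds2: str,
    on_stop: str = "error",
) -> CodonAlignment:
    """Thread CDS codons through a protein alignment, dropping gap columns.

    Each aligned residue is replaced by its codon; columns where either side
    is a gap are dropped at codon granularity. An internal stop codon raises
    unless ``on_stop='drop'``, which drops that codon column instead.
    """
    if len(prot_aln1) != len(prot_aln2):
        raise ValueError("protein alignment rows differ in length")
    for aln, cds, name in ((prot_aln1, cds1, "1"), (prot_aln2, cds2, "2")):
        ungapped = aln.replace("-", "")
        if len(ungapped) * 3 != len(cds):
            raise ValueError(
                f"sequence {name}: protein length {len(ungapped)} x 3 != CDS length {len(cds)}"
            )
    if on_stop not in ("error", "drop"):
        raise ValueError("on_stop must be 'error' or 'drop'")

    out1, out2 = [], []
    i1 = i2 = 0
    for r1, r2 in zip(prot_aln1, prot_aln2):
        codon1 = cds1[3 * i1 : 3 * i1 + 3] if r1 != "-" else None
        codon2 = cds2[3 * i2 : 3 * i2 + 3] if r2 != "-" else None
        if r1 != "-":
            i1 += 1
        if r2 != "-":
            i2 += 1
        if codon1 is None or codon2 is None:
            continue
        if GENETIC_CODE.get(codon1) == "*" or GENETIC_CODE.get(codon2) == "*":
            if on_stop == "error":
                raise ValueError("internal stop codon in alignment")
            continue
        out1.append(codon1)
        out2.append(codon2)
    return CodonAlignment("".join(out1), "".join(out2))


def align_cds_pair(cds1: str, cds2: str, on_stop: str = "error") -> CodonAlignment:
    """Globally align the translations of two CDS and back-translate."""
    from Bio.Align import PairwiseAligner, substitution_matrices

    p1, p2 = translate(cds1), translate(cds2)
    p1 = p1[:-1] if p1.endswith("*") else p1
    p2 = p2[:-1] if p2.endswith("*") else p2
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(p1, p2)[0]
    a1, a2 = str(aln[0]), str(aln[1])
    return backtranslate_alignment(a1, a2, cds1[: 3 * len(p1)], cds2[: 3 * len(p2)], on_stop)


# ---------------------------------------------------------------------------
# Ks / Ka (NG86)
# ---------------------------------------------------------------------------


def _jukes_cantor(p: float) -> float | None:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return None
    return -0.75 * math.log(arg)


def compute_ks(alignment: CodonAlignment, method: str = "NG86") -> dict:
    """Synonymous and nonsynonymous distances for a codon alignment.

    NG86: per-codon synonymous/nonsynonymous site counts averaged across the
    two sequences, pairwise differences averaged over minimal codon paths,
    Jukes-Cantor multiple-hit correction. Returns a dict with ks, ka, the
    raw proportions, site counts and a ``saturated`` flag; ks/ka are NaN when
    the corrected log argument is non-positive.
    """
    if method != "NG86":
        raise ValueError(f"unknown method {method!r}")
    if alignment.n_codons < MIN_ALIGNMENT_CODONS:
        raise ValueError(f"alignment shorter than {MIN_ALIGNMENT_CODONS} codons")
    S = N = Sd = Nd = 0.0
    for c1, c2 in alignment.codon_pairs():
        if GENETIC_CODE[c1] == "*" or GENETIC_CODE[c2] == "*":
            continue
        s1, n1 = codon_site_counts(c1)
        s2, n2 = codon_site_counts(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = codon_pair_differences(c1, c2)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    return {
        "ks": float("nan") if ks is None else ks,
        "ka": float("nan") if ka is None else ka,
        "ps": ps,
        "pn": pn,
        "syn_sites": S,
        "nonsyn_sites": N,
        "saturated": ks is None,
    }


# ---------------------------------------------------------------------------
# 4dtv
# ---------------------------------------------------------------------------


def compute_4dtv(alignment: CodonAlignment, correction: str = "hky") -> dict:
    """Transversion rate at fourfold-degenerate third positions.

    A site qualifies when both codons share identical first two positions
    belonging to a fourfold-degenerate codon box. ``fourdtv_raw`` is the
    transversion fraction among those sites; the corrected value applies an
    HKY85-style transversion distance using the purine/pyrimidine
    composition observed at the sites (reduces to the K2P transversion
    distance for balanced composition). NaN when undefined (n4 = 0 or
    saturation).
    """
    if correction not in ("hky", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    n4 = 0
    transversions = 0
    transitions = 0
    bases = []
    for c1, c2 in alignment.codon_pairs():
        if c1[:2] != c2[:2] or c1[:2] not in FOURFOLD_PREFIXES:
            continue
        n4 += 1
        bases.append(c1[2])
        bases.append(c2[2])
        if c1[2] != c2[2]:
            if is_transition(c1[2], c2[2]):
                transitions += 1
            else:
                transversions += 1
    if n4 == 0:
        return {"fourdtv_raw": float("nan"), "fourdtv_corrected": float("nan"), "n4": 0}
    raw = transversions / n4
    if correction == "none":
        corrected = raw
    else:
        pur = sum(1 for b in bases if b in "AG") / len(bases)
        pyr = 1.0 - pur
        denom = 2.0 * pur * pyr
        if denom <= 0 or raw >= denom:
            corrected = float("nan")
        else:
            corrected = -denom * math.log(1.0 - raw / denom)
    return {"fourdtv_raw": raw, "fourdtv_corrected": corrected, "n4": n4}


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


def divergence_table(pairs, on_stop: str = "error") -> pd.DataFrame:
    """Ks/4dtv per (pair_id, cds_a, cds_b) triple; pairs are pre-aligned CDS."""
    rows = []
    for pair_id, a, b in pairs:
        aln = CodonAlignment(a, b)
        ks = compute_ks(aln)
        four = compute_4dtv(aln)
        rows.append(
            (
                pair_id,
                ks["ks"],
                ks["ka"],
                four["fourdtv_raw"],
                four["fourdtv_corrected"],
                four["n4"],
                "saturated" if ks["saturated"] else "",
            )
        )
    return pd.DataFrame(
        rows, columns=["pair_id", "ks", "ka", "fourdtv_raw", "fourdtv_corrected", "n4", "flag"]
    )


def distribution_summary(
    values,
    bandwidth=None,
    ceiling: float = DEFAULT_KS_CEILING,
    min_values: int = 20,
):
    """Filter a divergence distribution and summarize it with a Gaussian KDE.

    Zeros and undefined (NaN) values are removed, as are values above the
    ceiling. The KDE (Scott's-rule bandwidth unless given) is evaluated on a
    512-point grid over [0, ceiling]; peaks are local maxima with density at
    least 5% of the global maximum. Returns ``(kept_values, grid, density,
    peaks)``.
    """
    values = np.asarray(values, dtype=float)
    kept = values[np.isfinite(values) & (values > 0) & (values <= ceiling)]
    if kept.size < min_values:
        raise ValueError(
            f"only {kept.size} values survive filtering (need >= {min_values})"
        )
    kde = gaussian_kde(kept, bw_method=bandwidth)
    grid = np.linspace(0.0, ceiling, KDE_GRID_POINTS)
    density = kde(grid)
    floor = PEAK_MIN_DENSITY_FRACTION * density.max()
    interior = (
        (density[1:-1] > density[:-2])
        & (density[1:-1] >= density[2:])
        & (density[1:-1] >= floor)
    )
    peaks = grid[1:-1][interior]
    return kept, grid, density, peaks
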