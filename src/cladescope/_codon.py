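"""Codon-level primitives shared by the paralog simulator and divergence estimators.

Standard genetic code only. Coordinates are 0-based internally; sequences are
uppercase ACGT strings whose length is a multiple of 3.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

NUCLEOTIDES = "ACGT"
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

# Standard genetic code (table 1), stops as '*'.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

# First-two-position prefixes whose four codons encode one amino acid.
FOURFOLD_PREFIXES = frozenset(
    p
    for p in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=2))
    if len({GENETIC_CODE[p + n] for n in NUCLEOTIDES}) == 1
)


def is_transition(a: str, b: str) -> bool:
    """True if a->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return a != b and (
        (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)
    )


def translate(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def has_internal_stop(cds: str) -> bool:
    prot = translate(cds)
    return "*" in prot[:-1]


@lru_cache(maxsize=None)
def synonymous_changes(codon: str) -> tuple[tuple[int, str, bool], ...]:
    """All single-nucleotide synonymous changes of a sense codon.

    Returns tuples (position, new_base, is_transition). Changes producing a
    stop codon never appear because a stop is never synonymous with a sense
    codon.
    """
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:
                out.append((pos, base, is_transition(codon[pos], base)))
    return tuple(out)


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts (s, n) for one codon.

    Each position contributes f/3 synonymous sites where f is the fraction of
    its three possible changes that are synonymous; changes to stop codons
    count as nonsynonymous.
    """
    aa = GENETIC_CODE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site counts")
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous difference counts (sd, nd) for a codon pair.

    Averages over all minimal mutational paths between the codons; paths that
    pass through a stop codon are excluded unless every path does.
    """
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_positions):
        current = c1
        sd = nd = 0
        via_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                via_stop = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        paths.append((via_stop, sd, nd))
    usable = [(sd, nd) for via_stop, sd, nd in paths if not via_stop]
    if not usable:
        usable = [(sd, nd) for _, sd, nd in paths]
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def iter_codons(cds: str):
    for i in range(0, len(cds), 3):
        yield cds[i : i + 3]
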