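"""Codon-level bookkeeping for counting-based dN/dS estimation.

Implements the Nei–Gojobori building blocks: expected synonymous /
non-synonymous site fractions per codon, and synonymous / non-synonymous
difference counts for a codon pair averaged over all shortest mutational
pathways (pathways traversing a stop codon are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

NUCLEOTIDES = "ACGT"

#: Standard genetic code, codon -> one-letter amino acid ("*" = stop).
GENETIC_CODE: dict[str, str] = {}
_BASES_BY_AA = {
    "F": ["TTT", "TTC"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"],
    "M": ["ATG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "Y": ["TAT", "TAC"],
    "H": ["CAT", "CAC"],
    "Q": ["CAA", "CAG"],
    "N": ["AAT", "AAC"],
    "K": ["AAA", "AAG"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"],
    "W": ["TGG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "*": ["TAA", "TAG", "TGA"],
}
for _aa, _codons in _BASES_BY_AA.items():
    for _c in _codons:
        GENETIC_CODE[_c] = _aa

STOP_CODONS = frozenset(_BASES_BY_AA["*"])
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

#: All 64 codons in lexicographic order (used for dense lookup tables).
ALL_CODONS = tuple(sorted(GENETIC_CODE))
ALL_CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def translate_codon(codon: str) -> str:
    """Translate a single codon; raises ``KeyError`` on ambiguity characters."""
    return GENETIC_CODE[codon.upper()]


def is_sense(codon: str) -> bool:
    return codon in GENETIC_CODE and codon not in STOP_CODONS


def codon_neighbors(codon: str):
    """Yield (position, new_base, neighbor_codon) for the 9 single-nt changes."""
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base != codon[pos]:
                yield pos, base, codon[:pos] + base + codon[pos + 1 :]


@dataclass(frozen=True)
class SiteCounts:
    """Expected non-synonymous and synonymous site counts for one codon.

    ``n_sites + s_sites == 3`` for every sense codon: each of the three
    positions contributes the fraction of its three possible changes that
    are synonymous to ``s_sites`` and the rest to ``n_sites``.  Changes
    into a stop codon count as non-synonymous.
    """

    n_sites: float
    s_sites: float


@lru_cache(maxsize=None)
def count_sites(codon: str) -> SiteCounts:
    """Nei–Gojobori expected site counts for a sense codon.

    Raises
    ------
    ValueError
        If the codon is a stop codon or contains ambiguity characters.
    """
    codon = codon.upper()
    if codon not in GENETIC_CODE:
        raise ValueError(f"ambiguous or invalid codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon has no defined site counts: {codon}")
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for _pos, _base, nb in codon_neighbors(codon):
        # stop-codon neighbours are counted as non-synonymous
        if nb not in STOP_CODONS and GENETIC_CODE[nb] == aa:
            syn += 1.0
    s = syn / 3.0
    return SiteCounts(n_sites=3.0 - s, s_sites=s)


@lru_cache(maxsize=None)
def pathway_counts(codon1: str, codon2: str) -> tuple[float, float]:
    """(Nd, Sd) for a codon pair, averaged over all shortest pathways.

    A pathway is an ordering of the differing positions; each step is a
    single-nucleotide change, classified synonymous iff it preserves the
    amino acid.  Pathways whose intermediate codons are stops are excluded
    from the average; if every pathway is stop-blocked, the whole
    difference is counted as non-synonymous.
    """
    codon1, codon2 = codon1.upper(), codon2.upper()
    if codon1 == codon2:
        return 0.0, 0.0
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    totals = []
    for order in permutations(diff_pos):
        cur = codon1
        nd = sd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon2:
                blocked = True
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked and cur == codon2:
            totals.append((nd, sd))
    if not totals:
        return float(len(diff_pos)), 0.0
    nd_mean = sum(t[0] for t in totals) / len(totals)
    sd_mean = sum(t[1] for t in totals) / len(totals)
    return nd_mean, sd_mean


@lru_cache(maxsize=1)
def pathway_tables() -> tuple[np.ndarray, np.ndarray]:
    """Dense 64x64 (Nd, Sd) lookup tables over ``ALL_CODONS`` indices.

    Entries involving a stop codon are NaN; used for fast vectorised
    classification of reconstructed parent->child codon changes.
    """
    n = len(ALL_CODONS)
    nd = np.full((n, n), np.nan)
    sd = np.full((n, n), np.nan)
    for i, c1 in enumerate(ALL_CODONS):
        if c1 in STOP_CODONS:
            continue
        for j, c2 in enumerate(ALL_CODONS):
            if c2 in STOP_CODONS:
                continue
            nd[i, j], sd[i, j] = pathway_counts(c1, c2)
    return nd, sd


@lru_cache(maxsize=1)
def site_count_table() -> tuple[np.ndarray, np.ndarray]:
    """Per-codon (n_sites, s_sites) arrays over ``ALL_CODONS`` (NaN for stops)."""
    n = np.full(len(ALL_CODONS), np.nan)
    s = np.full(len(ALL_CODONS), np.nan)
    for i, c in enumerate(ALL_CODONS):
        if c not in STOP_CODONS:
            sc = count_sites(c)
            n[i], s[i] = sc.n_sites, sc.s_sites
    return n, s


@lru_cache(maxsize=None)
def weighted_site_fractions(kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Mutational-opportunity site counts per codon over ``ALL_CODONS``.

    Like :func:`count_sites` but with each single-nucleotide change
    weighted by ``kappa`` when it is a transition, and with stop-codon
    neighbours excluded (they are inaccessible under the substitution
    process).  With ``kappa = 1`` and stops counted this reduces to the
    plain Nei–Gojobori fractions; the weighted version keeps counting
    estimators centred when transitions are enriched, because
    synonymous changes are predominantly transitions at third positions.
    Returns (n_sites, s_sites) arrays with ``n + s = 3`` (NaN for stops).
    """
    n = np.full(len(ALL_CODONS), np.nan)
    s = np.full(len(ALL_CODONS), np.nan)
    for i, codon in enumerate(ALL_CODONS):
        if codon in STOP_CODONS:
            continue
        aa = GENETIC_CODE[codon]
        syn_w = nonsyn_w = 0.0
        for pos, base, nb in codon_neighbors(codon):
            if nb in STOP_CODONS:
                continue
            w = kappa if (codon[pos], base) in TRANSITIONS else 1.0
            if GENETIC_CODE[nb] == aa:
                syn_w += w
            else:
                nonsyn_w += w
        total = syn_w + nonsyn_w
        s[i] = 3.0 * syn_w / total if total > 0 else 0.0
        n[i] = 3.0 - s[i]
    return n, s


def translate(seq: str) -> str:
    """Translate an in-frame, possibly gapped nucleotide sequence.

    Whole-codon gaps ("---") become "-", codons with ambiguity become "X".
    """
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3].upper()
        if codon == "---":
            out.append("-")
        else:
            out.append(GENETIC_CODE.get(codon, "X"))
    return "".join(out)
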