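"""Independent brute-force oracles used by the tests and acceptance script.

These deliberately re-derive everything from first principles (explicit
enumeration, no shared helpers with the package) so they can serve as
ground truth for the package's optimised implementations.
"""

from __future__ import annotations

import itertools
import math

# A locally re-derived standard genetic code (kept separate from the
# package's table on purpose).
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOPS = {c for c, aa in CODE.items() if aa == "*"}


def brute_site_counts(codon: str) -> tuple[float, float]:
    """(n_sites, s_sites) by enumerating all nine single-nt neighbours."""
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            nbr = codon[:pos] + base + codon[pos + 1 :]
            if nbr not in STOPS and CODE[nbr] == CODE[codon]:
                syn += 1
    s = syn / 3.0
    return 3.0 - s, s


def brute_pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Nd, Sd) averaged over stop-free shortest pathways, by enumeration."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diffs):
        cur, nd, sd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS and nxt != c2:
                ok = False
                break
            if CODE[cur] == CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((nd, sd))
    if not results:
        return float(len(diffs)), 0.0
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def brute_pairwise_omega(seq1: str, seq2: str):
    """Full independent Nei-Gojobori estimate; returns dict of parts."""
    nd = sd = 0.0
    n1 = s1 = n2 = s2 = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if any(b not in "ACGT" for b in c1 + c2) or c1 in STOPS or c2 in STOPS:
            continue
        a_n, a_s = brute_site_counts(c1)
        b_n, b_s = brute_site_counts(c2)
        n1, s1, n2, s2 = n1 + a_n, s1 + a_s, n2 + b_n, s2 + b_s
        d_n, d_s = brute_pathway_counts(c1, c2)
        nd, sd = nd + d_n, sd + d_s
    n_sites, s_sites = (n1 + n2) / 2, (s1 + s2) / 2

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    dn = jc(nd / n_sites) if n_sites else float("nan")
    ds = jc(sd / s_sites) if s_sites else float("nan")
    omega = dn / ds if ds and not math.isnan(ds) and ds > 0 and not math.isnan(dn) else float("nan")
    return dict(nd=nd, sd=sd, n_sites=n_sites, s_sites=s_sites, dn=dn, ds=ds, omega=omega)


def brute_parsimony_score(children: dict, leaf_states: dict, states: list) -> int:
    """Minimum changes over all ancestral labelings, by exhaustive enumeration.

    ``children`` maps internal node id -> list of child ids (leaves are
    ids present in ``leaf_states``); the root is the node that is no
    one's child.
    """
    internal = list(children)
    all_nodes = set(children) | {c for cs in children.values() for c in cs}
    root = next(n for n in children if all(n not in cs for cs in children.values()))
    _ = root, all_nodes
    best = math.inf
    for assignment in itertools.product(states, repeat=len(internal)):
        labels = dict(zip(internal, assignment))
        labels.update(leaf_states)
        changes = 0
        for parent, cs in children.items():
            for child in cs:
                if labels[parent] != labels[child]:
                    changes += 1
        best = min(best, changes)
    return int(best)


def brute_interface(receptor_residue_coords: dict, ligand_coords, cutoff: float):
    """Interface residue ordinals by checking every atom pair distance."""
    hits = []
    for ordinal, coords in receptor_residue_coords.items():
        found = False
        for ax, ay, az in coords:
            for bx, by, bz in ligand_coords:
                d = math.sqrt((ax - bx) ** 2 + (ay - by) ** 2 + (az - bz) ** 2)
                if d <= cutoff:
                    found = True
                    break
            if found:
                break
        if found:
            hits.append(ordinal)
    return hits
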