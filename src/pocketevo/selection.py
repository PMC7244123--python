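"""Counting-based selection estimators on codon alignments and trees.

Three layers:

* ``pairwise_omega`` — Nei–Gojobori-style dN/dS between two in-frame
  sequences, with pathway-averaged multi-hit codons and a Jukes–Cantor
  correction of the proportions.
* ``fitch_reconstruct`` / internal vectorised reconstruction — minimum
  state changes on a (possibly multifurcating) tree.  A unit-cost
  Sankoff dynamic program is used so polytomies are scored exactly; on
  bifurcating trees it coincides with Fitch parsimony.  Ties are broken
  towards the lexicographically smallest state so results are
  deterministic.
* ``branch_omega`` / ``site_selection_scan`` — SLAC-style per-branch and
  per-site substitution counts obtained from the reconstructed ancestral
  codons, classified synonymous / non-synonymous through the same
  pathway-averaging rule.

Branch lengths play no role here: counts are sums over edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .alignment import CodonAlignment, ColumnSet
from .genetics import (
    ALL_CODONS,
    GENETIC_CODE,
    STOP_CODONS,
    count_sites,
    pathway_counts,
    pathway_tables,
    site_count_table,
)

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_INF = np.int32(1 << 20)


# ---------------------------------------------------------------------------
# pairwise dN/dS


@dataclass
class OmegaEstimate:
    """Counting-based dN/dS estimate.

    ``nd``/``sd`` are pathway-averaged non-synonymous / synonymous
    difference (or substitution) counts, ``n_sites``/``s_sites`` the
    expected site totals.  ``dn``, ``ds`` and ``omega`` are NaN when
    undefined (no synonymous signal, or a saturated proportion).
    """

    nd: float
    sd: float
    n_sites: float
    s_sites: float
    dn: float
    ds: float
    omega: float
    n_codons: int = 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.omega)


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - (4/3) p); NaN once p >= 3/4 (saturation)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def pairwise_omega(seq1: str, seq2: str) -> OmegaEstimate:
    """Nei–Gojobori dN/dS between two equal-length in-frame sequences.

    Codon pairs where either side is a gap, ambiguous, or a stop codon
    are skipped.  Site totals are averaged over the two sequences and
    restricted to the counted codons.
    """
    if len(seq1) != len(seq2):
        raise ValueError(f"sequence length mismatch: {len(seq1)} != {len(seq2)}")
    if len(seq1) % 3:
        raise ValueError("sequences must be in frame (length multiple of 3)")
    seq1, seq2 = seq1.upper(), seq2.upper()
    nd = sd = 0.0
    n1 = s1 = n2 = s2 = 0.0
    counted = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if c1 not in GENETIC_CODE or c2 not in GENETIC_CODE:
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        counted += 1
        sc1, sc2 = count_sites(c1), count_sites(c2)
        n1 += sc1.n_sites
        s1 += sc1.s_sites
        n2 += sc2.n_sites
        s2 += sc2.s_sites
        if c1 != c2:
            d_n, d_s = pathway_counts(c1, c2)
            nd += d_n
            sd += d_s
    n_sites = (n1 + n2) / 2.0
    s_sites = (s1 + s2) / 2.0
    dn = ds = omega = float("nan")
    if n_sites > 0:
        dn = jukes_cantor(nd / n_sites)
    if s_sites > 0:
        ds = jukes_cantor(sd / s_sites)
    if not math.isnan(dn) and not math.isnan(ds) and ds > 0:
        omega = dn / ds
    return OmegaEstimate(nd, sd, n_sites, s_sites, dn, ds, omega, n_codons=counted)


# ---------------------------------------------------------------------------
# parsimony reconstruction


@dataclass
class FitchResult:
    """Parsimony score plus per-node candidate and resolved states."""

    score: int
    state_sets: dict  # dendropy Node -> frozenset of optimal states
    resolved: dict  # dendropy Node -> single state (deterministic)


def fitch_reconstruct(tree: dendropy.Tree, leaf_states: dict) -> FitchResult:
    """Minimum-change ancestral reconstruction for one character.

    ``leaf_states`` maps leaf labels to states (any hashable, ordered by
    ``sorted``).  Leaves missing from the map are treated as wildcards
    (they match anything) and logged.  Polytomies are handled exactly via
    a unit-cost Sankoff recursion; the reported per-node state set is the
    set of minimum-cost states of the node's subtree, and ``resolved``
    is a deterministic labelling: the lexicographically smallest optimal
    state, preferring the parent's state when it is optimal.
    """
    alphabet = sorted({s for s in leaf_states.values()})
    if not alphabet:
        raise ValueError("no leaf states given")
    index = {s: i for i, s in enumerate(alphabet)}
    k = len(alphabet)
    cost: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label in leaf_states:
                c = np.full(k, _INF, dtype=np.int64)
                c[index[leaf_states[label]]] = 0
            else:
                logger.warning("leaf %r has no state; treated as wildcard", label)
                c = np.zeros(k, dtype=np.int64)
            cost[node] = c
        else:
            c = np.zeros(k, dtype=np.int64)
            for child in node.child_nodes():
                cc = cost[child]
                c = c + np.minimum(cc, cc.min() + 1)
            cost[node] = c

    root_cost = cost[tree.seed_node]
    score = int(root_cost.min())

    state_sets = {
        node: frozenset(alphabet[i] for i in np.flatnonzero(c == c.min()))
        for node, c in cost.items()
    }

    resolved: dict = {}
    for node in tree.preorder_node_iter():
        c = cost[node]
        if node is tree.seed_node:
            resolved[node] = alphabet[int(np.argmin(c))]  # argmin -> smallest index on ties
        else:
            p = index[resolved[node.parent_node]]
            adjusted = np.minimum(c, _INF) + (np.arange(k) != p)
            resolved[node] = alphabet[int(np.argmin(adjusted))]
    return FitchResult(score=score, state_sets=state_sets, resolved=resolved)


# ---------------------------------------------------------------------------
# vectorised reconstruction over alignment columns


class _TreeIndex:
    """Postorder node/edge bookkeeping shared by branch and site scans."""

    def __init__(self, tree: dendropy.Tree, aln: CodonAlignment):
        self.tree = tree
        self.nodes = list(tree.postorder_node_iter())
        self.node_pos = {id(n): i for i, n in enumerate(self.nodes)}
        self.n_nodes = len(self.nodes)
        labels = set(aln.records)
        for lf in tree.leaf_node_iter():
            if lf.taxon.label not in labels:
                raise ValueError(f"tree leaf {lf.taxon.label!r} not in alignment")
        self.leaf_row = {
            id(lf): list(aln.records).index(lf.taxon.label)
            for lf in tree.leaf_node_iter()
        }


def _reconstruct_nt(
    ti: _TreeIndex, nt_matrix: np.ndarray
) -> np.ndarray:
    """Resolved ancestral nucleotide states for every node and column.

    ``nt_matrix`` is (n_species, n_nt_cols) with 0..3 for A/C/G/T and -1
    for gaps/ambiguity (wildcards).  Returns (n_nodes, n_nt_cols) int8 of
    resolved states in postorder node order; leaf rows echo the input
    states (wildcard leaves resolve to the parent state).
    """
    n_cols = nt_matrix.shape[1]
    cost = np.zeros((ti.n_nodes, 4, n_cols), dtype=np.int32)
    for i, node in enumerate(ti.nodes):
        if node.is_leaf():
            states = nt_matrix[ti.leaf_row[id(node)]]
            c = np.zeros((4, n_cols), dtype=np.int32)
            known = states >= 0
            c[:, known] = _INF
            c[states[known], np.flatnonzero(known)] = 0
            cost[i] = c
        else:
            c = np.zeros((4, n_cols), dtype=np.int32)
            for child in node.child_nodes():
                cc = cost[ti.node_pos[id(child)]]
                c += np.minimum(cc, cc.min(axis=0, keepdims=True) + 1)
            cost[i] = c

    resolved = np.empty((ti.n_nodes, n_cols), dtype=np.int8)
    root_i = ti.node_pos[id(ti.tree.seed_node)]
    resolved[root_i] = np.argmin(cost[root_i], axis=0)  # argmin ties -> smallest state
    for node in ti.tree.preorder_node_iter():
        if node is ti.tree.seed_node:
            continue
        i = ti.node_pos[id(node)]
        parent_states = resolved[ti.node_pos[id(node.parent_node)]]
        penalty = (np.arange(4)[:, None] != parent_states[None, :]).astype(np.int32)
        resolved[i] = np.argmin(np.minimum(cost[i], _INF) + penalty, axis=0)
    return resolved


def _edge_codon_counts(
    tree: dendropy.Tree, aln: CodonAlignment, cols: ColumnSet
):
    """Per-edge, per-column (nd, sd) substitution counts from reconstruction.

    Returns ``(edges, nd, sd)`` where ``edges`` is the list of non-seed
    edges (preorder) and ``nd``/``sd`` are (n_edges, n_columns) arrays of
    pathway-averaged counts.  Columns where the child is a leaf gap, or
    where a reconstructed codon is a stop, contribute nothing (the stop
    case is logged).
    """
    ti = _TreeIndex(tree, aln)
    codon_mat = aln.codon_matrix()  # (n_species, n_codons), -1 for gap/ambiguous
    pcols = np.asarray(cols.protein_columns, dtype=int)
    n_cols = len(pcols)

    # nucleotide states restricted to the selected codon columns
    nt_cols = np.empty(3 * n_cols, dtype=int)
    nt_cols[0::3], nt_cols[1::3], nt_cols[2::3] = 3 * pcols, 3 * pcols + 1, 3 * pcols + 2
    nt_matrix = np.full((len(aln.records), 3 * n_cols), -1, dtype=np.int8)
    for r, seq in enumerate(aln.records.values()):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)[nt_cols]
        for base, idx in _BASE_INDEX.items():
            nt_matrix[r, arr == ord(base)] = idx

    resolved = _reconstruct_nt(ti, nt_matrix)
    # codon index per node/column; ALL_CODONS is lexicographic so the
    # base-4 expansion over (A,C,G,T) is exactly its index
    codons = (
        16 * resolved[:, 0::3].astype(np.int32)
        + 4 * resolved[:, 1::3].astype(np.int32)
        + resolved[:, 2::3].astype(np.int32)
    )
    # leaves keep their observed codons (gaps -> -1, skipped)
    for lf in tree.leaf_node_iter():
        codons[ti.node_pos[id(lf)]] = codon_mat[ti.leaf_row[id(lf)], pcols]

    nd_table, sd_table = pathway_tables()
    stop_idx = np.array([ALL_CODONS.index(c) for c in sorted(STOP_CODONS)])
    is_stop = np.zeros(len(ALL_CODONS) + 1, dtype=bool)
    is_stop[stop_idx] = True

    edges = []
    nd_rows, sd_rows = [], []
    n_stop_skipped = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        child = codons[ti.node_pos[id(node)]]
        parent = codons[ti.node_pos[id(node.parent_node)]]
        nd_row = np.zeros(n_cols)
        sd_row = np.zeros(n_cols)
        valid = (child >= 0) & (parent >= 0)
        stop_mask = valid & (is_stop[child] | is_stop[parent])
        n_stop_skipped += int(stop_mask.sum())
        use = valid & ~stop_mask & (child != parent)
        if use.any():
            nd_row[use] = nd_table[parent[use], child[use]]
            sd_row[use] = sd_table[parent[use], child[use]]
        edges.append(node.edge)
        nd_rows.append(nd_row)
        sd_rows.append(sd_row)
    if n_stop_skipped:
        logger.warning(
            "skipped %d edge/column pairs with reconstructed stop codons",
            n_stop_skipped,
        )
    return edges, np.array(nd_rows), np.array(sd_rows)


# ---------------------------------------------------------------------------
# per-branch omega


def branch_omega(
    tree: dendropy.Tree,
    aln: CodonAlignment,
    cols: ColumnSet,
    partition: dict[str, list],
    group: str,
    kappa: float = 2.0,
) -> OmegaEstimate:
    """Pocket-restricted dN/dS for one taxonomic group's edges.

    Substitutions are read off the reconstructed parent -> child codon
    pairs on the group's edges and summed; site totals come from the
    reference pocket codons.  ``dn = Nd/N`` and ``ds = Sd/S`` are
    uncorrected per-edge-sum rates; ``omega`` is NaN when ``ds = 0``.
    """
    if group not in partition:
        raise KeyError(f"unknown group {group!r}")
    if len(cols) == 0:
        raise ValueError("empty column set")
    edges, nd_arr, sd_arr = _edge_codon_counts(tree, aln, cols)
    group_edges = {id(e) for e in partition[group]}
    rows = [i for i, e in enumerate(edges) if id(e) in group_edges]
    nd = float(nd_arr[rows].sum()) if rows else 0.0
    sd = float(sd_arr[rows].sum()) if rows else 0.0
    n_sites, s_sites = _reference_site_totals(aln, cols, kappa)
    dn = nd / n_sites if n_sites > 0 else float("nan")
    ds = sd / s_sites if s_sites > 0 else float("nan")
    omega = dn / ds if ds and ds > 0 else float("nan")
    return OmegaEstimate(nd, sd, n_sites, s_sites, dn, ds, omega, n_codons=len(cols))


def all_branch_omegas(
    tree: dendropy.Tree,
    aln: CodonAlignment,
    cols: ColumnSet,
    partition: dict[str, list],
    kappa: float = 2.0,
) -> dict[str, OmegaEstimate]:
    """``branch_omega`` for every group, sharing one reconstruction pass."""
    edges, nd_arr, sd_arr = _edge_codon_counts(tree, aln, cols)
    n_sites, s_sites = _reference_site_totals(aln, cols, kappa)
    edge_group = {id(e): g for g, es in partition.items() for e in es}
    out: dict[str, OmegaEstimate] = {}
    for group in partition:
        rows = [i for i, e in enumerate(edges) if edge_group.get(id(e)) == group]
        nd = float(nd_arr[rows].sum()) if rows else 0.0
        sd = float(sd_arr[rows].sum()) if rows else 0.0
        dn = nd / n_sites if n_sites > 0 else float("nan")
        ds = sd / s_sites if s_sites > 0 else float("nan")
        omega = dn / ds if ds and ds > 0 else float("nan")
        out[group] = OmegaEstimate(nd, sd, n_sites, s_sites, dn, ds, omega, len(cols))
    return out


def _reference_site_totals(aln: CodonAlignment, cols: ColumnSet, kappa: float = 2.0):
    """Opportunity-weighted site totals over the reference pocket codons.

    ``kappa`` is the assumed transition/transversion rate ratio (2 is a
    typical value for vertebrate nuclear genes); it reweights the
    expected synonymous/non-synonymous site split so that a neutral
    sequence yields omega near 1 even under transition bias.
    """
    from .genetics import ALL_CODON_INDEX, weighted_site_fractions

    n_tab, s_tab = weighted_site_fractions(kappa)
    n_sites = s_sites = 0.0
    ref = aln.records[aln.reference_id]
    for c in cols.protein_columns:
        codon = ref[3 * c : 3 * c + 3]
        if codon in GENETIC_CODE and codon not in STOP_CODONS:
            i = ALL_CODON_INDEX[codon]
            n_sites += n_tab[i]
            s_sites += s_tab[i]
    return n_sites, s_sites


# ---------------------------------------------------------------------------
# per-site scan


@dataclass
class SiteSelectionCall:
    """Per-column selection classes from the counting scan.

    ``table`` has one row per protein column: nd, sd, expected
    non-synonymous fraction, raw and Holm-adjusted p-values, dn-ds score
    and class in {positive, neutral, purifying, uninformative}.
    """

    table: pd.DataFrame
    alpha: float
    correction: str = "holm"

    @property
    def positive_columns(self) -> list[int]:
        return self.table.index[self.table["class"] == "positive"].tolist()


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def site_selection_scan(
    tree: dendropy.Tree,
    aln: CodonAlignment,
    alpha: float = 0.05,
    correction: str = "holm",
    kappa: float = 2.0,
) -> SiteSelectionCall:
    """Counting-based per-site selection scan over the whole alignment.

    For every protein column, non-synonymous and synonymous substitution
    counts are summed over all edges from the ancestral reconstruction
    and compared against the neutral expectation given the column's site
    composition (exact binomial, two-sided).  Because several hundred
    columns are tested, p-values are Holm-adjusted before any site is
    declared positive or purifying (``correction="none"`` disables this).
    """
    if len(aln.records) < 3:
        raise ValueError("site scan needs at least 3 sequences")
    cols = ColumnSet.all_columns(aln)
    edges, nd_arr, sd_arr = _edge_codon_counts(tree, aln, cols)
    del edges
    nd_tot = nd_arr.sum(axis=0)
    sd_tot = sd_arr.sum(axis=0)

    from .genetics import weighted_site_fractions

    n_tab, s_tab = weighted_site_fractions(kappa)
    codon_mat = aln.codon_matrix()
    ref_row = list(aln.records).index(aln.reference_id)

    records = []
    for c in range(aln.n_codons):
        ref_codon = codon_mat[ref_row, c]
        if ref_codon >= 0 and not math.isnan(n_tab[ref_codon]):
            n_c, s_c = n_tab[ref_codon], s_tab[ref_codon]
        else:
            observed = codon_mat[:, c]
            observed = observed[observed >= 0]
            observed = observed[~np.isnan(n_tab[observed])]
            if len(observed) == 0:
                records.append((c, 0.0, 0.0, np.nan, np.nan, np.nan, "uninformative"))
                continue
            n_c, s_c = n_tab[observed].mean(), s_tab[observed].mean()
        p0 = n_c / (n_c + s_c)
        nd, sd = nd_tot[c], sd_tot[c]
        total = nd + sd
        if total <= 0:
            records.append((c, nd, sd, p0, np.nan, np.nan, "uninformative"))
            continue
        k, n = int(round(nd)), int(round(total))
        k = min(k, n)
        p_raw = stats.binomtest(k, n, p0).pvalue
        dn = nd / n_c if n_c > 0 else np.nan
        ds = sd / s_c if s_c > 0 else (0.0 if sd == 0 else np.inf)
        score = dn - ds
        records.append((c, nd, sd, p0, p_raw, score, None))

    df = pd.DataFrame(
        records,
        columns=["column", "nd", "sd", "expected_nonsyn_frac", "p_raw", "score", "class"],
    ).set_index("column")

    informative = df["class"].isna()
    df["p_adj"] = np.nan
    if informative.any():
        p_raw = df.loc[informative, "p_raw"].to_numpy()
        p_adj = _holm(p_raw) if correction == "holm" else p_raw.copy()
        df.loc[informative, "p_adj"] = p_adj
        frac = df.loc[informative, "nd"] / (
            df.loc[informative, "nd"] + df.loc[informative, "sd"]
        )
        excess = frac > df.loc[informative, "expected_nonsyn_frac"]
        sig = df.loc[informative, "p_adj"] < alpha
        cls = np.where(sig & excess, "positive", np.where(sig & ~excess, "purifying", "neutral"))
        df.loc[informative, "class"] = cls
    return SiteSelectionCall(table=df, alpha=alpha, correction=correction)


def positive_sites_in_pocket(call: SiteSelectionCall, cols: ColumnSet):
    """Intersection of positively selected columns with the pocket columns."""
    pocket = set(cols.protein_columns)
    hits = sorted(pocket & set(call.positive_columns))
    return bool(hits), hits
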