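"""Per-branch conservation indexes.

For every taxonomic group the table reports: mean percent identity of
the binding pocket to the mammalian reference (%ID BP), mean percent
identity of the whole sequence (%ID Mol), the Welch test comparing the
two across the group's species, the within-branch non-synonymous count
N (a minimum count of amino-acid-changing events among the group's
species at pocket columns), and the pocket-restricted per-branch dN and
ω from the counting estimator.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import CodonAlignment, ColumnSet
from .branches import BranchScheme, ligand_present
from .selection import SiteSelectionCall, all_branch_omegas, positive_sites_in_pocket, site_selection_scan

logger = logging.getLogger(__name__)

#: Column order of the serialised per-branch table.
TABLE_COLUMNS = [
    "pct_id_pocket",
    "pct_id_whole",
    "omega_pocket",
    "dn_pocket",
    "n_nonsyn",
    "n_species",
    "p_value",
    "direction",
    "ligand_present",
]


def _per_species_identity(
    aln: CodonAlignment, columns: list[int], species: list[str]
) -> dict[str, float]:
    """% identity of each species to the reference over the given columns.

    Columns where the reference itself is gapped are dropped from the
    denominator; a gap in the species at a counted column is a mismatch.
    Species gapped at every counted column are excluded (logged).
    """
    ref_aas = [aln.amino_acid(aln.reference_id, c) for c in columns]
    counted = [(c, aa) for c, aa in zip(columns, ref_aas) if aa != "-"]
    out: dict[str, float] = {}
    for sp in species:
        aas = [aln.amino_acid(sp, c) for c, _ in counted]
        if all(a == "-" for a in aas) and counted:
            logger.warning("species %r is all-gap over the compared columns; excluded", sp)
            continue
        matches = sum(a == r for a, (_, r) in zip(aas, counted))
        out[sp] = 100.0 * matches / len(counted) if counted else float("nan")
    return out


def _group_species(aln: CodonAlignment, scheme: BranchScheme, group: str) -> list[str]:
    members = scheme.species_of(group)
    return [sp for sp in aln.species if sp in members]


def pct_identity_pocket(
    aln: CodonAlignment, cols: ColumnSet, scheme: BranchScheme, group: str
):
    """(branch mean, per-species values) of pocket %ID to the reference.

    The reference is excluded from its own group's average.  Returns
    (NaN, {}) with a warning when the group has no usable species.
    """
    species = [sp for sp in _group_species(aln, scheme, group) if sp != aln.reference_id]
    values = _per_species_identity(aln, cols.protein_columns, species)
    if not values:
        logger.warning("group %r has no usable species for pocket %%ID", group)
        return float("nan"), {}
    return float(np.mean(list(values.values()))), values


def pct_identity_whole(aln: CodonAlignment, scheme: BranchScheme, group: str):
    """As ``pct_identity_pocket`` but over all protein columns."""
    species = [sp for sp in _group_species(aln, scheme, group) if sp != aln.reference_id]
    values = _per_species_identity(aln, list(range(aln.n_codons)), species)
    if not values:
        logger.warning("group %r has no usable species for whole-sequence %%ID", group)
        return float("nan"), {}
    return float(np.mean(list(values.values()))), values


def compare_pocket_vs_whole(
    pocket_values: dict[str, float],
    whole_values: dict[str, float],
    alpha: float = 0.05,
):
    """Welch two-sample test of pocket vs whole-sequence per-species %ID.

    Returns ``(p_value, direction)`` with direction in
    {"pocket-higher", "whole-higher", "none"}; direction is "none"
    unless p < alpha.  Fewer than 2 species per side yields (NaN, "none").
    """
    common = sorted(set(pocket_values) & set(whole_values))
    pocket = np.array([pocket_values[s] for s in common], dtype=float)
    whole = np.array([whole_values[s] for s in common], dtype=float)
    if len(common) < 2:
        return float("nan"), "none"
    if np.allclose(pocket, whole):
        return 1.0, "none"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(pocket, whole, equal_var=False)
    p = float(res.pvalue)
    if math.isnan(p):  # both samples constant but unequal
        p = 0.0
    direction = "none"
    if p < alpha:
        direction = "pocket-higher" if pocket.mean() > whole.mean() else "whole-higher"
    return p, direction


def count_nonsyn_within_branch(
    aln: CodonAlignment, cols: ColumnSet, species: list[str]
) -> int:
    """Within-branch non-synonymous count N over the pocket columns.

    Per column: number of distinct amino acids observed among the given
    species (gaps ignored) minus one, floored at zero — a minimum count
    of amino-acid-changing events inside the branch.
    """
    n = 0
    for c in cols.protein_columns:
        seen = {aln.amino_acid(sp, c) for sp in species if sp in aln.records}
        seen.discard("-")
        if len(seen) > 1:
            n += len(seen) - 1
    return n


@dataclass
class IndexTable:
    """Per-branch index rows plus site-level selection results."""

    table: pd.DataFrame  # indexed by group name in scheme order
    pocket_columns: ColumnSet
    site_calls: SiteSelectionCall | None = None
    positive_sites: list[int] | None = None
    positive_pocket_sites: list[int] | None = None

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["omega_pocket"] = out["omega_pocket"].map(_fmt_na)
        out["dn_pocket"] = out["dn_pocket"].map(_fmt_na)
        out["p_value"] = out["p_value"].map(_fmt_na)
        out.to_csv(path, sep="\t", index_label="group")

    def to_json(self, path) -> None:
        doc = {
            "rows": json.loads(self.table.to_json(orient="index")),
            "pocket_columns_1based": [c + 1 for c in self.pocket_columns.protein_columns],
            "positive_sites_1based": [c + 1 for c in (self.positive_sites or [])],
            "positive_pocket_sites_1based": [
                c + 1 for c in (self.positive_pocket_sites or [])
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)


def _fmt_na(x):
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return x


def build_index_table(
    aln: CodonAlignment,
    cols: ColumnSet,
    scheme: BranchScheme,
    tree,
    partition: dict[str, list],
    alpha: float = 0.05,
    scan_correction: str = "holm",
) -> IndexTable:
    """Compute the full per-branch index table plus the site scan."""
    omegas = all_branch_omegas(tree, aln, cols, partition)
    rows = []
    for group, members in scheme.groups:
        species = _group_species(aln, scheme, group)
        if not species:
            rows.append(
                dict(
                    group=group,
                    pct_id_pocket=np.nan,
                    pct_id_whole=np.nan,
                    omega_pocket=np.nan,
                    dn_pocket=np.nan,
                    n_nonsyn=0,
                    n_species=0,
                    p_value=np.nan,
                    direction="none",
                    ligand_present=ligand_present(scheme, group),
                )
            )
            continue
        pocket_mean, pocket_vals = pct_identity_pocket(aln, cols, scheme, group)
        whole_mean, whole_vals = pct_identity_whole(aln, scheme, group)
        p, direction = compare_pocket_vs_whole(pocket_vals, whole_vals, alpha=alpha)
        n = count_nonsyn_within_branch(aln, cols, species)
        om = omegas[group]
        rows.append(
            dict(
                group=group,
                pct_id_pocket=pocket_mean,
                pct_id_whole=whole_mean,
                omega_pocket=om.omega,
                dn_pocket=om.dn,
                n_nonsyn=n,
                n_species=len(species),
                p_value=p,
                direction=direction,
                ligand_present=ligand_present(scheme, group),
            )
        )
    table = pd.DataFrame(rows).set_index("group")[TABLE_COLUMNS]

    calls = site_selection_scan(tree, aln, alpha=alpha, correction=scan_correction)
    flag, pocket_hits = positive_sites_in_pocket(calls, cols)
    _ = flag
    return IndexTable(
        table=table,
        pocket_columns=cols,
        site_calls=calls,
        positive_sites=calls.positive_columns,
        positive_pocket_sites=pocket_hits,
    )
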