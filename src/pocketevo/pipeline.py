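"""End-to-end orchestration: files in, index table + scenario call out."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from .alignment import CodonAlignment, map_positions_to_columns
from .branches import BranchScheme, ensure_rooted, load_branch_scheme, load_tree, partition_edges
from .classifier import ScenarioCall, Thresholds, classify
from .indexes import IndexTable, build_index_table
from .structures import DEFAULT_CUTOFF, PocketDefinition, extract_interface, read_complex

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    alignment_path: str
    tree_path: str
    scheme_path: str
    reference_id: str
    pocket_path: str | None = None  # precomputed pocket TSV
    structure_path: str | None = None  # else extract from PDB
    receptor_chain: str = "A"
    ligand_chain: str = "B"
    cutoff: float = DEFAULT_CUTOFF
    output_dir: str = "pocketevo_out"
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        for name in ("alignment_path", "tree_path", "scheme_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name.replace('_path', '')} file not found: {p}")
        if self.pocket_path is None and self.structure_path is None:
            raise ValueError("either a pocket TSV or a PDB structure must be given")
        for p in (self.pocket_path, self.structure_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


def run_pipeline(cfg: RunConfig) -> tuple[IndexTable, ScenarioCall, Path]:
    """Execute pocket extraction/loading, mapping, indexes, selection and
    classification; write the TSV/JSON artifacts and a per-branch text
    report into the output directory."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.pocket_path:
        pocket = PocketDefinition.from_tsv(cfg.pocket_path)
    else:
        complex_structure = read_complex(
            cfg.structure_path, chains=[cfg.receptor_chain, cfg.ligand_chain]
        )
        pocket = extract_interface(
            complex_structure, cfg.receptor_chain, cfg.ligand_chain, cfg.cutoff
        )
        pocket.to_tsv(out / "pocket.tsv")

    aln = CodonAlignment.from_fasta(cfg.alignment_path, reference_id=cfg.reference_id)
    scheme = load_branch_scheme(cfg.scheme_path)
    tree = ensure_rooted(load_tree(cfg.tree_path), scheme)
    cols = map_positions_to_columns(aln, pocket.positions)
    partition = partition_edges(tree, scheme)

    table = build_index_table(aln, cols, scheme, tree, partition,
                              alpha=cfg.thresholds.alpha)
    call = classify(table, scheme, cfg.thresholds)

    table.to_tsv(out / "index_table.tsv")
    table.to_json(out / "index_table.json")
    call.to_json(out / "scenario.json")
    report = render_report(table, call)
    (out / "report.txt").write_text(report)
    return table, call, out


def render_report(table: IndexTable, call: ScenarioCall) -> str:
    """Human-readable per-branch report plus the criterion audit."""
    lines = []
    lines.append("Per-branch indexes (ancestral -> mammals)")
    header = f"{'group':<16}{'%ID BP':>8}{'%ID Mol':>9}{'omega':>8}{'dN':>8}{'N':>5}  {'p':>9}  direction"
    lines.append(header)
    lines.append("-" * len(header))
    for group, row in table.table.iterrows():
        omega = _na(row["omega_pocket"], "{:.3f}")
        dn = _na(row["dn_pocket"], "{:.3f}")
        p = _na(row["p_value"], "{:.2e}")
        pid = _na(row["pct_id_pocket"], "{:.1f}")
        wid = _na(row["pct_id_whole"], "{:.1f}")
        flag = "*" if row["ligand_present"] else " "
        lines.append(
            f"{group:<15}{flag}{pid:>8}{wid:>9}{omega:>8}{dn:>8}"
            f"{int(row['n_nonsyn']):>5}  {p:>9}  {row['direction']}"
        )
    lines.append("(* = ligand present in this branch)")
    if table.positive_sites:
        lines.append(
            "positively selected sites (1-based): "
            + ", ".join(str(c + 1) for c in table.positive_sites)
        )
        lines.append(
            "of which in the pocket: "
            + (", ".join(str(c + 1) for c in table.positive_pocket_sites) or "none")
        )
    else:
        lines.append("positively selected sites: none")
    lines.append("")
    lines.append(f"Scenario call: {call.label}")
    if call.notes:
        lines.append(f"note: {call.notes}")
    for c in call.criteria:
        lines.append(f"  [{'x' if c.satisfied else ' '}] {c.id}: {c.description}")
    return "\n".join(lines) + "\n"


def _na(value, fmt: str) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return fmt.format(value)
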