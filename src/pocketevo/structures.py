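"""Binding-interface extraction from a receptor-ligand 3D complex.

The pocket is defined geometrically: a receptor residue belongs to the
binding interface iff at least one of its heavy atoms lies within a
distance cutoff (default 5.0 Å) of any heavy atom of the ligand chain.
Residue positions are reported as 1-based ordinals along the receptor
chain's standard amino-acid residues in file order — not author
numbering — because downstream mapping is against the ungapped
reference protein sequence; the ordinal -> author-number map is kept in
the provenance block for traceability.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_NAMES = {"HOH", "WAT", "DOD"}
DEFAULT_CUTOFF = 5.0


class StructureError(ValueError):
    pass


@dataclass
class Residue:
    chain: str
    author_number: int
    insertion_code: str
    name: str
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3)
    is_standard_aa: bool


@dataclass
class ComplexStructure:
    """Heavy atoms of selected chains, grouped by residue in file order."""

    residues: dict[str, list[Residue]]  # chain id -> residues as encountered

    @property
    def chains(self) -> list[str]:
        return list(self.residues)

    def chain_atoms(self, chain: str, standard_only: bool = False) -> np.ndarray:
        if chain not in self.residues:
            raise StructureError(
                f"chain {chain!r} not present; available chains: {sorted(self.residues)}"
            )
        coords = [
            r.coords
            for r in self.residues[chain]
            if (r.is_standard_aa or not standard_only)
        ]
        if not coords:
            return np.empty((0, 3))
        return np.vstack(coords)


def read_complex(path: str | Path, chains: list[str] | None = None) -> ComplexStructure:
    """Parse a PDB file and keep the heavy atoms of the requested chains.

    Altlocs are resolved to the highest-occupancy conformer (ties: first
    listed); hydrogens (and deuteriums) are dropped; waters are dropped.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure("complex", str(path))
        except Exception as exc:  # unparseable input
            raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise StructureError(f"no models in PDB file {path}")

    available = [ch.id for ch in model]
    wanted = chains if chains is not None else available
    missing = [c for c in wanted if c not in available]
    if missing:
        raise StructureError(
            f"chain(s) {missing} not present; available chains: {sorted(available)}"
        )

    residues: dict[str, list[Residue]] = {}
    for chain in model:
        if chain.id not in wanted:
            continue
        res_list = []
        for res in chain:
            hetflag, resseq, icode = res.id
            if res.resname.strip() in WATER_NAMES or hetflag == "W":
                continue
            names, coords = [], []
            for atom in res:
                # disordered atoms delegate to the selected conformer, which
                # Biopython sets to the highest occupancy (ties: first listed)
                element = (atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                names.append(atom.get_name())
                coords.append(atom.coord)
            if not coords:
                continue
            res_list.append(
                Residue(
                    chain=chain.id,
                    author_number=resseq,
                    insertion_code=icode.strip(),
                    name=res.resname.strip(),
                    atom_names=names,
                    coords=np.asarray(coords, dtype=float),
                    is_standard_aa=(hetflag == " " and res.resname.strip() in STANDARD_AA3),
                )
            )
        residues[chain.id] = res_list
    return ComplexStructure(residues=residues)


@dataclass
class PocketDefinition:
    """Interface residue positions on the reference receptor sequence."""

    receptor_id: str
    positions: list[int]  # 1-based ordinals, strictly increasing
    residue_names: list[str] = field(default_factory=list)
    author_numbers: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("pocket positions must be strictly increasing")
        if any(p < 1 for p in self.positions):
            raise ValueError("pocket positions are 1-based")

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("receptor_id\tposition\tauthor_number\tresidue_name\n")
            for i, p in enumerate(self.positions):
                auth = self.author_numbers[i] if self.author_numbers else ""
                name = self.residue_names[i] if self.residue_names else ""
                fh.write(f"{self.receptor_id}\t{p}\t{auth}\t{name}\n")
        with open(path.with_suffix(".provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PocketDefinition":
        positions, names, auth = [], [], []
        receptor_id = "receptor"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {h: i for i, h in enumerate(header)}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                receptor_id = parts[idx["receptor_id"]]
                positions.append(int(parts[idx["position"]]))
                if "residue_name" in idx and len(parts) > idx["residue_name"]:
                    names.append(parts[idx["residue_name"]])
                if "author_number" in idx and len(parts) > idx["author_number"]:
                    auth.append(parts[idx["author_number"]])
        return cls(receptor_id=receptor_id, positions=positions,
                   residue_names=names, author_numbers=auth)


def extract_interface(
    complex_structure: ComplexStructure,
    receptor_chain: str,
    ligand_chain: str,
    cutoff: float = DEFAULT_CUTOFF,
    receptor_id: str = "receptor",
) -> PocketDefinition:
    """Interface residues: receptor residues with a heavy atom within
    ``cutoff`` Å of any ligand heavy atom.

    Only standard amino-acid residues of the receptor chain are eligible
    pocket members; every heavy atom of the ligand chain counts (the
    ligand may be a peptide or a small molecule).  An empty interface is
    returned with a warning, not an error.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    for ch in (receptor_chain, ligand_chain):
        if ch not in complex_structure.residues:
            raise StructureError(
                f"chain {ch!r} not present; available chains: "
                f"{sorted(complex_structure.residues)}"
            )
    ligand_coords = complex_structure.chain_atoms(ligand_chain)
    receptor_residues = [
        r for r in complex_structure.residues[receptor_chain] if r.is_standard_aa
    ]
    positions, names, auth = [], [], []
    if len(ligand_coords):
        tree = cKDTree(ligand_coords)
        for ordinal, res in enumerate(receptor_residues, start=1):
            dmin = tree.query(res.coords, k=1)[0].min()
            if dmin <= cutoff:
                positions.append(ordinal)
                names.append(res.name)
                auth.append(f"{res.author_number}{res.insertion_code}")
    if not positions:
        logger.warning(
            "no interface residues within %.2f A between chains %s and %s",
            cutoff, receptor_chain, ligand_chain,
        )
    return PocketDefinition(
        receptor_id=receptor_id,
        positions=positions,
        residue_names=names,
        author_numbers=auth,
        provenance={
            "receptor_chain": receptor_chain,
            "ligand_chain": ligand_chain,
            "cutoff_angstrom": cutoff,
            "interface_criterion": (
                "heavy-atom distance cutoff (geometric substitute; the "
                "original contact annotations are not reproduced here)"
            ),
            "ordinal_to_author": {
                str(p): a for p, a in zip(positions, auth)
            },
        },
    )
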