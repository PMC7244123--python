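import sys
from pathlib import Path

import dendropy
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from pocketevo.alignment import CodonAlignment


@pytest.fixture
def toy_alignment() -> CodonAlignment:
    """4 species x 4 codons, reference first, no gaps."""
    return CodonAlignment(
        records={
            "ref": "ATGAAATTTGGG",
            "sp1": "ATGAAATTTGGG",
            "sp2": "ATGAAATTCGGG",  # syn change codon 3
            "sp3": "ATGCGTTTTGGG",  # nonsyn changes codon 2
        },
        reference_id="ref",
    )


@pytest.fixture
def gapped_alignment() -> CodonAlignment:
    """Reference with an internal whole-codon gap."""
    return CodonAlignment(
        records={
            "ref": "ATG---AAATTT",
            "sp1": "ATGCCCAAATTT",
            "sp2": "ATGCCC---TTT",
        },
        reference_id="ref",
    )


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def write_pdb(path: Path, atoms) -> Path:
    """Write minimal fixed-column PDB ATOM/HETATM records.

    ``atoms``: iterable of (record, serial, name, resname, chain, resseq,
    x, y, z, element).
    """
    lines = []
    for rec, serial, name, resname, chain, resseq, x, y, z, element in atoms:
        lines.append(
            f"{rec:<6}{serial:>5} {name:^4} {resname:<3} {chain}{resseq:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def make_protein_chain(chain: str, residues, start_serial: int = 1):
    """Atom tuples for a chain of ALA-like residues.

    ``residues``: list of (resseq, [(name, element, x, y, z), ...]).
    """
    atoms = []
    serial = start_serial
    for resseq, atom_list in residues:
        for name, element, x, y, z in atom_list:
            atoms.append(("ATOM", serial, name, "ALA", chain, resseq, x, y, z, element))
            serial += 1
    return atoms


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
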