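"""In-frame codon alignments and pocket-position -> column mapping.

The consumed artifact is an in-frame codon multiple sequence alignment
(e.g. produced by a Pal2Nal-style back-translation) with one designated
mammalian reference record.  Frame integrity is enforced at load: every
record must have the same length, the length must be a multiple of three,
and gaps may only occur as whole-codon triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .genetics import ALL_CODON_INDEX, STOP_CODONS, GENETIC_CODE, translate

GAP_CODON = "---"


class FrameError(ValueError):
    """Raised when a record violates in-frame codon alignment invariants."""


@dataclass
class CodonAlignment:
    """A gapped, in-frame codon MSA with a designated reference record.

    Parameters
    ----------
    records : dict
        Mapping species id -> aligned coding sequence (uppercase enforced).
        Insertion order is preserved and is the canonical species order.
    reference_id : str
        Key of the reference (mammalian) record.
    """

    records: dict[str, str]
    reference_id: str

    def __post_init__(self) -> None:
        if self.reference_id not in self.records:
            raise KeyError(f"reference {self.reference_id!r} not in alignment")
        self.records = {k: v.upper() for k, v in self.records.items()}
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise FrameError(f"records have unequal lengths: {sorted(lengths)}")
        (self.length,) = lengths
        if self.length % 3 != 0:
            raise FrameError(f"alignment length {self.length} not a multiple of 3")
        for sp, seq in self.records.items():
            for i in range(0, self.length, 3):
                codon = seq[i : i + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise FrameError(f"{sp}: mid-codon gap at column {i}: {codon!r}")
        ref_ungapped = self.records[self.reference_id].replace("-", "")
        prot = translate(ref_ungapped)
        if "*" in prot[:-1]:
            raise FrameError("reference contains an internal stop codon")

    # -- basic accessors ------------------------------------------------

    @property
    def species(self) -> list[str]:
        return list(self.records)

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, species: str, column: int) -> str:
        """Codon of ``species`` at protein column ``column`` (0-based)."""
        seq = self.records[species]
        return seq[3 * column : 3 * column + 3]

    def amino_acid(self, species: str, column: int) -> str:
        codon = self.codon(species, column)
        if codon == GAP_CODON:
            return "-"
        return GENETIC_CODE.get(codon, "X")

    def codon_matrix(self) -> np.ndarray:
        """(n_species, n_codons) matrix of codon indices into ``ALL_CODONS``.

        Gap codons and codons with ambiguity characters are encoded as -1.
        """
        mat = np.full((len(self.records), self.n_codons), -1, dtype=np.int16)
        for i, seq in enumerate(self.records.values()):
            for j in range(self.n_codons):
                idx = ALL_CODON_INDEX.get(seq[3 * j : 3 * j + 3])
                if idx is not None:
                    mat[i, j] = idx
        return mat

    # -- serialisation --------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path, reference_id: str) -> "CodonAlignment":
        records = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise FrameError(f"duplicate record id {rec.id!r}")
            records[rec.id] = str(rec.seq)
        if not records:
            raise FrameError(f"no FASTA records in {path}")
        return cls(records=records, reference_id=reference_id)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sp, seq in self.records.items():
                fh.write(f">{sp}\n{seq}\n")


@dataclass
class ColumnSet:
    """Pocket columns of an alignment at protein and nucleotide resolution.

    ``protein_columns`` are 0-based protein-level alignment columns in the
    order the pocket positions were given; ``codon_columns`` holds the
    corresponding nucleotide column triples.
    """

    protein_columns: list[int]
    codon_columns: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.codon_columns:
            self.codon_columns = [(3 * c, 3 * c + 1, 3 * c + 2) for c in self.protein_columns]
        if len(self.codon_columns) != len(self.protein_columns):
            raise ValueError("codon_columns must be one triple per protein column")

    def __len__(self) -> int:
        return len(self.protein_columns)

    @classmethod
    def all_columns(cls, aln: CodonAlignment) -> "ColumnSet":
        return cls(protein_columns=list(range(aln.n_codons)))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_column_1based\tnt_columns_1based\n")
            for c, triple in zip(self.protein_columns, self.codon_columns):
                fh.write(f"{c + 1}\t{','.join(str(t + 1) for t in triple)}\n")


def map_positions_to_columns(aln: CodonAlignment, positions) -> ColumnSet:
    """Map 1-based ungapped reference residue positions to alignment columns.

    Column ``c`` is returned for position ``p`` iff the reference's p-th
    non-gap codon sits at protein column ``c``.  Order of ``positions``
    is preserved; the mapping is injective and order-preserving for
    sorted input.
    """
    pos_list = list(getattr(positions, "positions", positions))
    ref = aln.records[aln.reference_id]
    # ungapped residue index (1-based) -> protein column (0-based)
    residue_to_column = {}
    residue = 0
    for col in range(aln.n_codons):
        if ref[3 * col : 3 * col + 3] != GAP_CODON:
            residue += 1
            residue_to_column[residue] = col
    n_residues = residue
    cols = []
    for p in pos_list:
        if not 1 <= p <= n_residues:
            raise ValueError(
                f"pocket position {p} beyond reference length {n_residues}"
            )
        cols.append(residue_to_column[p])
    return ColumnSet(protein_columns=cols)


def slice_alignment(aln: CodonAlignment, cols: ColumnSet) -> CodonAlignment:
    """Sub-alignment restricted to the codon columns of ``cols``.

    Species order and the reference designation are preserved.  An empty
    column set yields a zero-length alignment over the same species.
    """
    for c in cols.protein_columns:
        if not 0 <= c < aln.n_codons:
            raise ValueError(f"column {c} out of range for {aln.n_codons}-codon alignment")
    records = {
        sp: "".join(seq[3 * c : 3 * c + 3] for c in cols.protein_columns)
        for sp, seq in aln.records.items()
    }
    return CodonAlignment(records=records, reference_id=aln.reference_id)
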