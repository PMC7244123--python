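"""Per-branch %ID, the Welch comparison and the within-branch N count."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketevo.alignment import CodonAlignment, ColumnSet
from pocketevo.branches import BranchScheme
from pocketevo.indexes import (
    compare_pocket_vs_whole,
    count_nonsyn_within_branch,
    pct_identity_pocket,
    pct_identity_whole,
)

AAA, AAG, CGT, TTT, TTC, GGG = "AAA", "AAG", "CGT", "TTT", "TTC", "GGG"


def _aln(records):
    return CodonAlignment(records=records, reference_id="ref")


def _scheme(**groups):
    return BranchScheme(
        groups=[(name, set(sp)) for name, sp in groups.items()],
        ligand_group_index=0,
    )


class TestPctIdentity:
    def test_identical_species_give_100(self):
        aln = _aln({"ref": AAA + TTT, "a": AAA + TTT, "b": AAA + TTT})
        scheme = _scheme(g=["a", "b", "ref"])
        value, per_species = pct_identity_pocket(aln, ColumnSet(protein_columns=[0, 1]), scheme, "g")
        assert value == 100.0
        assert set(per_species) == {"a", "b"}  # reference excluded

    def test_no_shared_pocket_residue_gives_0(self):
        aln = _aln({"ref": AAA + TTT, "a": CGT + GGG, "b": CGT + GGG})
        scheme = _scheme(g=["a", "b"])
        value, _ = pct_identity_pocket(aln, ColumnSet(protein_columns=[0, 1]), scheme, "g")
        assert value == 0.0

    def test_hand_counted_mean_87_5(self):
        # 4-column pocket; a matches 4/4, b matches 3/4 -> (100 + 75) / 2
        aln = _aln(
            {
                "ref": AAA + TTT + GGG + CGT,
                "a": AAA + TTT + GGG + CGT,
                "b": AAA + TTT + GGG + AAA,
            }
        )
        scheme = _scheme(g=["a", "b"])
        value, _ = pct_identity_pocket(aln, ColumnSet(protein_columns=[0, 1, 2, 3]), scheme, "g")
        assert value == pytest.approx(87.5)

    def test_synonymous_codon_still_matches_amino_acid(self):
        aln = _aln({"ref": TTT, "a": TTC})  # both Phe
        scheme = _scheme(g=["a"])
        value, _ = pct_identity_pocket(aln, ColumnSet(protein_columns=[0]), scheme, "g")
        assert value == 100.0

    def test_gap_counts_as_mismatch(self):
        aln = _aln({"ref": AAA + TTT, "a": AAA + "---"})
        scheme = _scheme(g=["a"])
        value, _ = pct_identity_pocket(aln, ColumnSet(protein_columns=[0, 1]), scheme, "g")
        assert value == 50.0

    def test_whole_sequence_hand_count(self):
        # 10 columns, species matches 6/10
        ref = AAA * 10
        sp = AAA * 6 + CGT * 4
        aln = _aln({"ref": ref, "a": sp})
        value, _ = pct_identity_whole(aln, _scheme(g=["a"]), "g")
        assert value == pytest.approx(60.0)

    def test_all_gap_species_excluded_with_sentinel_row(self):
        aln = _aln({"ref": AAA + TTT, "a": "------"})
        value, per = pct_identity_pocket(
            aln, ColumnSet(protein_columns=[0, 1]), _scheme(g=["a"]), "g"
        )
        assert math.isnan(value) and per == {}

    def test_bounds_always_respected(self, rng):
        from pocketevo.genetics import SENSE_CODONS

        for _ in range(20):
            seqs = {
                name: "".join(rng.choice(list(SENSE_CODONS), size=8))
                for name in ("ref", "a", "b", "c")
            }
            aln = _aln(seqs)
            value, per = pct_identity_whole(aln, _scheme(g=["a", "b", "c"]), "g")
            assert 0.0 <= value <= 100.0
            assert all(0.0 <= v <= 100.0 for v in per.values())


class TestComparePocketVsWhole:
    def test_identical_lists_give_p_1_direction_none(self):
        vals = {"a": 80.0, "b": 90.0, "c": 85.0}
        p, direction = compare_pocket_vs_whole(vals, dict(vals))
        assert p == 1.0 and direction == "none"

    def test_clearly_higher_pocket_detected(self):
        pocket = {s: v for s, v in zip("abcd", [95.0, 96.0, 97.0, 98.0])}
        whole = {s: v for s, v in zip("abcd", [60.0, 61.0, 62.0, 63.0])}
        p, direction = compare_pocket_vs_whole(pocket, whole)
        assert direction == "pocket-higher"
        assert p < 0.05
        # cross-check against the standard Welch formula
        from scipy import stats

        expected = stats.ttest_ind(
            [95, 96, 97, 98], [60, 61, 62, 63], equal_var=False
        ).pvalue
        assert p == pytest.approx(float(expected))

    def test_single_species_gives_sentinel(self):
        p, direction = compare_pocket_vs_whole({"a": 90.0}, {"a": 50.0})
        assert math.isnan(p) and direction == "none"

    def test_whole_higher_direction(self):
        pocket = {s: v for s, v in zip("abcd", [10.0, 11.0, 12.0, 13.0])}
        whole = {s: v for s, v in zip("abcd", [80.0, 81.0, 82.0, 83.0])}
        p, direction = compare_pocket_vs_whole(pocket, whole)
        assert direction == "whole-higher" and p < 0.05


class TestCountNonsyn:
    def _aln4(self, codons_by_species):
        return _aln({sp: "".join(cs) for sp, cs in codons_by_species.items()})

    def test_monomorphic_branch_gives_zero(self):
        aln = self._aln4({"ref": [AAA] * 4, "a": [AAA] * 4, "b": [AAA] * 4})
        n = count_nonsyn_within_branch(aln, ColumnSet(protein_columns=list(range(4))), ["a", "b"])
        assert n == 0

    def test_one_polymorphic_column(self):
        # column 0 has residues {K, R, R}: one amino-acid change
        aln = self._aln4(
            {
                "ref": [AAA] * 4,
                "a": [AAA, TTT, TTT, TTT],
                "b": [CGT, TTT, TTT, TTT],
                "c": [CGT, TTT, TTT, TTT],
            }
        )
        n = count_nonsyn_within_branch(
            aln, ColumnSet(protein_columns=list(range(4))), ["a", "b", "c"]
        )
        assert n == 1

    def test_five_columns_three_residues_each(self):
        # 5 columns x (3 distinct - 1) = 10
        rows = {
            "a": [AAA] * 5,
            "b": [CGT] * 5,
            "c": [TTT] * 5,
            "d": [TTT] * 5,
            "ref": [AAA] * 5,
        }
        aln = self._aln4(rows)
        n = count_nonsyn_within_branch(
            aln, ColumnSet(protein_columns=list(range(5))), ["a", "b", "c", "d"]
        )
        assert n == 10

    def test_synonymous_variation_not_counted(self):
        aln = self._aln4({"ref": [TTT], "a": [TTT], "b": [TTC]})
        n = count_nonsyn_within_branch(aln, ColumnSet(protein_columns=[0]), ["a", "b"])
        assert n == 0

    def test_gaps_ignored(self):
        aln = self._aln4({"ref": [AAA], "a": ["---"], "b": [AAA]})
        n = count_nonsyn_within_branch(aln, ColumnSet(protein_columns=[0]), ["a", "b"])
        assert n == 0

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_upper_bound_and_permutation_invariance(self, seed):
        from pocketevo.genetics import SENSE_CODONS

        rng = np.random.default_rng(seed)
        n_cols, n_species = 4, 4
        species = [f"s{i}" for i in range(n_species)]
        records = {"ref": "AAA" * n_cols}
        for sp in species:
            records[sp] = "".join(rng.choice(list(SENSE_CODONS), size=n_cols))
        aln = _aln(records)
        cols = ColumnSet(protein_columns=list(range(n_cols)))
        n = count_nonsyn_within_branch(aln, cols, species)
        assert 0 <= n <= n_cols * (n_species - 1)
        assert n == count_nonsyn_within_branch(aln, cols, species[::-1])
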