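"""Selection estimators: pairwise dN/dS, parsimony, branch and site scans."""

import math

import dendropy
import numpy as np
import pytest

from conftest import make_tree
from oracles import brute_pairwise_omega, brute_parsimony_score
from pocketevo.alignment import CodonAlignment, ColumnSet
from pocketevo.branches import BranchScheme, partition_edges
from pocketevo.genetics import SENSE_CODONS
from pocketevo.selection import (
    all_branch_omegas,
    branch_omega,
    fitch_reconstruct,
    pairwise_omega,
    positive_sites_in_pocket,
    site_selection_scan,
)


def random_codon_seq(rng, n):
    return "".join(rng.choice(list(SENSE_CODONS), size=n))


class TestPairwiseOmega:
    def test_identical_sequences_give_sentinel_omega(self):
        seq = "ATGAAATTTGGGCCC"
        est = pairwise_omega(seq, seq)
        assert est.nd == est.sd == 0
        assert est.dn == 0 and est.ds == 0
        assert math.isnan(est.omega)

    def test_single_synonymous_third_position_change(self):
        base = ["AAA"] * 25
        other = base.copy()
        other[10] = "AAG"  # Lys -> Lys
        est = pairwise_omega("".join(base), "".join(other))
        assert est.nd == 0 and est.sd == 1
        assert est.dn == 0 and est.ds > 0
        assert est.omega == 0

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(20):
            s1 = random_codon_seq(rng, 100)
            s2 = random_codon_seq(rng, 100)
            est = pairwise_omega(s1, s2)
            oracle = brute_pairwise_omega(s1, s2)
            for key in ("nd", "sd", "n_sites", "s_sites"):
                assert getattr(est, key) == pytest.approx(oracle[key], abs=1e-9)
            for key in ("dn", "ds"):
                a, b = getattr(est, key), oracle[key]
                assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b, abs=1e-9)

    def test_symmetry(self, rng):
        s1 = random_codon_seq(rng, 60)
        s2 = random_codon_seq(rng, 60)
        a, b = pairwise_omega(s1, s2), pairwise_omega(s2, s1)
        assert a.nd == pytest.approx(b.nd)
        assert a.sd == pytest.approx(b.sd)
        assert a.n_sites == pytest.approx(b.n_sites)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_omega("ATG", "ATGATG")

    def test_gapped_and_stop_codons_skipped(self):
        est = pairwise_omega("ATG---TAAAAA", "ATGCCCTAAAAA")
        assert est.n_codons == 2  # ATG and AAA only


class TestFitch:
    def test_monomorphic_states_score_zero(self):
        tree = make_tree("((L1,L2),(L3,L4));")
        res = fitch_reconstruct(tree, {f"L{i}": "A" for i in range(1, 5)})
        assert res.score == 0
        assert all(s == "A" for s in res.resolved.values())

    def test_balanced_split_scores_one(self):
        tree = make_tree("((L1,L2),(L3,L4));")
        res = fitch_reconstruct(tree, {"L1": "A", "L2": "A", "L3": "B", "L4": "B"})
        assert res.score == 1

    def test_missing_leaf_state_is_wildcard(self):
        tree = make_tree("((L1,L2),(L3,L4));")
        res = fitch_reconstruct(tree, {"L1": "A", "L2": "A", "L3": "B"})
        assert res.score == 1  # L4 free

    def test_matches_exhaustive_minimum_on_random_trees(self, rng):
        states = ["A", "C", "G", "T"]
        for rep in range(60):
            n_leaves = int(rng.integers(3, 7))
            taxa = [f"t{i}" for i in range(n_leaves)]
            # random bifurcating topology by sequential joining
            nodes = list(taxa)
            children = {}
            nxt = 0
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
                a, b = nodes[j], nodes[i]
                name = f"n{nxt}"
                nxt += 1
                children[name] = [nodes.pop(j), nodes.pop(i)]
                nodes.append(name)
            root = nodes[0]

            def newick(node):
                if node in children:
                    return "(" + ",".join(newick(c) for c in children[node]) + ")"
                return node

            tree = make_tree(newick(root) + ";")
            k = int(rng.integers(2, 5))
            leaf_states = {t: states[int(rng.integers(0, k))] for t in taxa}
            res = fitch_reconstruct(tree, leaf_states)
            expected = brute_parsimony_score(children, leaf_states, states[:k])
            assert res.score == expected, f"rep {rep}"

    def test_resolution_is_deterministic(self):
        tree = make_tree("((L1,L2),(L3,L4));")
        states = {"L1": "A", "L2": "B", "L3": "A", "L4": "B"}
        r1 = fitch_reconstruct(tree, states)
        r2 = fitch_reconstruct(tree, states)
        assert [r1.resolved[n] for n in tree.preorder_node_iter()] == [
            r2.resolved[n] for n in tree.preorder_node_iter()
        ]


def _two_group_setup(records):
    aln = CodonAlignment(records=records, reference_id="m1")
    tree = make_tree("((m1:1,m2:1):1,(f1:1,f2:1):1);")
    scheme = BranchScheme(
        groups=[("fish", {"f1", "f2"}), ("mammals", {"m1", "m2"})],
        ligand_group_index=0,
    )
    partition = partition_edges(tree, scheme)
    return aln, tree, scheme, partition


class TestBranchOmega:
    def test_single_synonymous_change_lands_in_its_group(self):
        # m2 carries one synonymous change (AAA->AAG) on its pendant edge
        records = {
            "m1": "ATGAAATTTGGG",
            "m2": "ATGAAGTTTGGG",
            "f1": "ATGAAATTTGGG",
            "f2": "ATGAAATTTGGG",
        }
        aln, tree, scheme, partition = _two_group_setup(records)
        cols = ColumnSet(protein_columns=[0, 1, 2, 3])
        est_m = branch_omega(tree, aln, cols, partition, "mammals")
        est_f = branch_omega(tree, aln, cols, partition, "fish")
        assert est_m.sd == pytest.approx(1.0) and est_m.nd == 0
        assert est_f.sd == 0 and est_f.nd == 0
        assert est_m.omega == 0  # dn = 0 with ds > 0

    def test_nonsynonymous_change_counts_as_nd(self):
        records = {
            "m1": "ATGAAATTTGGG",
            "m2": "ATGAAATTTGGG",
            "f1": "ATGCCATTTGGG",  # AAA->CCA (both pathways non-synonymous)
            "f2": "ATGCCATTTGGG",
        }
        aln, tree, scheme, partition = _two_group_setup(records)
        cols = ColumnSet(protein_columns=[0, 1, 2, 3])
        totals = all_branch_omegas(tree, aln, cols, partition)
        assert totals["fish"].nd + totals["mammals"].nd == pytest.approx(2.0)
        assert totals["fish"].sd + totals["mammals"].sd == pytest.approx(0.0)

    def test_multi_hit_codon_pathway_averaged(self):
        # AAA(K)->CGA(R): of the two stop-free pathways one passes through
        # AGA(R), whose second step is synonymous -> (1.5, 0.5)
        records = {
            "m1": "ATGAAATTTGGG",
            "m2": "ATGAAATTTGGG",
            "f1": "ATGCGATTTGGG",
            "f2": "ATGCGATTTGGG",
        }
        aln, tree, scheme, partition = _two_group_setup(records)
        cols = ColumnSet(protein_columns=[0, 1, 2, 3])
        est = branch_omega(tree, aln, cols, partition, "fish")
        assert est.nd == pytest.approx(1.5)
        assert est.sd == pytest.approx(0.5)

    def test_group_sums_equal_whole_tree_counts(self, rng):
        """Partition conservation: per-group Nd/Sd sum to the all-edges total."""
        from pocketevo.simulate import SCENARIO_SCHEDULES, default_case_tree, SimulationConfig, simulate_alignment
        from pocketevo.simulate import default_pocket_columns

        tree, scheme = default_case_tree(2)
        pocket = default_pocket_columns(60, 6)
        cfg = SimulationConfig(
            tree=tree, scheme=scheme, n_codons=60, pocket_columns=pocket,
            omega_schedule=SCENARIO_SCHEDULES["S2"], seed=99,
        )
        aln = simulate_alignment(cfg)
        cols = ColumnSet(protein_columns=pocket)
        partition = partition_edges(tree, scheme)
        per_group = all_branch_omegas(tree, aln, cols, partition)
        single_group = BranchScheme(
            groups=[("all", set(aln.species))], ligand_group_index=0
        )
        whole = all_branch_omegas(
            tree, aln, cols, partition_edges(tree, single_group)
        )["all"]
        assert sum(e.nd for e in per_group.values()) == pytest.approx(whole.nd)
        assert sum(e.sd for e in per_group.values()) == pytest.approx(whole.sd)

    def test_empty_column_set_rejected(self):
        records = {sp: "ATGAAA" for sp in ("m1", "m2", "f1", "f2")}
        aln, tree, scheme, partition = _two_group_setup(records)
        with pytest.raises(ValueError):
            branch_omega(tree, aln, ColumnSet(protein_columns=[]), partition, "fish")


class TestSiteScan:
    def test_monomorphic_columns_are_uninformative(self):
        records = {sp: "ATGAAATTTGGG" for sp in ("m1", "m2", "f1", "f2")}
        aln, tree, *_ = _two_group_setup(records)
        call = site_selection_scan(tree, aln)
        assert (call.table["class"] == "uninformative").all()

    def test_strong_nonsynonymous_column_called_positive(self):
        """A column with many amino-acid changes and no synonymous ones
        across many edges is flagged positive."""
        n_leaves = 24
        taxa = [f"t{i:02d}" for i in range(n_leaves)]
        newick = f"({taxa[0]}:1,{taxa[1]}:1)"
        for t in taxa[2:]:
            newick = f"({newick}:1,{t}:1)"
        tree = make_tree(newick + ";")
        # column 1 alternates Pro (CCA) / Gln (CAA) along the caterpillar:
        # every change is a single non-synonymous transversion
        records = {
            t: "ATG" + ("CCA" if i % 2 == 0 else "CAA") + "GGGCCCAAA"
            for i, t in enumerate(taxa)
        }
        aln = CodonAlignment(records=records, reference_id="t00")
        call = site_selection_scan(tree, aln, alpha=0.05)
        assert call.table.loc[1, "nd"] >= 10
        assert call.table.loc[1, "sd"] == 0
        assert call.table.loc[1, "class"] == "positive"

    def test_neutralish_column_not_positive(self):
        records = {
            "m1": "ATGAAATTTGGG",
            "m2": "ATGAAGTTTGGG",
            "f1": "ATGAAATTCGGG",
            "f2": "ATGAAATTTGGG",
        }
        aln, tree, *_ = _two_group_setup(records)
        call = site_selection_scan(tree, aln)
        assert "positive" not in set(call.table["class"])


class TestPositiveSitesInPocket:
    def test_intersection_logic(self):
        class FakeCall:
            positive_columns = [10, 55]

        flag, hits = positive_sites_in_pocket(FakeCall(), ColumnSet(protein_columns=[55, 60]))
        assert flag and hits == [55]
        flag, hits = positive_sites_in_pocket(FakeCall(), ColumnSet(protein_columns=[7]))
        assert not flag and hits == []

    def test_no_positive_sites(self):
        class FakeCall:
            positive_columns = []

        flag, hits = positive_sites_in_pocket(FakeCall(), ColumnSet(protein_columns=[1, 2]))
        assert not flag and hits == []
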