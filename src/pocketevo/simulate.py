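"""Codon-evolution simulator and synthetic scenario families.

Sequences evolve along a tree by a continuous-time codon process with
single-nucleotide changes only: the rate of codon i -> j is

    kappa^[transition] * pi_j * f(omega)

where f is 1 for synonymous changes, omega for non-synonymous changes
and 0 for changes into a stop codon.  omega depends on the edge's
position relative to the ligand-appearance branch (pre / appearance /
post) and on the site class (pocket / background).  Rates are scaled so
one unit of branch length equals one expected substitution per codon
under neutrality (omega = 1) at the stationary codon frequencies —
the usual codon-model normalisation.  Simulation is exact (Gillespie)
per codon along each edge; no indels and no stop codons are ever
produced.

``generate_case`` packages a complete synthetic receptor family (codon
alignment, tree, branch scheme, pocket definition) under one of the
three scenario selection regimes, and ``recovery_benchmark`` runs the
whole pipeline over many such cases to measure how often the classifier
recovers the generating scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .alignment import CodonAlignment, ColumnSet
from .branches import DEFAULT_GROUP_NAMES, BranchScheme, partition_edges
from .classifier import Thresholds, classify
from .genetics import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, TRANSITIONS

BranchClass = str  # "pre" | "appearance" | "post"
SiteClass = str  # "pocket" | "background"

#: omega schedules defining the three scenario regimes.
SCENARIO_SCHEDULES: dict[str, dict[tuple[BranchClass, SiteClass], float]] = {
    "S1": {
        ("pre", "pocket"): 0.02, ("appearance", "pocket"): 0.02, ("post", "pocket"): 0.02,
        ("pre", "background"): 0.4, ("appearance", "background"): 0.4, ("post", "background"): 0.4,
    },
    "S2": {
        ("pre", "pocket"): 1.0, ("appearance", "pocket"): 1.5, ("post", "pocket"): 1.5,
        ("pre", "background"): 0.2, ("appearance", "background"): 0.2, ("post", "background"): 0.2,
    },
    "S3": {
        ("pre", "pocket"): 1.5, ("appearance", "pocket"): 1.5, ("post", "pocket"): 0.02,
        ("pre", "background"): 0.3, ("appearance", "background"): 0.3, ("post", "background"): 0.3,
    },
}

# Default case geometry (branch lengths in expected substitutions per
# codon).  The family emulates a receptor present since the first
# metazoans: the four pre-vertebrate groups sit on long stems (their
# real orthologs are several hundred My apart), the vertebrate-and-later
# radiation is much shallower, and within-group diversity is small.
PENDANT_LENGTH = 0.07
DEEP_STEM_LENGTH = 2.0  # opisthokonts .. deuterostomians
SHALLOW_STEM_LENGTH = 1.2  # vertebrates .. mammals
N_DEEP_GROUPS = 4
BACKBONE_LENGTH = 0.8
#: mammals are the densest-sampled taxon in real ortholog sets and the
#: reference needs enough close conspecifics for the within-group tests
N_MAMMAL_SPECIES = 5
MAMMAL_PENDANT_LENGTH = 0.04
REFERENCE_ID = "mammals_ref"


@dataclass
class SimulationConfig:
    """Everything needed to simulate one codon alignment."""

    tree: dendropy.Tree
    scheme: BranchScheme
    n_codons: int
    pocket_columns: list[int]
    omega_schedule: dict[tuple[BranchClass, SiteClass], float]
    kappa: float = 2.0
    codon_frequencies: np.ndarray | None = None  # over SENSE_CODONS; None = equal
    seed: int = 0
    reference_id: str = REFERENCE_ID

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if any(not 0 <= c < self.n_codons for c in self.pocket_columns):
            raise ValueError("pocket columns out of range")
        for v in self.omega_schedule.values():
            if not np.isfinite(v) or v < 0:
                raise ValueError("omega values must be finite and >= 0")
        if self.codon_frequencies is not None:
            f = np.asarray(self.codon_frequencies, dtype=float)
            if f.shape != (len(SENSE_CODONS),) or not np.isclose(f.sum(), 1.0):
                raise ValueError("codon frequencies must be a simplex over sense codons")
            self.codon_frequencies = f


class _CodonProcess:
    """Precomputed neighbour/rate tables for the single-nucleotide codon process."""

    def __init__(self, kappa: float, freqs: np.ndarray | None):
        ns = len(SENSE_CODONS)
        self.freqs = np.full(ns, 1.0 / ns) if freqs is None else freqs
        sense_index = {c: i for i, c in enumerate(SENSE_CODONS)}
        self.nbr_target = np.full((ns, 9), -1, dtype=np.int64)
        self.nbr_weight = np.zeros((ns, 9))
        self.nbr_syn = np.zeros((ns, 9), dtype=bool)
        for i, codon in enumerate(SENSE_CODONS):
            k = 0
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    nbr = codon[:pos] + base + codon[pos + 1 :]
                    if nbr not in STOP_CODONS:
                        j = sense_index[nbr]
                        w = (kappa if (codon[pos], base) in TRANSITIONS else 1.0) * self.freqs[j]
                        self.nbr_target[i, k] = j
                        self.nbr_weight[i, k] = w
                        self.nbr_syn[i, k] = GENETIC_CODE[codon] == GENETIC_CODE[nbr]
                    k += 1
        self.syn_rate = (self.nbr_weight * self.nbr_syn).sum(axis=1)
        self.nonsyn_rate = (self.nbr_weight * ~self.nbr_syn).sum(axis=1)
        # normalise: 1 unit of branch length = 1 expected neutral substitution/codon
        mean_neutral = float(self.freqs @ (self.syn_rate + self.nonsyn_rate))
        self.scale = 1.0 / mean_neutral

    def total_rate(self, codons: np.ndarray, omega: float) -> np.ndarray:
        return self.scale * (self.syn_rate[codons] + omega * self.nonsyn_rate[codons])

    def evolve(self, codons: np.ndarray, t: float, omega: float, rng: np.random.Generator):
        """Evolve codon indices in place for time ``t`` at a single omega."""
        if t <= 0 or len(codons) == 0:
            return codons
        rates = self.total_rate(codons, omega)
        waits = rng.exponential(1.0, size=len(codons)) / np.where(rates > 0, rates, np.inf)
        for idx in np.flatnonzero(waits < t):
            elapsed = waits[idx]
            state = codons[idx]
            while elapsed < t:
                w = self.nbr_weight[state] * np.where(self.nbr_syn[state], 1.0, omega)
                total = w.sum()
                if total <= 0:
                    break
                state = self.nbr_target[state, rng.choice(9, p=w / total)]
                rate = self.scale * (self.syn_rate[state] + omega * self.nonsyn_rate[state])
                elapsed += rng.exponential(1.0) / rate if rate > 0 else np.inf
            codons[idx] = state
        return codons


def _edge_branch_class(edge, scheme: BranchScheme) -> BranchClass:
    gi = scheme.index_of(edge.pocketevo_group)
    if gi < scheme.ligand_group_index:
        return "pre"
    if gi == scheme.ligand_group_index:
        return "appearance"
    return "post"


def simulate_alignment(cfg: SimulationConfig) -> CodonAlignment:
    """Simulate a gapless in-frame codon alignment under the config.

    The root sequence is drawn from the codon frequencies; each edge is
    evolved with the omega looked up from (edge branch class, site
    class).  Reproducible: one child RNG stream per edge, spawned
    deterministically from the master seed in preorder edge order.
    """
    partition_edges(cfg.tree, cfg.scheme)  # annotates edge.pocketevo_group
    process = _CodonProcess(cfg.kappa, cfg.codon_frequencies)

    pocket_mask = np.zeros(cfg.n_codons, dtype=bool)
    pocket_mask[list(cfg.pocket_columns)] = True

    master = np.random.SeedSequence(cfg.seed)
    edges = [n.edge for n in cfg.tree.preorder_node_iter() if n is not cfg.tree.seed_node]
    streams = master.spawn(len(edges) + 1)
    root_rng = np.random.default_rng(streams[0])

    root_seq = root_rng.choice(len(SENSE_CODONS), size=cfg.n_codons, p=process.freqs)
    seqs = {id(cfg.tree.seed_node): root_seq}
    leaf_seqs: dict[str, np.ndarray] = {}
    for edge, stream in zip(edges, streams[1:]):
        rng = np.random.default_rng(stream)
        node = edge.head_node
        seq = seqs[id(node.parent_node)].copy()
        t = edge.length or 0.0
        bclass = _edge_branch_class(edge, cfg.scheme)
        omega_pocket = cfg.omega_schedule[(bclass, "pocket")]
        omega_bg = cfg.omega_schedule[(bclass, "background")]
        # background first, then pocket: fixed order keeps streams reproducible
        bg = seq[~pocket_mask]
        process.evolve(bg, t, omega_bg, rng)
        seq[~pocket_mask] = bg
        pk = seq[pocket_mask]
        process.evolve(pk, t, omega_pocket, rng)
        seq[pocket_mask] = pk
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = seq
        else:
            seqs[id(node)] = seq

    records = {
        sp: "".join(SENSE_CODONS[i] for i in leaf_seqs[sp])
        for sp in sorted(leaf_seqs)
    }
    return CodonAlignment(records=records, reference_id=cfg.reference_id)


# ---------------------------------------------------------------------------
# scenario case generation


@dataclass
class SyntheticCase:
    """A complete synthetic receptor family with a known true scenario."""

    alignment: CodonAlignment
    tree: dendropy.Tree
    scheme: BranchScheme
    pocket_positions: list[int]  # 1-based reference residue positions
    true_label: str
    seed: int = 0

    @property
    def pocket_columns(self) -> ColumnSet:
        # the simulated alignment has no gaps, so positions map 1:1 to columns
        return ColumnSet(protein_columns=[p - 1 for p in self.pocket_positions])

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.alignment.to_fasta(out / "alignment.fasta")
        self.tree.write(path=str(out / "tree.nwk"), schema="newick",
                        suppress_rooting=True, unquoted_underscores=True)
        self.scheme.to_yaml(out / "scheme.yaml")
        with open(out / "pocket.tsv", "w") as fh:
            fh.write("receptor_id\tposition\n")
            for p in self.pocket_positions:
                fh.write(f"synthetic_{self.true_label}\t{p}\n")


def default_case_tree(
    n_species_per_group: int = 3,
    pendant: float = PENDANT_LENGTH,
    stems: list[float] | float | None = None,
    backbone: float = BACKBONE_LENGTH,
) -> tuple[dendropy.Tree, BranchScheme]:
    """Clade-ladder tree over the 10 default taxonomic groups.

    Each group is a star clade of ``n_species_per_group`` species on a
    stem; the mammalian group additionally contains the designated
    reference.  The ladder orders groups from the most ancestral
    (splitting at the root) to mammals.  ``stems`` may be one length per
    group; the default is depth-graded — long stems for the four
    pre-vertebrate groups, short ones for the vertebrate radiation —
    mirroring the divergence profile of real metazoan-wide ortholog
    sets.
    """
    if stems is None:
        stems = [DEEP_STEM_LENGTH] * N_DEEP_GROUPS + [SHALLOW_STEM_LENGTH] * (
            len(DEFAULT_GROUP_NAMES) - N_DEEP_GROUPS
        )
    elif isinstance(stems, (int, float)):
        stems = [float(stems)] * len(DEFAULT_GROUP_NAMES)
    subtrees = []
    groups: list[tuple[str, set[str]]] = []
    for name, stem in zip(DEFAULT_GROUP_NAMES, stems):
        if name == "mammals":
            n_sp, tip_len = N_MAMMAL_SPECIES, MAMMAL_PENDANT_LENGTH
        else:
            n_sp, tip_len = n_species_per_group, pendant
        species = [f"{name}_sp{i + 1}" for i in range(n_sp)]
        if name == "mammals":
            species.append(REFERENCE_ID)
        tips = ",".join(f"{sp}:{tip_len}" for sp in species)
        subtrees.append(f"({tips}):{stem}")
        groups.append((name, set(species)))
    node = f"({subtrees[-2]},{subtrees[-1]})"
    for sub in reversed(subtrees[:-2]):
        node = f"({sub},{node}:{backbone})"
    tree = dendropy.Tree.get(data=node + ";", schema="newick", preserve_underscores=True)
    scheme = BranchScheme(groups=groups, ligand_group_index=DEFAULT_GROUP_NAMES.index("vertebrates"))
    return tree, scheme


def default_pocket_columns(n_codons: int = 500, n_pocket: int = 50) -> list[int]:
    """Evenly spaced pocket columns (0-based)."""
    return [round(i * n_codons / n_pocket) for i in range(n_pocket)]


def generate_case(
    true_label: str,
    seed: int,
    n_codons: int = 500,
    n_pocket: int = 50,
    n_species_per_group: int = 3,
    kappa: float = 2.0,
    schedule: dict | None = None,
) -> SyntheticCase:
    """Simulate a receptor family under one scenario's selection regime."""
    if true_label not in SCENARIO_SCHEDULES:
        raise ValueError(f"true_label must be one of {sorted(SCENARIO_SCHEDULES)}")
    tree, scheme = default_case_tree(n_species_per_group)
    pocket = default_pocket_columns(n_codons, n_pocket)
    cfg = SimulationConfig(
        tree=tree,
        scheme=scheme,
        n_codons=n_codons,
        pocket_columns=pocket,
        omega_schedule=schedule or SCENARIO_SCHEDULES[true_label],
        kappa=kappa,
        seed=seed,
    )
    aln = simulate_alignment(cfg)
    return SyntheticCase(
        alignment=aln,
        tree=tree,
        scheme=scheme,
        pocket_positions=[c + 1 for c in pocket],
        true_label=true_label,
        seed=seed,
    )


def analyze_case(case: SyntheticCase, thresholds: Thresholds | None = None):
    """Run indexes + selection + classification on a synthetic case."""
    from .indexes import build_index_table  # local import avoids a cycle

    partition = partition_edges(case.tree, case.scheme)
    table = build_index_table(
        case.alignment, case.pocket_columns, case.scheme, case.tree, partition
    )
    call = classify(table, case.scheme, thresholds)
    return table, call


def neutral_omega_estimate(
    omega: float,
    seed: int,
    n_codons: int = 500,
    n_taxa: int = 8,
    edge_length: float = 0.2,
    kappa: float = 2.0,
):
    """Simulate a single-regime family and re-estimate its dN/dS.

    A balanced ``n_taxa`` tree with uniform edge lengths is evolved with
    the given omega at every site and edge; the per-branch counting
    estimator is then run over all columns and all edges, returning the
    whole-tree OmegaEstimate.  Used for the parameter-recovery checks.
    """
    from .selection import all_branch_omegas

    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = [f"{t}:{edge_length}" for t in taxa]
    while len(nodes) > 1:
        nodes = [
            f"({nodes[i]},{nodes[i + 1]}):{edge_length}" if i + 1 < len(nodes) else nodes[i]
            for i in range(0, len(nodes), 2)
        ]
    tree = dendropy.Tree.get(data=nodes[0] + ";", schema="newick", preserve_underscores=True)
    scheme = BranchScheme(groups=[("all", set(taxa))], ligand_group_index=0)
    schedule = {
        (b, s): omega for b in ("pre", "appearance", "post") for s in ("pocket", "background")
    }
    cfg = SimulationConfig(
        tree=tree, scheme=scheme, n_codons=n_codons,
        pocket_columns=list(range(n_codons)), omega_schedule=schedule,
        kappa=kappa, seed=seed, reference_id=taxa[0],
    )
    aln = simulate_alignment(cfg)
    cols = ColumnSet(protein_columns=list(range(n_codons)))
    partition = partition_edges(tree, scheme)
    est = all_branch_omegas(tree, aln, cols, partition, kappa=kappa)["all"]
    return est, tree, aln


def recovery_benchmark(
    n_cases_per_label: int,
    seed: int,
    labels: tuple[str, ...] = ("S1", "S2", "S3"),
    schedules: dict[str, dict] | None = None,
    thresholds: Thresholds | None = None,
    **case_kwargs,
):
    """Confusion matrix and recovery rate of the full pipeline.

    Generates ``n_cases_per_label`` families per scenario (deterministic
    given ``seed``), pushes each through indexes -> selection ->
    classification, and tabulates true vs called labels.  ``schedules``
    may override the omega schedule used for a given true label (for
    negative controls).
    """
    if n_cases_per_label < 1:
        raise ValueError("n_cases_per_label must be >= 1")
    rng = np.random.default_rng(seed)
    called_labels = ["S1", "S2", "S3", "UNCLASSIFIED"]
    confusion = pd.DataFrame(0, index=list(labels), columns=called_labels)
    for label in labels:
        for _ in range(n_cases_per_label):
            case_seed = int(rng.integers(2**31))
            schedule = (schedules or {}).get(label)
            case = generate_case(label, case_seed, schedule=schedule, **case_kwargs)
            _, call = analyze_case(case, thresholds)
            confusion.loc[label, call.label] += 1
    correct = sum(confusion.loc[lb, lb] for lb in labels if lb in confusion.columns)
    rate = correct / confusion.to_numpy().sum()
    return confusion, float(rate)
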