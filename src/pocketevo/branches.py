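"""Taxonomic branch scheme, tree handling and edge partitioning.

The animal tree of life is summarised as an ordered list of "main
branches" (taxonomic groups, most ancestral first, mammals last).  Each
alignment species belongs to exactly one group, and one group is marked
as the branch in which the receptor's first ligand appeared; that group
and every more derived group are "ligand-present".

Per-branch statistics need tree *edges* assigned to groups.  The rule
used here: an edge belongs to the most ancestral group found among the
leaves that descend from it.  Edges inside a group's clade therefore get
that group, and backbone stem edges get the group diverging at that
depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import yaml

#: Default 10-group template mirroring the major divergence branches of
#: the animal tree (fill in the species lists before use).
DEFAULT_GROUP_NAMES = [
    "opisthokonts",
    "metazoans",
    "bilaterians",
    "deuterostomians",
    "vertebrates",
    "teleosts",
    "sarcopterygians",
    "tetrapods",
    "amniotes",
    "mammals",
]


@dataclass
class BranchScheme:
    """Ordered taxonomic groups with species assignments and ligand origin."""

    groups: list[tuple[str, set[str]]]  # (name, species), ancestral -> derived
    ligand_group_index: int

    def __post_init__(self) -> None:
        names = [g[0] for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names in branch scheme")
        seen: set[str] = set()
        for name, species in self.groups:
            dup = seen & set(species)
            if dup:
                raise ValueError(f"species assigned to more than one group: {sorted(dup)}")
            seen |= set(species)
        if not 0 <= self.ligand_group_index < len(self.groups):
            raise ValueError(f"ligand group index {self.ligand_group_index} out of range")

    @property
    def group_names(self) -> list[str]:
        return [g[0] for g in self.groups]

    @property
    def all_species(self) -> set[str]:
        out: set[str] = set()
        for _, sp in self.groups:
            out |= sp
        return out

    def group_of(self, species: str) -> str:
        for name, members in self.groups:
            if species in members:
                return name
        raise KeyError(f"species {species!r} not assigned to any group")

    def index_of(self, group_name: str) -> int:
        try:
            return self.group_names.index(group_name)
        except ValueError:
            raise KeyError(f"unknown group {group_name!r}; known: {self.group_names}")

    def species_of(self, group_name: str) -> set[str]:
        return set(self.groups[self.index_of(group_name)][1])

    def validate_against(self, species: set[str]) -> None:
        """Check the scheme covers exactly the given alignment species."""
        missing = species - self.all_species
        if missing:
            raise ValueError(f"alignment species missing from branch scheme: {sorted(missing)}")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "groups": [{"name": n, "species": sorted(sp)} for n, sp in self.groups],
            "ligand_group": self.group_names[self.ligand_group_index],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def load_branch_scheme(path: str | Path) -> BranchScheme:
    """Load a BranchScheme from YAML (``groups:`` list + ``ligand_group:``)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "groups" not in doc or "ligand_group" not in doc:
        raise ValueError(f"{path}: expected mapping with 'groups' and 'ligand_group'")
    groups = [(g["name"], set(g.get("species", []))) for g in doc["groups"]]
    names = [n for n, _ in groups]
    ligand = doc["ligand_group"]
    if ligand not in names:
        raise ValueError(f"ligand_group {ligand!r} is not one of the groups {names}")
    return BranchScheme(groups=groups, ligand_group_index=names.index(ligand))


def ligand_present(scheme: BranchScheme, group_name: str) -> bool:
    """True iff the ligand exists in ``group_name``.

    The branch of appearance itself counts as ligand-present.
    """
    return scheme.index_of(group_name) >= scheme.ligand_group_index


# ---------------------------------------------------------------------------
# trees


def load_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")
    return tree


def ensure_rooted(tree: dendropy.Tree, scheme: BranchScheme) -> dendropy.Tree:
    """Root an unrooted tree on the edge separating the most ancestral group.

    Trees whose seed node already has two children are returned unchanged.
    """
    root = tree.seed_node
    if len(root.child_nodes()) <= 2:
        return tree
    ancestral = None
    for name, members in tree_groups_in_order(scheme):
        present = [lf for lf in tree.leaf_node_iter() if lf.taxon.label in members]
        if present:
            ancestral = present
            break
    if not ancestral:
        raise ValueError("no scheme species found in tree")
    if len(ancestral) == 1:
        node = ancestral[0]
    else:
        node = tree.mrca(taxa=[lf.taxon for lf in ancestral])
    if node is tree.seed_node:  # fall back: reroot above the first ancestral leaf
        node = ancestral[0]
    tree.reroot_at_edge(node.edge, update_bipartitions=False)
    return tree


def tree_groups_in_order(scheme: BranchScheme):
    yield from scheme.groups


def partition_edges(tree: dendropy.Tree, scheme: BranchScheme) -> dict[str, list]:
    """Assign every edge to the most ancestral group among its descendant leaves.

    Returns a mapping group name -> list of dendropy ``Edge`` objects; every
    edge below the seed node appears in exactly one list.  Each edge also
    receives a ``pocketevo_group`` attribute for downstream use.
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    scheme.validate_against(leaf_labels)
    extra = scheme.all_species - leaf_labels
    # species in the scheme but absent from this tree are tolerated (the
    # scheme may be a template covering more species than were sampled)
    _ = extra

    min_index: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            min_index[id(node)] = scheme.index_of(scheme.group_of(node.taxon.label))
        else:
            min_index[id(node)] = min(min_index[id(ch)] for ch in node.child_nodes())

    partition: dict[str, list] = {name: [] for name in scheme.group_names}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        group = scheme.group_names[min_index[id(node)]]
        node.edge.pocketevo_group = group
        partition[group].append(node.edge)
    return partition


def partition_to_tsv(partition: dict[str, list], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group\tedge_subtending_leaves\tlength\n")
        for group, edges in partition.items():
            for edge in edges:
                leaves = sorted(
                    lf.taxon.label for lf in edge.head_node.leaf_iter()
                )
                fh.write(f"{group}\t{','.join(leaves)}\t{edge.length}\n")
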