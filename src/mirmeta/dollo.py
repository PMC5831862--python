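"""Dollo parsimony gain/loss reconstruction on a labelled species tree.

Each family is gained exactly once; its gain node is the most recent common
ancestor of the species possessing it, and losses fall on the branches to the
maximal subtrees below the gain node that contain no possessing species.  This
is the loss-minimizing single-gain assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import pandas as pd


class SpeciesTree:
    """Rooted tree whose leaves are species and whose internal nodes carry
    taxon names (e.g. Chordata).  Unnamed internal nodes get synthetic names.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        self._tree = tree
        self._name_nodes()
        self.leaves = [nd.taxon.label for nd in tree.leaf_node_iter()]
        if len(self.leaves) < 2:
            raise ValueError("degenerate tree: need at least 2 leaves")
        if len(set(self.leaves)) != len(self.leaves):
            raise ValueError("duplicate leaf names")
        self._node_by_name = {self.node_name(nd): nd for nd in tree}
        if len(self._node_by_name) != sum(1 for _ in tree):
            raise ValueError("duplicate internal node names")

    @classmethod
    def from_newick(cls, source: str | Path) -> "SpeciesTree":
        text = str(source)
        if "(" not in text:  # a path, not a newick string
            text = Path(source).read_text()
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls(tree)

    def _name_nodes(self) -> None:
        counter = 0
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf():
                if nd.taxon is None:
                    raise ValueError("leaf without a name")
            elif not nd.label:
                nd.label = f"node{counter}"
            counter += 1

    @staticmethod
    def node_name(node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    def node(self, name: str) -> dendropy.Node:
        return self._node_by_name[name]

    def node_names(self) -> list[str]:
        return [self.node_name(nd) for nd in self._tree.preorder_node_iter()]

    def leaves_under(self, name: str) -> set[str]:
        return {nd.taxon.label for nd in self.node(name).leaf_iter()}

    def mrca(self, leaf_names: Sequence[str]) -> str:
        taxa = set(leaf_names)
        missing = taxa - set(self.leaves)
        if missing:
            raise ValueError(f"leaves not in tree: {sorted(missing)}")
        if len(taxa) == 1:
            return next(iter(taxa))
        node = self._tree.mrca(taxon_labels=list(taxa))
        return self.node_name(node)

    def children(self, name: str) -> list[str]:
        return [self.node_name(c) for c in self.node(name).child_nodes()]

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class FamilyHistory:
    family: str
    gain_node: str
    loss_branches: frozenset[str]  # identified by the child node of the edge
    present_leaves: frozenset[str]


@dataclass
class DolloReconstruction:
    tree: SpeciesTree
    families: dict[str, FamilyHistory] = field(default_factory=dict)


def _loss_branches(
    tree: SpeciesTree, gain: str, present: set[str]
) -> frozenset[str]:
    """Branches to maximal subtrees under the gain node with no present leaf."""
    losses: set[str] = set()

    def walk(node: dendropy.Node) -> bool:
        # returns True iff subtree contains a present leaf
        if node.is_leaf():
            return node.taxon.label in present
        any_present = False
        child_flags = []
        for child in node.child_nodes():
            flag = walk(child)
            child_flags.append((child, flag))
            any_present = any_present or flag
        if any_present:
            for child, flag in child_flags:
                if not flag:
                    losses.add(tree.node_name(child))
        return any_present

    walk(tree.node(gain))
    return frozenset(losses)


def dollo_reconstruct(
    matrix: pd.DataFrame, tree: SpeciesTree
) -> DolloReconstruction:
    """Reconstruct the single-gain / multiple-loss history of each family.

    ``matrix`` is the binary families x species table; its columns must match
    the tree leaves and every row must have at least one present species.
    """
    if set(matrix.columns) != set(tree.leaves):
        raise ValueError("matrix columns do not match tree leaves")
    recon = DolloReconstruction(tree=tree)
    for fam, row in matrix.iterrows():
        present = {sp for sp in matrix.columns if row[sp]}
        if not present:
            raise ValueError(f"family {fam}: present in no species")
        gain = tree.mrca(sorted(present))
        losses = (
            frozenset()
            if gain in present and len(present) == 1
            else _loss_branches(tree, gain, present)
        )
        recon.families[str(fam)] = FamilyHistory(
            family=str(fam),
            gain_node=gain,
            loss_branches=losses,
            present_leaves=frozenset(present),
        )
    return recon


def assign_acquisition(history: FamilyHistory, tree: SpeciesTree) -> str:
    """Named taxon at whose origin the family arose.

    The gain node is the MRCA of the present species, so presence necessarily
    spans >= 2 of its daughter lineages (unless the family is confined to one
    species, in which case the species name is reported as a terminal gain).
    Unnamed internal nodes report their synthetic name.
    """
    node = tree.node(history.gain_node)
    if node.is_leaf():
        return node.taxon.label
    spanning = sum(
        1
        for child in node.child_nodes()
        if {nd.taxon.label for nd in child.leaf_iter()} & history.present_leaves
    )
    assert spanning >= 2, "MRCA must span >=2 daughter lineages"
    return history.gain_node


def node_summary(
    recon: DolloReconstruction, focal_species: str | None = None
) -> pd.DataFrame:
    """Per-node acquisition/loss table (the +/- annotations of a taxonomy
    figure): families acquired at the node, loss events on the branch leading
    to the node, and acquired families retained in ``focal_species``.
    """
    tree = recon.tree
    if focal_species is not None and focal_species not in tree.leaves:
        raise ValueError(f"focal species {focal_species!r} not a tree leaf")
    names = tree.node_names()
    acquired = {n: 0 for n in names}
    lost = {n: 0 for n in names}
    retained = {n: 0 for n in names}
    for hist in recon.families.values():
        acquired[hist.gain_node] += 1
        for branch in hist.loss_branches:
            lost[branch] += 1
        if focal_species is not None and focal_species in hist.present_leaves:
            retained[hist.gain_node] += 1
    out = pd.DataFrame(
        {
            "node": names,
            "acquired": [acquired[n] for n in names],
            "lost": [lost[n] for n in names],
            "retained_in_focal": [retained[n] for n in names],
        }
    ).set_index("node")
    if focal_species is None:
        out = out.drop(columns=["retained_in_focal"])
    return out


def write_assignments(
    recon: DolloReconstruction, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("family\tgain_node\tn_losses\tloss_branches\tpresent_species\n")
        for fam in sorted(recon.families):
            h = recon.families[fam]
            fh.write(
                "\t".join(
                    [
                        fam,
                        assign_acquisition(h, recon.tree),
                        str(len(h.loss_branches)),
                        ",".join(sorted(h.loss_branches)) or "-",
                        ",".join(sorted(h.present_leaves)),
                    ]
                )
                + "\n"
            )
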