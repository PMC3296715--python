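"""Calibrated species tree: rooted, ultrametric, node ages in My.

Thin wrapper around a dendropy tree. Branches are addressed by the label of
their child node (taxon name for terminal branches); internal nodes must be
labeled in the input newick or are auto-labeled ``node<k>`` in preorder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import dendropy

from .types import ValidationError

AGE_TOL = 1e-6  # My; ultrametricity tolerance


@dataclass(frozen=True)
class Branch:
    label: str  # child node label
    parent_label: str
    parent_age: float
    child_age: float

    @property
    def duration(self) -> float:
        return self.parent_age - self.child_age

    @property
    def is_terminal(self) -> bool:
        # leaves have age 0 in an ultrametric tree
        return self.child_age <= AGE_TOL


class CalibratedTree:
    """Rooted bifurcating ultrametric tree with node ages in My."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._label_nodes()
        self._compute_ages()
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "CalibratedTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "CalibratedTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- internals -----------------------------------------------------

    def _label_nodes(self) -> None:
        k = 0
        for node in self.tree.preorder_node_iter():
            if node.taxon is not None and node.taxon.label:
                node.label = node.taxon.label.replace(" ", "_")
            elif not node.label:
                node.label = f"node{k}"
                k += 1

    def _compute_ages(self) -> None:
        # depth from root, then age = max_depth - depth
        depth: Dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depth[node] = 0.0
            else:
                depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        leaf_depths = [depth[lf] for lf in self.tree.leaf_node_iter()]
        self._max_depth = max(leaf_depths)
        self._leaf_depth_spread = self._max_depth - min(leaf_depths)
        self._age = {node.label: self._max_depth - d for node, d in depth.items()}
        self._node_by_label = {node.label: node for node in depth}

    def _validate(self) -> None:
        if self._leaf_depth_spread > AGE_TOL:
            depths = {
                lf.label: round(self._max_depth - self._age[lf.label], 6)
                for lf in self.tree.leaf_node_iter()
            }
            raise ValidationError(
                "tree is not ultrametric; root-to-leaf depth spread "
                f"{self._leaf_depth_spread:.6g} My exceeds {AGE_TOL}: {depths}"
            )
        for br in self.branches():
            if not br.parent_age > br.child_age >= -AGE_TOL:
                raise ValidationError(
                    f"branch {br.label}: parent_age {br.parent_age} must exceed "
                    f"child_age {br.child_age}"
                )

    # -- queries -------------------------------------------------------

    @property
    def taxa(self) -> List[str]:
        return [lf.label for lf in self.tree.leaf_node_iter()]

    @property
    def root_label(self) -> str:
        return self.tree.seed_node.label

    @property
    def root_age(self) -> float:
        return self._age[self.root_label]

    def node_age(self, label: str) -> float:
        return self._age[label]

    def has_node(self, label: str) -> bool:
        return label in self._node_by_label

    def node(self, label: str):
        return self._node_by_label[label]

    def branches(self) -> List[Branch]:
        """All branches as (child-label, parent-label, parent_age, child_age)."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            out.append(
                Branch(
                    label=node.label,
                    parent_label=node.parent_node.label,
                    parent_age=self._age[node.parent_node.label],
                    child_age=self._age[node.label],
                )
            )
        return out

    def branch(self, label: str) -> Branch:
        for br in self.branches():
            if br.label == label:
                return br
        raise KeyError(label)

    def leaves_under(self, label: str) -> List[str]:
        node = self._node_by_label[label]
        if node.is_leaf():
            return [node.label]
        return [lf.label for lf in node.leaf_iter()]

    def mrca_label(self, taxa) -> str:
        return self.tree.mrca(taxon_labels=list(taxa)).label

    def recent_branches(self, cutoff_my: float) -> List[Branch]:
        """Branches that arose (parent node age) within the last cutoff My."""
        return [b for b in self.branches() if b.parent_age <= cutoff_my + AGE_TOL]

    def without_taxa(self, drop) -> "CalibratedTree":
        tree = self.tree.clone(depth=1)
        tree.prune_taxa_with_labels(list(drop))
        return CalibratedTree(tree)


# ---------------------------------------------------------------------------
# Packaged 11-taxon Drosophila fixture
# ---------------------------------------------------------------------------

#: Consensus topology of the 11 sequenced Drosophila species with
#: TimeTree-style node ages (My). The mosquito outgroup attaches at 470 My.
DROSOPHILA_TREE_NEWICK = (
    "(((((("
    "D_melanogaster:5.4,(D_simulans:2.3,D_sechellia:2.3)sim_sec:3.1)mel_sim_sec:7.4,"
    "(D_yakuba:10.4,D_erecta:10.4)yak_ere:2.4)melanogaster_subgroup:31.4,"
    "D_ananassae:44.2)melanogaster_group:1.8,"
    "D_persimilis:46.0)obscura_join:7.0,"
    "D_willistoni:53.0)Sophophora:10.0,"
    "((D_mojavensis:19.0,D_virilis:19.0)moj_vir:23.0,"
    "D_grimshawi:42.0)Drosophila_subgenus:21.0)Drosophila_Sophophora;"
)

#: Same tree with the dipteran outgroup (A. gambiae analogue) at 470 My.
DROSOPHILA_TREE_WITH_OUTGROUP_NEWICK = (
    "(" + DROSOPHILA_TREE_NEWICK[:-1].replace(
        ")Drosophila_Sophophora", ")Drosophila_Sophophora:407.0"
    ) + ",A_gambiae:470.0)root;"
)

#: The ten branches used for genus-average rate estimation: terminal
#: branches younger than ~20 My plus the three recent internal branches
#: (the melanogaster-subgroup stem is clipped at the cutoff age).
RECENT_BRANCH_LABELS = [
    "D_melanogaster",
    "D_simulans",
    "D_sechellia",
    "D_yakuba",
    "D_erecta",
    "D_mojavensis",
    "D_virilis",
    "sim_sec",
    "yak_ere",
    "melanogaster_subgroup",
]


def drosophila_tree(with_outgroup: bool = False) -> CalibratedTree:
    """The packaged calibrated 11-taxon tree (optionally with outgroup)."""
    nwk = (
        DROSOPHILA_TREE_WITH_OUTGROUP_NEWICK if with_outgroup else DROSOPHILA_TREE_NEWICK
    )
    return CalibratedTree.from_newick(nwk)
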