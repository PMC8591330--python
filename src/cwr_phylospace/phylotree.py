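"""Phylogenetic tree parsing, the comparison tree, and tip-to-root path indexing.

Faith's PD sums the branch lengths connecting a set of tips to the root.
The conventions here are the standard ones: the root has no subtending
edge (so PD of the full taxon set equals total tree length), zero-length
branches are legal and contribute nothing, and polytomies are processed
as-is. The *comparison tree* used by relative PD (RPD) keeps the topology
but sets every branch length to the mean of the strictly positive observed
branch lengths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from cwr_phylospace.errors import TreeError

logger = logging.getLogger(__name__)


class PhyloTree:
    """Rooted tree with branch lengths, backed by a :class:`dendropy.Tree`.

    Invariants enforced at construction: unique tip labels, finite
    non-negative branch lengths, a single root whose edge (if present in
    the source file) is discarded with a warning.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        root = tree.seed_node
        if root.edge.length not in (None, 0, 0.0):
            warnings.warn(
                "tree has a root edge length; ignored (the root has no subtending branch)",
                stacklevel=2,
            )
        root.edge.length = None
        labels = []
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if label is None or not str(label).strip():
                raise TreeError("tree has an unlabelled tip")
            labels.append(str(label))
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            bl = node.edge.length
            if bl is None:
                node.edge.length = 0.0
            elif not np.isfinite(bl) or bl < 0:
                raise TreeError(f"branch length {bl!r} is not finite and >= 0")
        self._tree = tree

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [str(leaf.taxon.label) for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def branch_lengths(self) -> list[float]:
        """Lengths of all non-root branches, preorder."""
        root = self._tree.seed_node
        return [
            float(n.edge.length)
            for n in self._tree.preorder_node_iter()
            if n is not root
        ]

    @property
    def total_length(self) -> float:
        return float(sum(self.branch_lengths()))

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path, schema: str = "newick") -> None:
        self._tree.write(
            path=str(path),
            schema=schema,
            suppress_rooting=(schema == "newick"),
            real_value_format_specifier=".12g",
        )


def read_tree(path, schema: str | None = None) -> PhyloTree:
    """Read a rooted tree from newick or nexus.

    ``schema`` is inferred from the file suffix when omitted (.nex/.nexus
    -> nexus, otherwise newick). Quoted labels are unquoted; underscores
    are NOT converted to spaces (curated species lists use exact names).
    """
    path = Path(path)
    if schema is None:
        schema = "nexus" if path.suffix.lower() in {".nex", ".nexus", ".nxs"} else "newick"
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema=schema,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeError(f"cannot parse {path} as {schema}: {exc}") from exc
    return PhyloTree(tree)


def parse_newick(newick: str) -> PhyloTree:
    """Parse a newick string directly."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise TreeError(f"cannot parse newick string: {exc}") from exc
    return PhyloTree(tree)


def mean_nonzero_branch_length(tree: PhyloTree) -> float:
    lengths = np.array(tree.branch_lengths(), dtype=float)
    positive = lengths[lengths > 0]
    if positive.size == 0:
        raise TreeError("all branch lengths are zero; cannot form a comparison tree")
    return float(positive.mean())


def comparison_tree(tree: PhyloTree) -> PhyloTree:
    """Same topology, every branch set to the mean non-zero branch length.

    Originally zero-length branches also receive the mean, so the
    comparison tree's total length is (branch count) x (non-zero mean).
    """
    mean_bl = mean_nonzero_branch_length(tree)
    clone = tree.dendropy_tree.clone(depth=1)
    root = clone.seed_node
    for node in clone.preorder_node_iter():
        if node is not root:
            node.edge.length = mean_bl
    return PhyloTree(clone)


@dataclass
class TipPathIndex:
    """Per-tip branch sets enabling fast PD over arbitrary tip subsets.

    ``path_matrix[i, j]`` is True when branch ``j`` lies on tip ``i``'s
    path to the root; ``branch_lengths[j]`` is that branch's length.
    """

    tip_labels: list[str]
    path_matrix: np.ndarray  # (n_tips, n_branches) bool
    branch_lengths: np.ndarray  # (n_branches,) float

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_branches(self) -> int:
        return self.branch_lengths.size

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    def tip_index(self) -> dict[str, int]:
        return {label: i for i, label in enumerate(self.tip_labels)}

    def path_lengths(self, tip_label: str) -> list[float]:
        """Branch lengths on one tip's root path (tip edge first)."""
        i = self.tip_index()[tip_label]
        cols = np.nonzero(self.path_matrix[i])[0]
        return [float(self.branch_lengths[c]) for c in cols]


def build_tip_path_index(tree: PhyloTree) -> TipPathIndex:
    """Enumerate non-root branches and each tip's branch set."""
    dtree = tree.dendropy_tree
    root = dtree.seed_node
    branch_ids: dict[int, int] = {}
    lengths: list[float] = []
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        branch_ids[id(node)] = len(lengths)
        lengths.append(float(node.edge.length))

    leaves = list(dtree.leaf_node_iter())
    path = np.zeros((len(leaves), len(lengths)), dtype=bool)
    for i, leaf in enumerate(leaves):
        node = leaf
        while node is not root:
            path[i, branch_ids[id(node)]] = True
            node = node.parent_node
    return TipPathIndex(
        tip_labels=[str(leaf.taxon.label) for leaf in leaves],
        path_matrix=path,
        branch_lengths=np.array(lengths, dtype=float),
    )
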