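"""Tree-sample I/O and the Brownian-motion covariance structure.

Trees are held as :class:`dendropy.Tree` objects (rooted, dated, branch
lengths in time units).  The covariance matrix C implied by Brownian motion
on a tree has C[i, j] equal to the root-to-MRCA path length shared by tips
i and j, and C[i, i] equal to the root-to-tip distance; it is the common
input of both the phylogenetic-signal and correlation machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np


class TreeError(ValueError):
    """Raised for malformed trees or tip-set mismatches."""


@dataclass
class PhyloCovariance:
    """BM covariance matrix with its tip ordering."""

    tip_order: tuple[str, ...]
    matrix: np.ndarray  # (n, n), symmetric PSD

    def __post_init__(self):
        n = len(self.tip_order)
        if self.matrix.shape != (n, n):
            raise TreeError(
                f"covariance shape {self.matrix.shape} != ({n}, {n})"
            )

    def submatrix(self, tips: Sequence[str]) -> "PhyloCovariance":
        idx = [self.tip_order.index(t) for t in tips]
        return PhyloCovariance(
            tip_order=tuple(tips), matrix=self.matrix[np.ix_(idx, idx)]
        )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _normalize_label(label: str) -> str:
    return " ".join(label.split())


def read_trees(path, format: str = "nexus") -> dendropy.TreeList:
    """Read an ordered tree sample from Newick or NEXUS.

    NEXUS translate tables are resolved; tip labels are whitespace-
    normalized.  The file order defines the sample index.  All trees are
    interpreted as rooted at their first node, as is conventional for dated
    posterior samples.
    """
    if format not in ("newick", "nexus"):
        raise TreeError(f"unknown tree format {format!r}")
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema=format,
            rooting="default-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises many parse error types
        raise TreeError(f"cannot parse {path}: {exc}") from exc
    for tree in trees:
        for taxon in tree.taxon_namespace:
            taxon.label = _normalize_label(taxon.label)
    return trees


def tree_from_newick(newick: str) -> dendropy.Tree:
    """Parse a single rooted tree from a Newick string."""
    try:
        return dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="default-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"cannot parse newick: {exc}") from exc


def write_trees(trees: Iterable[dendropy.Tree], path, format: str = "newick"):
    tl = dendropy.TreeList(trees)
    tl.write(path=str(path), schema=format)


def prune(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Restrict a tree to ``keep``, preserving patristic structure.

    Unifurcations are suppressed with branch lengths summed; the path from
    the original root down to the retained subtree is kept as the pruned
    tree's root edge, so the BM covariance of the pruned tree equals the
    corresponding submatrix of the full tree's covariance.
    """
    keep = {_normalize_label(k) for k in keep}
    labels = set(tip_labels(tree))
    missing = sorted(keep - labels)
    if missing:
        raise TreeError(f"tips not in tree: {', '.join(missing)}")
    pruned = tree.clone(depth=1)
    taxa = [tx for tx in pruned.taxon_namespace if tx.label in keep]
    pruned.retain_taxa(taxa)
    return pruned


def vcv(
    tree: dendropy.Tree, tip_order: Optional[Sequence[str]] = None
) -> PhyloCovariance:
    """Brownian-motion covariance matrix of a rooted tree.

    Each branch of length l ancestral to a set of tips contributes l to
    every entry of the covariance block of those tips; a root edge (e.g.
    left by pruning) is shared by all tips.  Duplicate rows caused by
    zero-length terminal branches are detected and flagged with a warning,
    since GLS needs an invertible matrix.
    """
    if tree.seed_node is None or len(tree.seed_node.child_nodes()) == 0:
        raise TreeError("tree has no internal structure")
    labels = tip_labels(tree)
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate tip labels")
    if tip_order is None:
        tip_order = labels
    else:
        tip_order = [_normalize_label(t) for t in tip_order]
        missing = sorted(set(tip_order) - set(labels))
        if missing:
            raise TreeError(f"tips not in tree: {', '.join(missing)}")
        if len(tip_order) != len(labels):
            raise TreeError(
                "tip_order must list every tip; prune the tree first"
            )
    index = {label: i for i, label in enumerate(tip_order)}
    n = len(tip_order)
    C = np.zeros((n, n))

    # postorder: collect tip indices below each node, add edge contributions
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            idx = np.array([index[node.taxon.label]])
        else:
            idx = np.concatenate(
                [below.pop(id(ch)) for ch in node.child_nodes()]
            )
        below[id(node)] = idx
        length = node.edge.length
        if length is None:
            if node is tree.seed_node:
                continue
            raise TreeError("branch without length")
        if length < 0:
            raise TreeError(f"negative branch length {length}")
        C[np.ix_(idx, idx)] += length

    for i in range(n):
        dup = np.flatnonzero(
            (np.abs(C - C[i]) < 1e-12).all(axis=1)
        )
        if dup.size > 1 and dup[0] == i:
            warnings.warn(
                f"identical covariance rows for tips "
                f"{[tip_order[j] for j in dup]}: zero-length terminal "
                f"branches make C singular",
                stacklevel=2,
            )
            break
    return PhyloCovariance(tip_order=tuple(tip_order), matrix=C)
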