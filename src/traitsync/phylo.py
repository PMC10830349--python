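"""Patristic distances from Newick phylogenies, with species-complex collapsing.

The patristic (cophenetic) distance between two tips is the sum of branch
lengths along the unique path connecting them.  Where field identification
cannot separate species (e.g. the *Bombus lucorum/terrestris* complex),
the member tips are collapsed into a single operational unit whose distance
to every other species is the arithmetic mean of the members' distances.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np

from .errors import FormatError, InvalidArgumentError
from .matrices import DistanceMatrix

__all__ = [
    "PhyloTree",
    "normalize_label",
    "parse_newick",
    "read_newick",
    "patristic_matrix",
    "collapse_complex",
]


def normalize_label(label: str) -> str:
    """Canonical tip label: trimmed, underscores as spaces, case preserved."""
    return " ".join(str(label).replace("_", " ").split())


class PhyloTree:
    """A rooted tree with branch lengths and unique, normalized tip labels."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise FormatError("unlabelled tip in tree")
            leaf.taxon.label = normalize_label(leaf.taxon.label)
            labels.append(leaf.taxon.label)
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise FormatError(f"duplicate tip label(s): {dupes}")
        self.tip_labels = labels
        self._check_lengths()

    def _check_lengths(self) -> None:
        root = self.tree.seed_node
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue  # the root edge may legitimately lack a length
            if node.edge.length is None:
                where = (
                    node.taxon.label
                    if node.taxon is not None
                    else "internal node above tips "
                    + "/".join(sorted(l.taxon.label for l in node.leaf_iter())[:3])
                )
                raise FormatError(f"missing branch length at {where!r}")
            if node.edge.length < 0:
                raise FormatError(f"negative branch length ({node.edge.length})")

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)


def parse_newick(text: str) -> PhyloTree:
    """Parse Newick text into a validated :class:`PhyloTree`.

    Polytomies and quoted labels are accepted; internal node labels are
    ignored.  Malformed text, duplicate tips or absent branch lengths raise
    :class:`FormatError` naming the offending token.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise FormatError(f"malformed Newick: {exc}") from exc
    return PhyloTree(tree)


def read_newick(path: str | Path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def patristic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distance matrix."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    labels = sorted(tree.tip_labels)
    taxa = {t.label: t for t in tree.tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels, D, name="patristic")


def collapse_complex(D: DistanceMatrix, members, label: str) -> DistanceMatrix:
    """Merge ``members`` into one unit at mean distance to every other tip.

    The new row/column ``label`` gets ``d(label, x) = mean_m d(m, x)`` over
    the members, and ``d(label, label) = 0``.  The mean may break
    ultrametricity; only symmetry/nonnegativity/zero-diagonal survive by
    construction.
    """
    members = [normalize_label(m) for m in members]
    if len(members) < 2:
        raise InvalidArgumentError("a species complex needs at least 2 members")
    absent = [m for m in members if m not in D.labels]
    if absent:
        raise InvalidArgumentError(f"complex member(s) absent from matrix: {absent}")
    if label in set(D.labels) - set(members):
        raise InvalidArgumentError(f"complex label {label!r} collides with an existing tip")
    keep = [l for l in D.labels if l not in members]
    idx_keep = [D.labels.index(l) for l in keep]
    idx_mem = [D.labels.index(m) for m in members]
    base = D.values[np.ix_(idx_keep, idx_keep)]
    mean_to_others = D.values[np.ix_(idx_mem, idx_keep)].mean(axis=0)
    n = len(keep) + 1
    out = np.zeros((n, n))
    out[: len(keep), : len(keep)] = base
    out[-1, : len(keep)] = mean_to_others
    out[: len(keep), -1] = mean_to_others
    return DistanceMatrix(keep + [label], out, name=D.name)
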