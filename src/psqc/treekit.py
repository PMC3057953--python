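"""Trees, bipartitions, patristic distances and clade support.

Trees are :class:`dendropy.Tree` objects; this module fixes the Newick
conventions used throughout the package (internal node labels are
bootstrap supports on the 0-100 scale, branch lengths are expected
substitutions per site) and provides the split-based operations the
congruence and taxon-sampling analyses rely on: bipartition extraction
under the unrooted interpretation, split compatibility, induced
subtrees, and path-length (patristic) distance matrices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .msa_io import PsqcError

logger = logging.getLogger(__name__)

__all__ = [
    "Tree",
    "Bipartition",
    "DistanceMatrix",
    "parse_newick",
    "read_newick",
    "write_newick",
    "leaf_labels",
    "bipartitions",
    "split_support_map",
    "patristic_matrix",
    "restrict",
    "compatible",
    "clade_support",
]

#: The tree container used throughout the package.
Tree = dendropy.Tree


class NewickError(PsqcError):
    """Malformed Newick input."""


# ----------------------------------------------------------------------
# Bipartitions
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class Bipartition:
    """A canonical two-way split of a taxon set.

    ``side_a`` is the side containing the lexicographically smallest
    taxon; a split is trivial when one side is a single taxon.
    """

    side_a: frozenset
    side_b: frozenset

    @classmethod
    def from_sides(cls, a: Iterable[str], b: Iterable[str]) -> "Bipartition":
        a, b = frozenset(a), frozenset(b)
        if not a or not b:
            raise ValueError("both sides of a bipartition must be non-empty")
        if a & b:
            raise ValueError("bipartition sides must be disjoint")
        if min(a) > min(b):
            a, b = b, a
        return cls(side_a=a, side_b=b)

    @property
    def taxa(self) -> frozenset:
        return self.side_a | self.side_b

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) == 1

    def __str__(self) -> str:
        fmt = lambda s: ",".join(sorted(s))
        return f"{fmt(self.side_a)} | {fmt(self.side_b)}"


def compatible(split: Bipartition, reference_splits: Iterable[Bipartition]) -> bool:
    """Can ``split`` coexist with every reference split in one tree?

    Two splits on the same taxon set are compatible iff at least one of
    the four pairwise side intersections is empty.
    """
    for ref in reference_splits:
        if ref.taxa != split.taxa:
            raise ValueError(
                "splits are defined on different taxon sets: "
                f"{sorted(split.taxa ^ ref.taxa)} not shared"
            )
        if not (
            not (split.side_a & ref.side_a)
            or not (split.side_a & ref.side_b)
            or not (split.side_b & ref.side_a)
            or not (split.side_b & ref.side_b)
        ):
            return False
    return True


# ----------------------------------------------------------------------
# Distance matrices
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with NaN marking undefined pairs."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        v = self.values
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxa in distance matrix")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(v - v.T), initial=0.0) > 1e-12:
                raise ValueError("distance matrix is not symmetric")
            if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
                raise ValueError("distance matrix diagonal is not zero")
            if np.nanmin(v, initial=0.0) < -1e-12:
                raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def index(self, taxon: str) -> int:
        return self.taxa.index(taxon)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.index(a), self.index(b)])

    def is_defined(self) -> bool:
        return not np.isnan(self.values).any()

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if math.isnan(self.values[i, j]):
                    out.append((self.taxa[i], self.taxa[j]))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


# ----------------------------------------------------------------------
# Newick I/O
# ----------------------------------------------------------------------


def parse_newick(text: str) -> Tree:
    """Parse a Newick string.

    Internal node labels that read as numbers in [0, 100] are bootstrap
    supports (values in [0, 1] are rescaled to 0-100 with a warning) and
    are stored as ``edge.support``.  Missing branch lengths default to 0
    with a warning; negative lengths are an error.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"Newick parse failed: {exc}") from exc

    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate leaf labels: {dup}")

    warned_missing = False
    for node in tree.preorder_node_iter():
        edge = node.edge
        if node is tree.seed_node:
            edge.length = None
            edge.support = None
            continue
        if edge.length is None:
            if not warned_missing:
                logger.warning("missing branch length(s); defaulting to 0")
                warned_missing = True
            edge.length = 0.0
        if edge.length < 0:
            raise NewickError(f"negative branch length {edge.length}")
        edge.support = None
        if not node.is_leaf() and node.label is not None:
            try:
                value = float(node.label)
            except ValueError:
                value = None
            if value is not None and 0.0 <= value <= 100.0:
                if value <= 1.0:
                    logger.warning(
                        "support %s interpreted on the 0-1 scale; rescaling to 0-100",
                        node.label,
                    )
                    value *= 100.0
                edge.support = value
                node.label = None
    return tree


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def _format_number(x: float) -> str:
    """Shortest decimal string that round-trips to the same float."""
    if x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(float(x))


def _quote_label(label: str) -> str:
    if any(c in label for c in "():;, '\t\n[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, path=None) -> str:
    """Serialize a tree to Newick, supports as internal node labels."""

    def fmt(node) -> str:
        if node.is_leaf():
            body = _quote_label(node.taxon.label if node.taxon else (node.label or ""))
        else:
            inner = ",".join(fmt(c) for c in node.child_nodes())
            support = getattr(node.edge, "support", None)
            label = _format_number(support) if support is not None else (node.label or "")
            body = f"({inner}){label}"
        if node.parent_node is None:
            return body
        length = node.edge.length if node.edge.length is not None else 0.0
        return f"{body}:{_format_number(length)}"

    text = fmt(tree.seed_node) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


# ----------------------------------------------------------------------
# Tree interrogation
# ----------------------------------------------------------------------


def leaf_labels(tree: Tree) -> tuple[str, ...]:
    return tuple(lf.taxon.label for lf in tree.leaf_node_iter())


def _edge_splits(tree: Tree):
    """Yield ``(node, Bipartition)`` per edge, unrooted interpretation.

    The seed node's edge is skipped and duplicate root-adjacent splits
    collapse because bipartitions are canonical.
    """
    all_taxa = frozenset(leaf_labels(tree))
    below: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            acc = frozenset()
            for c in node.child_nodes():
                acc |= below[id(c)]
            below[id(node)] = acc
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = below[id(node)]
        other = all_taxa - side
        if not side or not other:
            continue
        yield node, Bipartition.from_sides(side, other)


def bipartitions(tree: Tree, include_trivial: bool = False) -> frozenset:
    """The set of bipartitions induced by the tree's edges."""
    if len(leaf_labels(tree)) < 2:
        raise ValueError("need at least 2 leaves")
    out = set()
    for _, split in _edge_splits(tree):
        if include_trivial or not split.is_trivial:
            out.add(split)
    return frozenset(out)


def split_support_map(tree: Tree) -> dict:
    """Map each non-trivial bipartition to its support (or None).

    When a rooted tree presents the same split on both root-adjacent
    edges, the maximum recorded support wins.
    """
    out: dict[Bipartition, float | None] = {}
    for node, split in _edge_splits(tree):
        if split.is_trivial:
            continue
        support = getattr(node.edge, "support", None)
        if split in out:
            prev = out[split]
            support = max(
                (s for s in (prev, support) if s is not None), default=None
            )
        out[split] = support
    return out


def patristic_matrix(tree: Tree) -> DistanceMatrix:
    """Path-length (patristic) distances between all leaf pairs."""
    leaves = list(tree.leaf_node_iter())
    taxa = tuple(lf.taxon.label for lf in leaves)
    adjacency: dict[int, list[tuple[object, float]]] = {}

    def add(u, v, w):
        adjacency.setdefault(id(u), []).append((v, w))
        adjacency.setdefault(id(v), []).append((u, w))

    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            add(node, child, child.edge.length or 0.0)

    n = len(leaves)
    values = np.zeros((n, n))
    for i, start in enumerate(leaves):
        dist = {id(start): 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adjacency.get(id(u), ()):
                if id(v) not in dist:
                    dist[id(v)] = dist[id(u)] + w
                    stack.append(v)
        for j, other in enumerate(leaves):
            values[i, j] = dist[id(other)]
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(taxa=taxa, values=values)


def restrict(tree: Tree, taxa: Iterable[str]) -> Tree:
    """Induced subtree on a taxon subset.

    Degree-2 nodes left by pruning are suppressed with branch lengths
    summed; supports on merged edges take the maximum of the merged
    values.  Patristic distances among retained taxa are unchanged.
    """
    keep = set(taxa)
    present = set(leaf_labels(tree))
    unknown = keep - present
    if unknown:
        raise KeyError(f"unknown taxa: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to restrict to")

    # operate on an independent copy; write/parse preserves lengths and
    # supports exactly (shortest round-trip formatting)
    copy = parse_newick(write_newick(tree))

    for leaf in list(copy.leaf_node_iter()):
        if leaf.taxon.label not in keep:
            leaf.parent_node.remove_child(leaf)

    changed = True
    while changed:
        changed = False
        for node in list(copy.postorder_node_iter()):
            if node.is_leaf() and node.taxon is not None:
                continue
            children = node.child_nodes()
            parent = node.parent_node
            if not children and parent is not None:
                # internal node whose leaves were all pruned
                parent.remove_child(node)
                changed = True
                break
            elif len(children) == 1 and parent is not None:
                child = children[0]
                merged_support = max(
                    (
                        s
                        for s in (
                            getattr(node.edge, "support", None),
                            getattr(child.edge, "support", None),
                        )
                        if s is not None
                    ),
                    default=None,
                )
                child.edge.length = (child.edge.length or 0.0) + (
                    node.edge.length or 0.0
                )
                child.edge.support = merged_support
                node.remove_child(child)
                parent.add_child(child)
                parent.remove_child(node)
                changed = True
                break
    # collapse a degree-1 seed node
    while len(copy.seed_node.child_nodes()) == 1:
        new_seed = copy.seed_node.child_nodes()[0]
        if new_seed.is_leaf():
            break
        copy.seed_node.remove_child(new_seed)
        new_seed.parent_node = None
        new_seed.edge.length = None
        new_seed.edge.support = None
        copy.seed_node = new_seed
    return copy


def clade_support(tree: Tree, taxa: Iterable[str]):
    """Support of the edge isolating exactly ``taxa``.

    Returns the support value (NaN when the edge exists but carries no
    support) or ``None`` when no edge induces that clade.
    """
    target = frozenset(taxa)
    leaves = frozenset(leaf_labels(tree))
    if not target or not target < leaves:
        raise ValueError("taxa must be a proper non-empty subset of the leaves")
    for node, split in _edge_splits(tree):
        if split.side_a == target or split.side_b == target:
            support = getattr(node.edge, "support", None)
            return float(support) if support is not None else math.nan
    return None
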