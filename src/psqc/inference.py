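"""Distance-based tree inference: p-distances, corrections, NJ, bootstrap.

This is the desk-scale engine standing in for the heavyweight ML and
Bayesian programs that large phylogenomic studies run externally.  It is
deliberately simple — s-state Poisson/gamma distance corrections of the
Jukes-Cantor family and neighbor joining — because that is enough to
reproduce, with known ground truth, the phenomena the diagnostics are
about: undetected multiple substitutions (saturation) and the
long-branch artifacts they cause.

Uncorrected (p) distances use pairwise deletion: each pair is compared
over the columns where neither sequence is missing, since supermatrices
routinely miss half their cells and complete deletion could discard
every column.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .msa_io import Alignment, PsqcError, SuperMatrix
from .treekit import DistanceMatrix, Tree, bipartitions, _edge_splits

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceModel",
    "p_distance",
    "correct_distance",
    "corrected_matrix",
    "neighbor_joining",
    "bootstrap_support",
]


@dataclass(frozen=True)
class DistanceModel:
    """How observed proportions of difference map to distances.

    ``uncorrected`` returns p itself; ``poisson`` inverts the s-state
    equal-rates substitution process; ``gamma`` additionally allows
    gamma-distributed rate variation across sites with shape
    ``gamma_shape`` (small shapes imply strong rate heterogeneity and a
    harsher correction).  ``n_states`` is 4 for nucleotides, 20 for
    amino acids.
    """

    kind: str = "poisson"
    gamma_shape: float | None = None
    n_states: int = 20

    def __post_init__(self) -> None:
        if self.kind not in ("uncorrected", "poisson", "gamma"):
            raise ValueError(f"unknown distance model kind {self.kind!r}")
        if self.n_states not in (4, 20):
            raise ValueError("n_states must be 4 or 20")
        if self.kind == "gamma":
            if self.gamma_shape is None or not (
                np.isfinite(self.gamma_shape) and self.gamma_shape > 0
            ):
                raise ValueError("gamma model needs a finite positive shape")


def _data_and_missing(source: Alignment | SuperMatrix):
    if isinstance(source, SuperMatrix):
        return source.alignment.data, source.missing_mask(), source.taxa
    return source.data, source.missing_mask(), source.taxa


def _p_matrix(data: np.ndarray, missing: np.ndarray):
    """Pairwise p-distances and comparable-site counts (pairwise deletion)."""
    n = data.shape[0]
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    ok = ~missing
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ok[i] & ok[j]
            m = int(comparable.sum())
            counts[i, j] = counts[j, i] = m
            if m == 0:
                values[i, j] = values[j, i] = np.nan
            else:
                d = int(((data[i] != data[j]) & comparable).sum())
                values[i, j] = values[j, i] = d / m
    return values, counts


def p_distance(
    source: Alignment | SuperMatrix, return_counts: bool = False
):
    """Uncorrected distance matrix: proportion of differing sites.

    Pairs with zero mutually non-missing columns are flagged undefined
    (NaN).  For supermatrices the missing mask respects each
    partition's alphabet.
    """
    data, missing, taxa = _data_and_missing(source)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    values, counts = _p_matrix(data, missing)
    dm = DistanceMatrix(taxa=tuple(taxa), values=values)
    if return_counts:
        return dm, counts
    return dm


def correct_distance(p, model: DistanceModel):
    """Map p-distances to model-corrected distances.

    Accepts scalars or arrays.  Values at or beyond the saturation
    ceiling (s-1)/s are undefined and returned as NaN rather than
    raised, because saturated pairs are an expected, reportable outcome.
    """
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.nanmin(p, initial=0.0) < 0:
        raise ValueError("p-distances must be non-negative")
    b = (model.n_states - 1) / model.n_states
    out = np.full(p.shape, np.nan)
    defined = ~np.isnan(p) & (p < b)
    q = 1.0 - p[defined] / b
    if model.kind == "uncorrected":
        out[defined] = p[defined]
    elif model.kind == "poisson":
        out[defined] = -b * np.log(q)
    else:
        a = model.gamma_shape
        out[defined] = a * b * (q ** (-1.0 / a) - 1.0)
    if scalar:
        return float(out[0])
    return out


def corrected_matrix(
    source: Alignment | SuperMatrix, model: DistanceModel
) -> DistanceMatrix:
    """p-distance followed by model correction, as a DistanceMatrix."""
    dm = p_distance(source)
    values = correct_distance(dm.values, model)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(taxa=dm.taxa, values=values)


# ----------------------------------------------------------------------
# Neighbor joining
# ----------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Q-criterion ties are broken by the lexicographically smallest pair
    of cluster names (a cluster is named by its smallest member taxon),
    so permuting the input taxon order yields an isomorphic tree.
    Negative branch lengths are clamped to zero with the deficit moved
    to the sibling edge, preserving the joined pair's distance.  The
    result is an unrooted tree (trifurcating seed node).
    """
    if not dm.is_defined():
        raise PsqcError(
            "distance matrix has undefined entries for pairs "
            f"{dm.undefined_pairs()}; impute them or remove taxa"
        )
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    namespace = dendropy.TaxonNamespace(list(dm.taxa))
    nodes = []
    for taxon in dm.taxa:
        node = dendropy.Node()
        node.taxon = namespace.get_taxon(taxon)
        nodes.append(node)
    keys = list(dm.taxa)  # smallest member taxon per active cluster
    D = dm.values.copy()
    active = list(range(n))

    def pair_key(i: int, j: int):
        a, b = keys[i], keys[j]
        return (a, b) if a <= b else (b, a)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        # subtraction order makes q asymmetric at the ulp level; only
        # the upper triangle is searched, symmetrized by np.minimum
        q = np.minimum(q, q.T)
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a, b in zip(*np.where(q == qmin)):
            if a >= b:
                continue
            i, j = active[a], active[b]
            if best is None or pair_key(i, j) < pair_key(*best):
                best = (i, j)
        i, j = best
        ai, aj = active.index(i), active.index(j)
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        elif lj < 0:
            li += lj
            lj = 0.0

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = float(li)
        nodes[j].edge.length = float(lj)

        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        u = D.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = float(max(lk, 0.0))

    tree = dendropy.Tree(taxon_namespace=namespace)
    tree.seed_node = center
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        node.edge.support = None
    return tree


# ----------------------------------------------------------------------
# Nonparametric bootstrap
# ----------------------------------------------------------------------


def _nj_from_arrays(data, missing, taxa, model: DistanceModel) -> Tree:
    values, _ = _p_matrix(data, missing)
    corrected = correct_distance(values, model)
    np.fill_diagonal(corrected, 0.0)
    # saturated pairs (p beyond the correction ceiling) are capped at
    # slightly above the largest defined distance so a replicate can
    # still be resolved instead of aborting the bootstrap
    bad = np.isnan(corrected) & ~np.isnan(values)
    if bad.any():
        finite = corrected[~np.isnan(corrected)]
        cap = (finite.max() if finite.size else 1.0) * 1.05 + 1.0
        logger.debug("capping %d saturated pairs at %.3f", bad.sum() // 2, cap)
        corrected[bad] = cap
    return neighbor_joining(DistanceMatrix(taxa=tuple(taxa), values=corrected))


def bootstrap_support(
    source: Alignment | SuperMatrix,
    B: int,
    seed: int,
    model: DistanceModel,
) -> Tree:
    """NJ point tree with nonparametric bootstrap supports.

    Columns are resampled with replacement (ignoring partition
    boundaries); replicate ``r`` uses random seed ``seed + r``, so runs
    are reproducible and independent of replicate order.  Each internal
    edge of the point tree receives support = 100 x the fraction of
    replicate trees containing its bipartition.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    data, missing, taxa = _data_and_missing(source)
    point = _nj_from_arrays(data, missing, taxa, model)
    counts: dict = {s: 0 for s in bipartitions(point)}
    L = data.shape[1]
    for r in range(B):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, L, size=L)
        rep = _nj_from_arrays(data[:, cols], missing[:, cols], taxa, model)
        rep_splits = bipartitions(rep)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for node, split in _edge_splits(point):
        if not split.is_trivial and split in counts:
            node.edge.support = 100.0 * counts[split] / B
    return point
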