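"""Saturation and congruence diagnostics for phylogenomic datasets.

Two screens that quantify non-phylogenetic signal before it is allowed
to shape a phylogeny:

* **Saturation slope** — ordinary least squares of uncorrected
  p-distances on patristic distances (tree path lengths) over all
  shared taxon pairs: the slope of the classic saturation plot.
  Unsaturated data give slope 1; the more multiple substitutions go
  undetected in the observed distances, the flatter the plot and the
  smaller the slope.  Per-partition slopes rank genes by how little
  saturation they carry.

* **Congruence screen** — an a-posteriori orthology check: every
  well-supported bipartition of each single-gene tree is tested for
  compatibility against the concatenated reference tree restricted to
  that gene's taxa.  Supported conflicts point at contamination,
  paralogy or reconstruction error in that gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .msa_io import Alignment, PsqcError, SuperMatrix
from .treekit import (
    Bipartition,
    Tree,
    bipartitions,
    compatible,
    leaf_labels,
    patristic_matrix,
    restrict,
    split_support_map,
)
from .inference import p_distance

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "CongruenceReport",
    "saturation_slope",
    "saturation_by_partition",
    "congruence_screen",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of uncorrected (y) against patristic (x) distances."""

    slope: float
    intercept: float
    r_squared: float
    n_pairs: int
    excluded_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs < 3:
            raise ValueError("a reported slope needs at least 3 pairs")


def _pairs(source, tree: Tree):
    taxa = sorted(set(source.taxa) & set(leaf_labels(tree)))
    if len(taxa) < 3:
        raise PsqcError(
            f"only {len(taxa)} taxa shared between alignment and tree; need >= 3"
        )
    P = p_distance(source)
    T = patristic_matrix(tree)
    xs, ys, excluded = [], [], 0
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            p = P[a, b]
            if math.isnan(p):
                excluded += 1
                continue
            xs.append(T[a, b])
            ys.append(p)
    return np.array(xs), np.array(ys), excluded


def saturation_slope(
    source: Alignment | SuperMatrix, tree: Tree
) -> RegressionResult:
    """Slope of the saturation plot for one dataset and tree.

    The tree supplies patristic distances (typically the best tree
    inferred for the dataset); the alignment supplies uncorrected
    p-distances.  All unordered taxon pairs present in both, with a
    defined p-distance, enter an OLS fit of p on patristic with free
    intercept.  Slope 1 means every inferred substitution is observed
    (no saturation); the slope shrinks toward 0 as multiple
    substitutions pile up undetected.
    """
    xs, ys, excluded = _pairs(source, tree)
    if len(xs) < 3:
        raise PsqcError(
            f"only {len(xs)} usable pairs ({excluded} undefined); need >= 3"
        )
    fit = stats.linregress(xs, ys)
    r2 = float(fit.rvalue) ** 2 if not math.isnan(fit.rvalue) else math.nan
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(max(r2, 0.0), 1.0) if not math.isnan(r2) else r2,
        n_pairs=len(xs),
        excluded_pairs=excluded,
    )


def saturation_by_partition(sm: SuperMatrix, tree: Tree) -> pd.DataFrame:
    """Per-gene saturation slopes against one fixed tree.

    Genes are ranked by slope descending (higher slope = less
    saturated).  Partitions with fewer than 3 usable pairs are reported
    with NaN statistics rather than dropped.
    """
    rows = []
    for part in sm.partitions:
        gene = sm.extract_partition(part.name)
        try:
            res = saturation_slope(gene, tree)
            rows.append(
                dict(
                    partition=part.name,
                    slope=res.slope,
                    intercept=res.intercept,
                    r_squared=res.r_squared,
                    n_pairs=res.n_pairs,
                    excluded_pairs=res.excluded_pairs,
                    defined=True,
                )
            )
        except PsqcError as exc:
            logger.info("partition %s: %s", part.name, exc)
            rows.append(
                dict(
                    partition=part.name,
                    slope=math.nan,
                    intercept=math.nan,
                    r_squared=math.nan,
                    n_pairs=0,
                    excluded_pairs=0,
                    defined=False,
                )
            )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["defined", "slope"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)


# ----------------------------------------------------------------------
# Congruence screen
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class CongruenceReport:
    """Tally of supported gene-tree splits conflicting with a reference.

    ``conflict_rate`` pools genes: total conflicting supported splits
    over total supported splits across all gene trees.  When no split
    reaches the support threshold, the rate is reported as 0 with
    ``no_testable_branches`` set.
    """

    per_gene: pd.DataFrame
    conflicts: Mapping[str, tuple]
    threshold: float
    no_testable_branches: bool

    @property
    def n_supported_total(self) -> int:
        return int(self.per_gene["n_supported"].sum())

    @property
    def n_conflicting_total(self) -> int:
        return int(self.per_gene["n_conflicting"].sum())

    @property
    def conflict_rate(self) -> float:
        total = self.n_supported_total
        if total == 0:
            return 0.0
        return self.n_conflicting_total / total

    def flagged_genes(self) -> list:
        """Genes with at least one supported conflicting split."""
        sel = self.per_gene["n_conflicting"] > 0
        return self.per_gene.loc[sel, "gene"].tolist()

    def to_tsv(self, path) -> None:
        self.per_gene.to_csv(path, sep="\t", index=False)


def congruence_screen(
    gene_trees: Mapping[str, Tree],
    reference: Tree,
    threshold: float = 70.0,
) -> CongruenceReport:
    """Screen supported single-gene splits against a reference tree.

    For each gene the reference is restricted to the gene's taxa; every
    non-trivial gene-tree split with support >= ``threshold`` is tested
    for compatibility with the restricted reference's splits.  Genes
    sharing fewer than 4 taxa with the reference contribute no testable
    branches (logged, not an error).
    """
    if not gene_trees:
        raise PsqcError("no gene trees supplied")
    ref_leaves = set(leaf_labels(reference))
    rows = []
    conflicts: dict = {}
    any_supported = False
    for name, gtree in gene_trees.items():
        leaves = set(leaf_labels(gtree))
        unknown = leaves - ref_leaves
        if unknown:
            raise PsqcError(
                f"gene {name!r} has leaves not in the reference: {sorted(unknown)}"
            )
        if len(leaves) < 4:
            logger.info(
                "gene %s shares only %d taxa with the reference; "
                "no testable branches",
                name,
                len(leaves),
            )
            rows.append(dict(gene=name, n_supported=0, n_conflicting=0))
            conflicts[name] = ()
            continue
        ref_splits = bipartitions(restrict(reference, leaves))
        supports = split_support_map(gtree)
        supported = [
            (split, sup)
            for split, sup in sorted(supports.items(), key=lambda kv: str(kv[0]))
            if sup is not None and sup >= threshold
        ]
        gene_conflicts = tuple(
            (split, sup)
            for split, sup in supported
            if not compatible(split, ref_splits)
        )
        any_supported = any_supported or bool(supported)
        rows.append(
            dict(
                gene=name,
                n_supported=len(supported),
                n_conflicting=len(gene_conflicts),
            )
        )
        conflicts[name] = gene_conflicts
    per_gene = pd.DataFrame(rows, columns=["gene", "n_supported", "n_conflicting"])
    return CongruenceReport(
        per_gene=per_gene,
        conflicts=conflicts,
        threshold=threshold,
        no_testable_branches=not any_supported,
    )
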