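"""Taxon-sampling experiments: reduced sampling and outgroup pruning.

Dense taxon sampling helps tree reconstruction detect multiple
substitutions; distant outgroups are a natural source of long branches
that can attract fast-evolving ingroup lineages.  This module runs both
kinds of deletion experiment over a supermatrix: each named condition
is a taxon keep-set, analyzed either with the internal NJ+bootstrap
engine or with an externally supplied tree (ingested as Newick, never
inferred here), and focal-clade supports are tabulated and contrasted
across conditions.
"""

from __future__ import annotations

import configparser
import logging
import math
import os
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .msa_io import PsqcError, SuperMatrix, subset_taxa
from .treekit import Tree, clade_support, leaf_labels, read_newick
from .inference import DistanceModel, bootstrap_support

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceSettings",
    "ExperimentSpec",
    "run_conditions",
    "compare_conditions",
    "outgroup_series",
    "read_experiment_spec",
]

#: Cell labels for non-numeric outcomes.
ABSENT = "absent"
NOT_EVALUABLE = "not evaluable"


@dataclass(frozen=True)
class InferenceSettings:
    """Distance model, bootstrap replicate count and master seed."""

    model: DistanceModel = field(default_factory=DistanceModel)
    bootstrap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap < 1:
            raise ValueError("bootstrap must be >= 1")


@dataclass(frozen=True)
class ExperimentSpec:
    """A deletion experiment over one base supermatrix.

    ``conditions`` maps names to taxon keep-sets (each >= 4 taxa);
    ``focal_clades`` maps names to the taxon sets whose support is
    tracked.  A condition is analyzed with an externally supplied tree
    from ``trees`` when present, otherwise with the internal engine
    using ``settings``.
    """

    supermatrix: SuperMatrix
    conditions: Mapping[str, frozenset]
    focal_clades: Mapping[str, frozenset]
    settings: InferenceSettings | None = None
    trees: Mapping[str, Tree] = field(default_factory=dict)

    def validate(self) -> None:
        base = set(self.supermatrix.taxa)
        if not self.conditions:
            raise PsqcError("no conditions defined")
        if not self.focal_clades:
            raise PsqcError("no focal clades defined")
        for name, keep in self.conditions.items():
            unknown = set(keep) - base
            if unknown:
                raise PsqcError(
                    f"condition {name!r} names unknown taxa: {sorted(unknown)}"
                )
            if len(keep) < 4:
                raise PsqcError(
                    f"condition {name!r} keeps only {len(keep)} taxa; need >= 4"
                )
            if name not in self.trees and self.settings is None:
                raise PsqcError(
                    f"condition {name!r} has neither a supplied tree nor "
                    "inference settings"
                )
        for name, clade in self.focal_clades.items():
            unknown = set(clade) - base
            if unknown:
                raise PsqcError(
                    f"clade {name!r} names unknown taxa: {sorted(unknown)}"
                )


def _condition_seed(base_seed: int, condition: str) -> int:
    """Stable per-condition seed: independent of condition order."""
    return (base_seed + zlib.crc32(condition.encode())) % (2**31 - 1)


def _evaluate_clade(tree: Tree, clade: frozenset) -> object:
    present = set(leaf_labels(tree))
    survivors = clade & present
    if len(survivors) < 2 or survivors == present:
        return NOT_EVALUABLE
    support = clade_support(tree, survivors)
    if support is None:
        return ABSENT
    return support


def run_conditions(spec: ExperimentSpec) -> pd.DataFrame:
    """Support of every focal clade under every condition.

    Focal clades are evaluated on their surviving members within each
    condition; clades reduced below 2 survivors are reported as
    ``'not evaluable'`` and clades no edge isolates as ``'absent'``.
    All conditions are validated before any inference starts, and
    results are invariant to condition order (per-condition seeds are
    derived from condition names).
    """
    spec.validate()
    table: dict = {}
    for name, keep in spec.conditions.items():
        if name in spec.trees:
            tree = spec.trees[name]
        else:
            sub = subset_taxa(spec.supermatrix, keep)
            tree = bootstrap_support(
                sub,
                B=spec.settings.bootstrap,
                seed=_condition_seed(spec.settings.seed, name),
                model=spec.settings.model,
            )
        table[name] = {
            clade_name: _evaluate_clade(tree, frozenset(clade))
            for clade_name, clade in spec.focal_clades.items()
        }
    out = pd.DataFrame.from_dict(table, orient="index")
    out.index.name = "condition"
    out.columns.name = "clade"
    return out.loc[list(spec.conditions), list(spec.focal_clades)]


def compare_conditions(table: pd.DataFrame, baseline: str) -> pd.DataFrame:
    """Per-clade support deltas of each condition against a baseline.

    Numeric cells subtract; categorical outcomes propagate as labels
    (``'lost (was 96)'`` when a supported clade disappears), never as
    numeric zeroes.
    """
    if baseline not in table.index:
        raise KeyError(f"baseline condition {baseline!r} not in table")
    base = table.loc[baseline]

    def delta(value, ref):
        v_num = isinstance(value, (int, float)) and not (
            isinstance(value, float) and math.isnan(value)
        )
        r_num = isinstance(ref, (int, float)) and not (
            isinstance(ref, float) and math.isnan(ref)
        )
        if v_num and r_num:
            return float(value) - float(ref)
        if value == NOT_EVALUABLE or ref == NOT_EVALUABLE:
            return NOT_EVALUABLE
        if v_num and ref == ABSENT:
            return f"gained ({value:g})"
        if r_num and value == ABSENT:
            return f"lost (was {ref:g})"
        return ABSENT

    out = table.copy()
    for condition in table.index:
        for clade in table.columns:
            out.loc[condition, clade] = delta(
                table.loc[condition, clade], base[clade]
            )
    return out


def outgroup_series(
    sm: SuperMatrix,
    outgroups: Sequence[tuple[str, frozenset]],
    ingroup: frozenset,
    focal_clades: Mapping[str, frozenset],
    settings: InferenceSettings,
) -> pd.DataFrame:
    """Nested outgroup-addition experiment, near to far.

    Condition i keeps the ingroup plus the first i outgroup groups (the
    closest only; closest+next; ...; all), so the table shows how focal
    ingroup supports respond as ever more distant outgroups join the
    analysis.
    """
    if not ingroup:
        raise PsqcError("empty ingroup")
    if not outgroups:
        raise PsqcError("need at least one outgroup group")
    ingroup = frozenset(ingroup)
    for name, group in outgroups:
        if frozenset(group) & ingroup:
            raise PsqcError(f"outgroup group {name!r} overlaps the ingroup")
    conditions = {}
    acc: frozenset = frozenset()
    for name, group in outgroups:
        acc = acc | frozenset(group)
        label = "+".join(n for n, _ in outgroups[: len(conditions) + 1])
        conditions[label] = ingroup | acc
    spec = ExperimentSpec(
        supermatrix=sm,
        conditions=conditions,
        focal_clades=focal_clades,
        settings=settings,
    )
    return run_conditions(spec)


# ----------------------------------------------------------------------
# Plain-text experiment specs
# ----------------------------------------------------------------------


def read_experiment_spec(path, supermatrix: SuperMatrix) -> ExperimentSpec:
    """Load an experiment spec from an INI-style text file.

    Sections: ``[conditions]`` and ``[clades]`` hold whitespace-
    separated taxon lists per name; ``[settings]`` holds ``model``,
    ``gamma_shape``, ``n_states``, ``bootstrap`` and ``seed``;
    an optional ``[trees]`` section maps condition names to Newick
    files (relative paths resolve against the spec file).
    """
    parser = configparser.ConfigParser()
    parser.optionxform = str  # preserve case of condition/taxon names
    read = parser.read(path)
    if not read:
        raise PsqcError(f"cannot read experiment spec {path}")
    if "conditions" not in parser or "clades" not in parser:
        raise PsqcError("spec needs [conditions] and [clades] sections")
    conditions = {
        name: frozenset(value.split())
        for name, value in parser["conditions"].items()
    }
    clades = {
        name: frozenset(value.split()) for name, value in parser["clades"].items()
    }
    settings = None
    if "settings" in parser:
        section = parser["settings"]
        model = DistanceModel(
            kind=section.get("model", "poisson"),
            gamma_shape=section.getfloat("gamma_shape", fallback=None),
            n_states=section.getint("n_states", fallback=20),
        )
        settings = InferenceSettings(
            model=model,
            bootstrap=section.getint("bootstrap", fallback=100),
            seed=section.getint("seed", fallback=0),
        )
    trees = {}
    if "trees" in parser:
        base = os.path.dirname(os.path.abspath(path))
        for name, tree_path in parser["trees"].items():
            if not os.path.isabs(tree_path):
                tree_path = os.path.join(base, tree_path)
            trees[name] = read_newick(tree_path)
    return ExperimentSpec(
        supermatrix=supermatrix,
        conditions=conditions,
        focal_clades=clades,
        settings=settings,
        trees=trees,
    )
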