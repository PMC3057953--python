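"""Sequence-evolution simulator with known ground truth.

Generates multi-gene supermatrices with the statistical structure the
diagnostics assume, so every screen in this package can be exercised
against a known generating process:

* site-homogeneous models (one equilibrium frequency vector, optional
  symmetric exchangeabilities) and CAT-like site-heterogeneous profile
  mixtures, in which each site draws its own set of acceptable residues
  and exchangeabilities are uniform;
* discrete-gamma rate variation across sites (4 categories) times
  per-gene rate multipliers;
* branch-length geometries prone to long-branch attraction, including a
  distant outgroup attached to the central edge of a two-long/two-short
  quartet;
* implanted sequence transfers (contamination/xenology ground truth for
  the congruence screen) and randomly masked missing data.

Branch lengths are expected substitutions per site at the site's own
rate, so gamma categories and gene multipliers rescale time.  Each
(gene, site) pair owns an independent random stream derived from the
master seed; adding genes or sites never perturbs data already
generated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .msa_io import Alignment, PsqcError, SuperMatrix, concatenate
from .treekit import Bipartition, Tree, parse_newick

logger = logging.getLogger(__name__)

__all__ = [
    "SubstitutionModel",
    "SimulationSpec",
    "make_lba_tree",
    "make_balanced_tree",
    "random_sparse_profiles",
    "random_tree",
    "simulate",
    "implant_transfer",
    "mask_missing",
    "discrete_gamma_rates",
]

NT_LETTERS = np.array(list("ACGT"))
AA_LETTERS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class SubstitutionModel:
    """Continuous-time substitution process for the simulator.

    ``mode='homogeneous'`` uses one equilibrium frequency vector for
    every site; ``mode='profile_mixture'`` draws, per site, one of K
    frequency profiles with the given weights (uniform exchangeabilities,
    the CAT convention: profiles differ only in which residues a site
    accepts).  ``gamma_shape=None`` means uniform rates across sites.
    """

    n_states: int = 20
    mode: str = "homogeneous"
    frequencies: tuple | None = None
    exchangeabilities: tuple | None = None
    profiles: tuple | None = None
    weights: tuple | None = None
    gamma_shape: float | None = None
    gene_rate_multipliers: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_states not in (4, 20):
            raise ValueError("n_states must be 4 or 20")
        if self.mode not in ("homogeneous", "profile_mixture"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gamma_shape is not None and not self.gamma_shape > 0:
            raise ValueError("gamma shape must be positive")
        for vec in self.profile_matrix():
            if abs(vec.sum() - 1.0) > _SUM_TOL or (vec < 0).any():
                raise ValueError("frequencies must be non-negative and sum to 1")
        w = self.weight_vector()
        if abs(w.sum() - 1.0) > _SUM_TOL or (w < 0).any():
            raise ValueError("mixture weights must be non-negative and sum to 1")
        if self.exchangeabilities is not None:
            R = np.asarray(self.exchangeabilities, dtype=float)
            if R.shape != (self.n_states, self.n_states):
                raise ValueError("exchangeability matrix has wrong shape")
            if np.abs(R - R.T).max() > _SUM_TOL or (R < 0).any():
                raise ValueError("exchangeabilities must be symmetric, >= 0")

    # -- constructors ------------------------------------------------

    @classmethod
    def homogeneous(
        cls,
        n_states: int = 20,
        frequencies: Sequence[float] | None = None,
        exchangeabilities=None,
        gamma_shape: float | None = None,
        gene_rate_multipliers: Sequence[float] | None = None,
    ) -> "SubstitutionModel":
        if frequencies is None:
            frequencies = np.full(n_states, 1.0 / n_states)
        return cls(
            n_states=n_states,
            mode="homogeneous",
            frequencies=tuple(float(x) for x in frequencies),
            exchangeabilities=(
                tuple(map(tuple, np.asarray(exchangeabilities, dtype=float)))
                if exchangeabilities is not None
                else None
            ),
            gamma_shape=gamma_shape,
            gene_rate_multipliers=(
                tuple(float(x) for x in gene_rate_multipliers)
                if gene_rate_multipliers is not None
                else None
            ),
        )

    @classmethod
    def profile_mixture(
        cls,
        profiles,
        weights: Sequence[float] | None = None,
        n_states: int = 20,
        gamma_shape: float | None = None,
        gene_rate_multipliers: Sequence[float] | None = None,
    ) -> "SubstitutionModel":
        profiles = np.asarray(profiles, dtype=float)
        if weights is None:
            weights = np.full(len(profiles), 1.0 / len(profiles))
        return cls(
            n_states=n_states,
            mode="profile_mixture",
            profiles=tuple(map(tuple, profiles)),
            weights=tuple(float(x) for x in weights),
            gamma_shape=gamma_shape,
            gene_rate_multipliers=(
                tuple(float(x) for x in gene_rate_multipliers)
                if gene_rate_multipliers is not None
                else None
            ),
        )

    # -- views -------------------------------------------------------

    def profile_matrix(self) -> np.ndarray:
        """(K, s) array of frequency profiles (K=1 when homogeneous)."""
        if self.mode == "homogeneous":
            freqs = (
                np.asarray(self.frequencies, dtype=float)
                if self.frequencies is not None
                else np.full(self.n_states, 1.0 / self.n_states)
            )
            return freqs[None, :]
        if self.profiles is None:
            raise ValueError("profile_mixture model needs profiles")
        return np.asarray(self.profiles, dtype=float)

    def weight_vector(self) -> np.ndarray:
        if self.mode == "homogeneous":
            return np.array([1.0])
        if self.weights is None:
            k = len(self.profiles)
            return np.full(k, 1.0 / k)
        return np.asarray(self.weights, dtype=float)

    def exchangeability_matrix(self) -> np.ndarray:
        if self.exchangeabilities is None:
            R = np.ones((self.n_states, self.n_states))
            np.fill_diagonal(R, 0.0)
            return R
        return np.asarray(self.exchangeabilities, dtype=float)

    def gene_multiplier(self, gene_index: int) -> float:
        if self.gene_rate_multipliers is None:
            return 1.0
        return float(self.gene_rate_multipliers[gene_index])


@dataclass(frozen=True)
class SimulationSpec:
    """One reproducible simulation run: tree, model, sizes, seed."""

    tree: Tree
    model: SubstitutionModel
    sites_per_gene: int
    n_genes: int = 1
    seed: int = 0
    gene_names: tuple | None = None

    def __post_init__(self) -> None:
        if self.sites_per_gene < 1:
            raise ValueError("sites_per_gene must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise ValueError("gene_names length must equal n_genes")

    def names(self) -> tuple:
        if self.gene_names is not None:
            return tuple(self.gene_names)
        width = len(str(self.n_genes))
        return tuple(f"gene{str(i + 1).zfill(width)}" for i in range(self.n_genes))


# ----------------------------------------------------------------------
# Scenario trees
# ----------------------------------------------------------------------


def make_lba_tree(
    long_len: float = 1.0,
    short_len: float = 0.1,
    internal_len: float = 0.02,
    outgroup_len: float | None = None,
) -> Tree:
    """Two-long/two-short quartet prone to long-branch attraction.

    The unrooted quartet ((L1,S1),(L2,S2)) pairs each long terminal
    branch with a short one across the central edge of length
    ``internal_len``.  With ``outgroup_len`` an OUT leaf is attached to
    the midpoint of the central edge — the distant-outgroup variant of
    the same artifact.  The true ingroup split L1,S1 | L2,S2 is recorded
    as ``tree.true_split``.
    """
    for value in (long_len, short_len, internal_len):
        if value < 0:
            raise ValueError("branch lengths must be >= 0")
    if outgroup_len is None:
        newick = (
            f"((L1:{long_len},S1:{short_len}):{internal_len},"
            f"L2:{long_len},S2:{short_len});"
        )
    else:
        if outgroup_len < 0:
            raise ValueError("branch lengths must be >= 0")
        half = internal_len / 2.0
        newick = (
            f"((L1:{long_len},S1:{short_len}):{half},"
            f"(L2:{long_len},S2:{short_len}):{half},OUT:{outgroup_len});"
        )
    tree = parse_newick(newick)
    tree.true_split = Bipartition.from_sides(
        {"L1", "S1"},
        {"L2", "S2"} | ({"OUT"} if outgroup_len is not None else set()),
    )
    return tree


def make_balanced_tree(
    depth: int = 3, edge_length: float = 0.05 / 6, prefix: str = ""
) -> Tree:
    """Balanced binary tree with 2**depth leaves and uniform edges.

    Every edge has the same length, so the tip-to-tip diameter is
    ``2 * depth * edge_length``; leaves are labeled A, B, C, ...
    Scaling ``edge_length`` is the global branch-length multiplier used
    in saturation experiments.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if edge_length < 0:
        raise ValueError("edge_length must be >= 0")
    counter = iter(range(2**depth))

    def build(level: int) -> str:
        if level == 0:
            i = next(counter)
            label = ""
            i += 1
            while i > 0:
                i, rem = divmod(i - 1, 26)
                label = chr(ord("A") + rem) + label
            return f"{prefix}{label}:{edge_length}"
        left = build(level - 1)
        right = build(level - 1)
        return f"({left},{right}):{edge_length}"

    inner = ",".join(build(depth - 1) for _ in range(2))
    return parse_newick(f"({inner});")


def random_tree(
    taxa: Sequence[str],
    seed: int | np.random.Generator = 0,
    min_len: float = 0.1,
    max_len: float = 1.0,
) -> Tree:
    """Random unrooted binary tree by sequential leaf insertion.

    Each leaf after the third is attached to a uniformly chosen edge;
    branch lengths are i.i.d. uniform on [min_len, max_len].
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    tree = parse_newick(f"({taxa[0]}:1,{taxa[1]}:1,{taxa[2]}:1);")
    for label in taxa[3:]:
        edges = [
            n for n in tree.preorder_node_iter() if n.parent_node is not None
        ]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent_node
        parent.remove_child(target)
        mid = target.__class__()
        mid.add_child(target)
        leaf = target.__class__()
        leaf.taxon = tree.taxon_namespace.new_taxon(label)
        mid.add_child(leaf)
        parent.add_child(mid)
        for node in (mid, leaf):
            node.edge.support = None
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(min_len, max_len))
        node.edge.support = None
    tree.update_taxon_namespace()
    return tree


def random_sparse_profiles(
    k: int, n_states: int = 20, alpha: float = 0.1, seed: int = 0
) -> np.ndarray:
    """K sparse Dirichlet(alpha) frequency profiles.

    Small ``alpha`` concentrates each profile on a few residues, the
    regime in which per-site state spaces are small and observed
    distances saturate quickly.
    """
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(n_states, alpha), size=k)
    return profiles / profiles.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------------
# Rates and transition matrices
# ----------------------------------------------------------------------


def discrete_gamma_rates(shape: float, n_categories: int = 4) -> np.ndarray:
    """Category mean rates of the equal-probability discrete gamma.

    Mean-one gamma with the given shape, cut at quantiles i/n; each
    category's rate is its conditional mean, renormalized to average
    exactly 1.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    edges = stats.gamma.ppf(np.linspace(0, 1, n_categories + 1), shape, scale=1.0 / shape)
    upper = stats.gamma.cdf(edges, shape + 1, scale=1.0 / shape)
    means = np.diff(upper) * n_categories
    return means / means.mean()


def _transition_matrix(pi: np.ndarray, R: np.ndarray, t: float) -> np.ndarray:
    """P(t) for the reversible process q_xy = R_xy * pi_y, mean rate 1.

    States with zero equilibrium frequency are absorbing-from-nowhere:
    they are never entered and never left (identity rows), which makes
    single-residue profiles yield invariant sites.
    """
    s = len(pi)
    support = pi > 0
    P = np.eye(s)
    idx = np.where(support)[0]
    if len(idx) == 1:
        return P
    ps = pi[idx]
    Q = R[np.ix_(idx, idx)] * ps[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(ps * np.diag(Q)).sum()
    if mu <= 0:
        return P
    Q /= mu
    root = np.sqrt(ps)
    sym = (Q * root[:, None]) / root[None, :]
    w, V = np.linalg.eigh((sym + sym.T) / 2.0)
    expwt = np.exp(w * t)
    sub = (V * expwt[None, :]) @ V.T
    sub = sub / root[:, None] * root[None, :]
    sub = np.clip(sub, 0.0, None)
    sub /= sub.sum(axis=1, keepdims=True)
    P[np.ix_(idx, idx)] = sub
    # zero-frequency states, if ever forced as a parent state, stay put
    return P


# ----------------------------------------------------------------------
# Simulation
# ----------------------------------------------------------------------


def _tree_arrays(tree: Tree):
    """Preorder node list, parent indices and branch lengths."""
    nodes = list(tree.preorder_node_iter())
    index = {id(node): i for i, node in enumerate(nodes)}
    parents = np.full(len(nodes), -1, dtype=int)
    lengths = np.zeros(len(nodes))
    for i, node in enumerate(nodes):
        if node.parent_node is not None:
            parents[i] = index[id(node.parent_node)]
            lengths[i] = node.edge.length or 0.0
    leaf_rows = [
        (node.taxon.label, i) for i, node in enumerate(nodes) if node.is_leaf()
    ]
    return nodes, parents, lengths, leaf_rows


def simulate(spec: SimulationSpec):
    """Simulate a supermatrix plus per-site ground truth.

    Returns ``(SuperMatrix, truth)`` where ``truth`` is a table with one
    row per (gene, site): the profile index the site drew and its total
    rate multiplier (gamma category rate x gene multiplier).  The run is
    a pure function of the spec: same spec, same seed, byte-identical
    output.
    """
    model = spec.model
    profiles = model.profile_matrix()
    weights = model.weight_vector()
    cum_weights = np.cumsum(weights)
    R = model.exchangeability_matrix()
    letters = NT_LETTERS if model.n_states == 4 else AA_LETTERS
    if model.gamma_shape is None:
        cat_rates = np.array([1.0])
    else:
        cat_rates = discrete_gamma_rates(model.gamma_shape)
    n_cats = len(cat_rates)
    cum_profiles = np.cumsum(profiles, axis=1)

    _, parents, lengths, leaf_rows = _tree_arrays(spec.tree)
    n_nodes = len(parents)
    n_sites = spec.sites_per_gene

    pmatrix_cache: dict = {}

    def transition(profile_idx: int, t_eff: float) -> np.ndarray:
        key = (profile_idx, float(t_eff))
        if key not in pmatrix_cache:
            pmatrix_cache[key] = np.cumsum(
                _transition_matrix(profiles[profile_idx], R, t_eff), axis=1
            )
        return pmatrix_cache[key]

    genes = []
    truth_rows = []
    for g, gene_name in enumerate(spec.names()):
        mult = model.gene_multiplier(g)
        # one stream per (gene, site): layout is [category, profile,
        # root draw, one draw per non-root preorder node]
        U = np.empty((n_sites, 2 + n_nodes))
        for site in range(n_sites):
            ss = np.random.SeedSequence(spec.seed, spawn_key=(g, site))
            U[site] = np.random.default_rng(ss).random(2 + n_nodes)
        cats = np.minimum((U[:, 0] * n_cats).astype(int), n_cats - 1)
        profs = np.searchsorted(cum_weights, U[:, 1], side="right")
        profs = np.minimum(profs, len(weights) - 1)

        states = np.empty((n_nodes, n_sites), dtype=int)
        for k in range(len(weights)):
            sel = profs == k
            if not sel.any():
                continue
            states[0, sel] = np.searchsorted(
                cum_profiles[k], U[sel, 2], side="right"
            )
        states[0] = np.minimum(states[0], model.n_states - 1)

        for node in range(1, n_nodes):
            parent_states = states[parents[node]]
            u = U[:, 2 + node]
            for k in range(len(weights)):
                for c in range(n_cats):
                    sel = (profs == k) & (cats == c)
                    if not sel.any():
                        continue
                    t_eff = lengths[node] * cat_rates[c] * mult
                    cumP = transition(k, t_eff)
                    rows = cumP[parent_states[sel]]
                    states[node, sel] = np.minimum(
                        (rows < u[sel, None]).sum(axis=1), model.n_states - 1
                    )

        records = [
            (taxon, "".join(letters[states[row]]))
            for taxon, row in leaf_rows
        ]
        alphabet = "nt" if model.n_states == 4 else "aa"
        genes.append((gene_name, Alignment.from_records(records, alphabet=alphabet)))
        truth_rows.append(
            pd.DataFrame(
                {
                    "gene": gene_name,
                    "site": np.arange(1, n_sites + 1),
                    "profile": profs,
                    "rate": cat_rates[cats] * mult,
                }
            )
        )

    sm = concatenate(genes)
    truth = pd.concat(truth_rows, ignore_index=True)
    return sm, truth


# ----------------------------------------------------------------------
# Perturbations: implanted transfers and masked missing data
# ----------------------------------------------------------------------


def implant_transfer(
    sm: SuperMatrix, gene: str, donor: str, recipient: str
) -> SuperMatrix:
    """Replace the recipient's cells in one gene by the donor's.

    Emulates contamination/xenology: within the gene the recipient
    becomes identical to the donor, everything else stays untouched.
    The event is recorded in ``events``.
    """
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    part = sm.partition(gene)
    taxa = list(sm.taxa)
    for name in (donor, recipient):
        if name not in taxa:
            raise KeyError(f"unknown taxon {name!r}")
    mask = sm.missing_mask()
    d, r = taxa.index(donor), taxa.index(recipient)
    if mask[d, part.columns].all():
        raise PsqcError(f"donor {donor!r} has no data in gene {gene!r}")
    if mask[r, part.columns].all():
        raise PsqcError(f"recipient {recipient!r} has no data in gene {gene!r}")
    data = sm.alignment.data.copy()
    data[r, part.columns] = data[d, part.columns]
    aln = Alignment(taxa=sm.taxa, data=data, alphabet=sm.alignment.alphabet)
    event = dict(kind="transfer", gene=gene, donor=donor, recipient=recipient)
    return SuperMatrix(
        alignment=aln, partitions=sm.partitions, events=sm.events + (event,)
    )


def mask_missing(
    sm: SuperMatrix,
    target_fraction: float,
    unit: str = "cell",
    seed: int = 0,
) -> SuperMatrix:
    """Randomly mask cells (or whole gene-by-taxon blocks) to '?'.

    Raises the overall missing fraction to ``target_fraction`` by
    masking uniformly at random among currently non-missing cells or
    blocks; already-missing cells are never touched and the achieved
    fraction lands within one masking unit of the target.
    """
    if not 0.0 <= target_fraction < 1.0:
        raise ValueError("target_fraction must be in [0, 1)")
    if unit not in ("cell", "gene_by_taxon"):
        raise ValueError("unit must be 'cell' or 'gene_by_taxon'")
    mask = sm.missing_mask()
    total = mask.size
    current = int(mask.sum())
    needed = target_fraction * total - current
    if needed < -1e-9:
        raise PsqcError(
            f"target fraction {target_fraction} is below the current "
            f"missing fraction {current / total:.4f}"
        )
    rng = np.random.default_rng(seed)
    data = sm.alignment.data.copy()
    if unit == "cell":
        candidates = np.flatnonzero(~mask.ravel())
        n_mask = int(round(target_fraction * total)) - current
        n_mask = max(0, min(n_mask, len(candidates)))
        chosen = rng.choice(candidates, size=n_mask, replace=False)
        flat = data.reshape(-1)
        flat[chosen] = "?"
        data = flat.reshape(data.shape)
    else:
        blocks = []
        for p in sm.partitions:
            for row in range(len(sm.taxa)):
                free = int((~mask[row, p.columns]).sum())
                if free > 0:
                    blocks.append((row, p, free))
        order = rng.permutation(len(blocks))
        masked = 0
        for b in order:
            row, p, free = blocks[b]
            if abs(masked + free - needed) <= abs(masked - needed):
                data[row, p.columns] = "?"
                masked += free
            if masked >= needed:
                break
    aln = Alignment(taxa=sm.taxa, data=data, alphabet=sm.alignment.alphabet)
    event = dict(kind="mask", unit=unit, target_fraction=target_fraction, seed=seed)
    return SuperMatrix(
        alignment=aln, partitions=sm.partitions, events=sm.events + (event,)
    )
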