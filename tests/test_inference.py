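import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psqc import (
    Alignment,
    DistanceMatrix,
    DistanceModel,
    PsqcError,
    bipartitions,
    bootstrap_support,
    clade_support,
    correct_distance,
    corrected_matrix,
    leaf_labels,
    neighbor_joining,
    p_distance,
    patristic_matrix,
    split_support_map,
)

from conftest import random_binary_tree


# -- p-distances -------------------------------------------------------


def test_p_distance_examples():
    aln = Alignment.from_records(
        [("A", "ACGTACGTAC"), ("B", "ACGTACGTAC"), ("C", "ACGTACGTAT")]
    )
    dm = p_distance(aln)
    assert dm["A", "B"] == 0.0
    assert dm["A", "C"] == pytest.approx(0.1)


def test_p_distance_pairwise_deletion():
    aln = Alignment.from_records([("A", "AC-T"), ("B", "ACGT")])
    dm, counts = p_distance(aln, return_counts=True)
    assert dm["A", "B"] == 0.0
    assert counts[0, 1] == 3
    disjoint = Alignment.from_records([("A", "AC??"), ("B", "??GT")])
    dm2 = p_distance(disjoint)
    assert math.isnan(dm2["A", "B"])
    assert ("A", "B") in dm2.undefined_pairs()


# -- distance corrections ---------------------------------------------


@pytest.mark.parametrize(
    "model",
    [
        DistanceModel("uncorrected", n_states=4),
        DistanceModel("poisson", n_states=20),
        DistanceModel("gamma", gamma_shape=0.5, n_states=20),
    ],
)
def test_zero_p_maps_to_zero(model):
    assert correct_distance(0.0, model) == pytest.approx(0.0)


def test_poisson_closed_form_value():
    # independent evaluation of -(s-1)/s * ln(1 - s p / (s-1)) at s=20, p=0.5
    expected = (19 / 20) * math.log(1.0 / (1.0 - 10.0 / 19.0))
    got = correct_distance(0.5, DistanceModel("poisson", n_states=20))
    assert got == pytest.approx(expected, abs=1e-12)


def test_gamma_with_huge_shape_approaches_poisson():
    grid = np.linspace(0.0, 0.9, 19)
    poisson = correct_distance(grid, DistanceModel("poisson", n_states=20))
    gamma = correct_distance(
        grid, DistanceModel("gamma", gamma_shape=1e6, n_states=20)
    )
    assert np.nanmax(np.abs(poisson - gamma)) < 1e-4


def test_saturated_p_flagged_not_raised():
    model = DistanceModel("poisson", n_states=4)
    assert math.isnan(correct_distance(0.75, model))
    assert math.isnan(correct_distance(0.9, model))


@settings(derandomize=True, max_examples=50)
@given(
    st.floats(min_value=0.0, max_value=0.73),
    st.floats(min_value=0.001, max_value=0.015),
)
def test_correction_monotone_and_never_shrinks(p, step):
    model = DistanceModel("gamma", gamma_shape=0.7, n_states=4)
    d0, d1 = correct_distance(p, model), correct_distance(p + step, model)
    assert d1 > d0
    assert d0 >= p - 1e-12


# -- neighbor joining --------------------------------------------------


def _edge_length_map(tree):
    out = {}
    from psqc.treekit import _edge_splits

    for node, split in _edge_splits(tree):
        out[split] = out.get(split, 0.0) + (node.edge.length or 0.0)
    return out


def test_nj_recovers_additive_trees(rng):
    for _ in range(20):
        n = int(rng.integers(6, 11))
        true = random_binary_tree([f"t{i}" for i in range(n)], rng)
        dm = patristic_matrix(true)
        inferred = neighbor_joining(dm)
        assert bipartitions(inferred) == bipartitions(true)
        lm_true, lm_inf = _edge_length_map(true), _edge_length_map(inferred)
        for split, length in lm_true.items():
            assert lm_inf[split] == pytest.approx(length, abs=1e-9)


def test_nj_three_taxa_three_point_formulas():
    dm = DistanceMatrix(
        taxa=("A", "B", "C"),
        values=np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]),
    )
    tree = neighbor_joining(dm)
    lengths = {
        n.taxon.label: n.edge.length for n in tree.leaf_node_iter()
    }
    assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}


def test_nj_invariant_under_taxon_permutation(rng):
    true = random_binary_tree([f"t{i}" for i in range(7)], rng)
    dm = patristic_matrix(true)
    order = list(rng.permutation(dm.n))
    shuffled = DistanceMatrix(
        taxa=tuple(dm.taxa[i] for i in order),
        values=dm.values[np.ix_(order, order)],
    )
    t1, t2 = neighbor_joining(dm), neighbor_joining(shuffled)
    assert bipartitions(t1) == bipartitions(t2)
    m1, m2 = _edge_length_map(t1), _edge_length_map(t2)
    for split in m1:
        assert m1[split] == pytest.approx(m2[split], abs=1e-9)


def test_nj_matches_skbio_oracle(rng):
    skbio_tree_mod = pytest.importorskip("skbio.tree")
    from skbio import DistanceMatrix as SkbioDM

    for _ in range(5):
        true = random_binary_tree([f"t{i}" for i in range(8)], rng)
        dm = patristic_matrix(true)
        mine = neighbor_joining(dm)
        theirs = skbio_tree_mod.nj(SkbioDM(dm.values, ids=list(dm.taxa)))
        their_splits = set()
        all_taxa = frozenset(dm.taxa)
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_taxa) - 1:
                from psqc import Bipartition

                their_splits.add(
                    Bipartition.from_sides(side, all_taxa - side)
                )
        assert bipartitions(mine) == their_splits


def test_nj_rejects_undefined_entries():
    values = np.array([[0.0, 1.0, np.nan], [1.0, 0.0, 1.0], [np.nan, 1.0, 0.0]])
    dm = DistanceMatrix(taxa=("A", "B", "C"), values=values)
    with pytest.raises(PsqcError, match="undefined"):
        neighbor_joining(dm)


# -- bootstrap ---------------------------------------------------------


def _quartet_alignment(n_sites=60):
    # every column supports AB|CD
    a = "A" * n_sites
    b = "A" * n_sites
    c = "C" * n_sites
    d = "C" * n_sites
    half = n_sites // 2
    b = "A" * half + "G" * (n_sites - half)
    d = "C" * half + "T" * (n_sites - half)
    return Alignment.from_records(
        [("A", a), ("B", b), ("C", c), ("D", d)], alphabet="nt"
    )


def test_bootstrap_saturated_signal_gives_full_support():
    aln = _quartet_alignment()
    model = DistanceModel("uncorrected", n_states=4)
    tree = bootstrap_support(aln, B=100, seed=5, model=model)
    assert clade_support(tree, {"A", "B"}) == 100.0


def test_bootstrap_deterministic_and_bounded(rng):
    rows = [
        (f"t{i}", "".join(rng.choice(list("ACGT"), size=80))) for i in range(6)
    ]
    aln = Alignment.from_records(rows, alphabet="nt")
    model = DistanceModel("uncorrected", n_states=4)
    t1 = bootstrap_support(aln, B=30, seed=9, model=model)
    t2 = bootstrap_support(aln, B=30, seed=9, model=model)
    s1, s2 = split_support_map(t1), split_support_map(t2)
    assert s1 == s2
    assert all(0.0 <= v <= 100.0 for v in s1.values())
    with pytest.raises(ValueError):
        bootstrap_support(aln, B=0, seed=1, model=model)


def test_bootstrap_noise_rarely_strongly_supported():
    # i.i.d. uniform columns carry no phylogenetic signal: strong
    # (>95) supports should be rare across seeds
    model = DistanceModel("uncorrected", n_states=4)
    supports = []
    for seed in range(10):
        gen = np.random.default_rng(1000 + seed)
        rows = [
            (f"t{i}", "".join(gen.choice(list("ACGT"), size=300)))
            for i in range(6)
        ]
        aln = Alignment.from_records(rows, alphabet="nt")
        tree = bootstrap_support(aln, B=50, seed=seed, model=model)
        supports.extend(split_support_map(tree).values())
    frac_high = np.mean([s > 95 for s in supports])
    assert frac_high < 0.10


def test_nj_consistency_with_sequence_length(reference12, aa_model, poisson20):
    # topology recovery improves to certainty as sites grow
    from psqc import SimulationSpec, simulate

    true_splits = bipartitions(reference12)
    hits = {}
    for n_sites in (100, 1000, 10000):
        sm, _ = simulate(
            SimulationSpec(
                tree=reference12, model=aa_model, sites_per_gene=n_sites, seed=77
            )
        )
        nj = neighbor_joining(corrected_matrix(sm, poisson20))
        hits[n_sites] = len(bipartitions(nj) & true_splits)
    assert hits[10000] == len(true_splits)
    assert hits[100] <= hits[1000] <= hits[10000]
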