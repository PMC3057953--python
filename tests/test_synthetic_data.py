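import math

import numpy as np
import pytest
from scipy import integrate, stats

from psqc import (
    Bipartition,
    DistanceModel,
    PsqcError,
    SimulationSpec,
    SubstitutionModel,
    bipartitions,
    corrected_matrix,
    discrete_gamma_rates,
    implant_transfer,
    leaf_labels,
    make_balanced_tree,
    make_lba_tree,
    mask_missing,
    missing_fraction,
    neighbor_joining,
    p_distance,
    parse_newick,
    patristic_matrix,
    random_sparse_profiles,
    simulate,
    write_newick,
)


# -- scenario trees ----------------------------------------------------


def test_lba_tree_has_requested_lengths():
    tree = make_lba_tree(long_len=1.0, short_len=0.1, internal_len=0.02)
    pm = patristic_matrix(tree)
    assert pm["L1", "S1"] == pytest.approx(1.1)
    assert pm["L1", "L2"] == pytest.approx(2.02)
    assert pm["S1", "S2"] == pytest.approx(0.22)
    assert tree.true_split == Bipartition.from_sides({"L1", "S1"}, {"L2", "S2"})


def test_lba_tree_zero_internal_and_mirror():
    star = make_lba_tree(internal_len=0.0)
    assert patristic_matrix(star)["S1", "S2"] == pytest.approx(0.2)
    a = make_lba_tree(long_len=0.7, short_len=0.2, internal_len=0.1)
    b = make_lba_tree(long_len=0.7, short_len=0.2, internal_len=0.1)
    assert patristic_matrix(a)["L1", "S2"] == patristic_matrix(b)["L2", "S1"]


def test_lba_tree_with_outgroup():
    tree = make_lba_tree(1.0, 0.1, 0.04, outgroup_len=2.0)
    assert "OUT" in leaf_labels(tree)
    pm = patristic_matrix(tree)
    assert pm["L1", "L2"] == pytest.approx(2.04)
    assert pm["OUT", "S1"] == pytest.approx(2.0 + 0.02 + 0.1)


# -- discrete gamma ----------------------------------------------------


def test_discrete_gamma_matches_numeric_integration():
    shape = 0.5
    rates = discrete_gamma_rates(shape)
    dist = stats.gamma(shape, scale=1.0 / shape)
    edges = dist.ppf(np.linspace(0, 1, 5))
    for i, rate in enumerate(rates):
        lo, hi = edges[i], min(edges[i + 1], 1e3)
        mean, _ = integrate.quad(lambda x: x * dist.pdf(x), lo, hi)
        assert rate == pytest.approx(mean * 4, rel=1e-5)
    assert np.mean(rates) == pytest.approx(1.0)


def test_discrete_gamma_limits():
    nearly_uniform = discrete_gamma_rates(1e6)
    assert np.allclose(nearly_uniform, 1.0, atol=1e-2)
    skewed = discrete_gamma_rates(0.2)
    assert skewed[0] < 1e-3 and skewed[-1] > 2.0


# -- simulate ----------------------------------------------------------


def test_zero_branch_lengths_copy_root_state(aa_model):
    sm, _ = simulate(
        SimulationSpec(
            tree=parse_newick("(A:0,B:0,C:0);"),
            model=SubstitutionModel.homogeneous(n_states=4),
            sites_per_gene=50,
            seed=3,
        )
    )
    rows = [seq for _, seq in sm.alignment.to_records()]
    assert rows[0] == rows[1] == rows[2]


def test_single_branch_matches_closed_form_probability():
    # uniform 4-state model: P(differ) = (3/4)(1 - exp(-4L/3))
    L, n = 0.75, 50000
    sm, _ = simulate(
        SimulationSpec(
            tree=parse_newick(f"(A:0,B:{L});"),
            model=SubstitutionModel.homogeneous(n_states=4),
            sites_per_gene=n,
            seed=42,
        )
    )
    expected = 0.75 * (1.0 - math.exp(-4.0 * L / 3.0))
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(p_distance(sm)["A", "B"] - expected) < 3 * se


def test_single_residue_profile_gives_invariant_sites():
    profile = np.zeros((1, 20))
    profile[0, 7] = 1.0
    model = SubstitutionModel.profile_mixture(profile)
    sm, truth = simulate(
        SimulationSpec(
            tree=parse_newick("(A:2.0,B:2.0);"), model=model, sites_per_gene=25, seed=1
        )
    )
    rows = [seq for _, seq in sm.alignment.to_records()]
    assert rows[0] == rows[1]
    assert len(set(rows[0])) == 1


def test_same_spec_same_seed_byte_identical(reference12, aa_model):
    spec = SimulationSpec(
        tree=reference12, model=aa_model, sites_per_gene=120, n_genes=3, seed=8
    )
    sm1, t1 = simulate(spec)
    sm2, t2 = simulate(spec)
    assert (sm1.alignment.data == sm2.alignment.data).all()
    assert t1.equals(t2)


def test_adding_genes_preserves_earlier_genes(reference12, aa_model):
    short = SimulationSpec(
        tree=reference12, model=aa_model, sites_per_gene=100, n_genes=2, seed=8
    )
    longer = SimulationSpec(
        tree=reference12, model=aa_model, sites_per_gene=100, n_genes=4, seed=8
    )
    sm_short, _ = simulate(short)
    sm_long, _ = simulate(longer)
    for gene in ("gene1", "gene2"):
        assert sm_long.extract_partition(gene) == sm_short.extract_partition(gene)


def test_truth_table_reports_rates_and_profiles():
    profiles = random_sparse_profiles(5, seed=2)
    model = SubstitutionModel.profile_mixture(
        profiles, gamma_shape=0.5, gene_rate_multipliers=(1.0, 3.0)
    )
    sm, truth = simulate(
        SimulationSpec(
            tree=make_balanced_tree(), model=model, sites_per_gene=200, n_genes=2, seed=5
        )
    )
    assert set(truth["gene"]) == {"gene1", "gene2"}
    assert truth["profile"].between(0, 4).all()
    cats = discrete_gamma_rates(0.5)
    g1 = truth[truth["gene"] == "gene1"]["rate"]
    g2 = truth[truth["gene"] == "gene2"]["rate"]
    assert set(np.round(g1, 12)) <= set(np.round(cats, 12))
    assert set(np.round(g2, 12)) <= set(np.round(cats * 3.0, 12))


def test_parameter_recovery_from_gamma_simulations():
    tree = parse_newick(
        "(((A:0.2,B:0.1):0.05,(C:0.15,D:0.08):0.06):0.05,"
        "((E:0.1,F:0.2):0.07,(G:0.12,H:0.09):0.05):0.06);"
    )
    model = SubstitutionModel.homogeneous(n_states=20, gamma_shape=0.5)
    dm = DistanceModel("gamma", gamma_shape=0.5, n_states=20)
    true_splits = bipartitions(tree)
    recovered = 0
    n_seeds = 10
    for seed in range(n_seeds):
        sm, _ = simulate(
            SimulationSpec(tree=tree, model=model, sites_per_gene=5000, seed=500 + seed)
        )
        nj = neighbor_joining(corrected_matrix(sm, dm))
        recovered += bipartitions(nj) == true_splits
    assert recovered >= 0.9 * n_seeds


# -- implant_transfer --------------------------------------------------


def test_implant_zeroes_within_gene_distance(small_simulated):
    sm, _ = small_simulated
    out = implant_transfer(sm, "gene2", donor="A", recipient="L")
    gene = out.extract_partition("gene2")
    assert p_distance(gene)["A", "L"] == 0.0
    for name in ("gene1", "gene3", "gene4", "gene5", "gene6"):
        assert out.extract_partition(name) == sm.extract_partition(name)
    assert out.events[-1]["kind"] == "transfer"


def test_implant_errors(small_simulated):
    sm, _ = small_simulated
    with pytest.raises(ValueError):
        implant_transfer(sm, "gene1", "A", "A")
    blanked = mask_missing(sm, 0.0, seed=1)  # no-op copy
    with pytest.raises(KeyError):
        implant_transfer(blanked, "gene1", "A", "nope")


def test_implant_rejects_all_missing_blocks():
    from psqc import Alignment, Partition, SuperMatrix

    aln = Alignment.from_records(
        [("a", "????ACGT"), ("b", "ACGTACGT"), ("c", "ACGAACGA")]
    )
    sm = SuperMatrix(
        alignment=aln,
        partitions=(Partition("g1", 1, 4, "nt"), Partition("g2", 5, 8, "nt")),
    )
    with pytest.raises(PsqcError, match="donor"):
        implant_transfer(sm, "g1", donor="a", recipient="b")
    with pytest.raises(PsqcError, match="recipient"):
        implant_transfer(sm, "g1", donor="b", recipient="a")


# -- mask_missing ------------------------------------------------------


def test_mask_zero_is_identity(small_simulated):
    sm, _ = small_simulated
    out = mask_missing(sm, 0.0, seed=9)
    assert (out.alignment.data == sm.alignment.data).all()


def test_mask_cells_achieves_target(small_simulated):
    sm, _ = small_simulated
    out = mask_missing(sm, 0.4, unit="cell", seed=9)
    total = out.alignment.data.size
    assert abs(missing_fraction(out) - 0.4) <= 1.0 / total + 1e-12
    again = mask_missing(sm, 0.4, unit="cell", seed=9)
    assert (out.alignment.data == again.alignment.data).all()


def test_mask_blocks_exact_count():
    from psqc import Alignment, concatenate

    genes = []
    for g in range(10):
        rows = [(f"t{i}", "ACGTACGTAC") for i in range(4)]
        genes.append((f"g{g}", Alignment.from_records(rows, alphabet="nt")))
    sm = concatenate(genes)
    out = mask_missing(sm, 0.5, unit="gene_by_taxon", seed=3)
    mask = out.missing_mask()
    masked_blocks = sum(
        mask[row, p.columns].all()
        for p in out.partitions
        for row in range(len(out.taxa))
    )
    assert masked_blocks == 20
    assert missing_fraction(out) == pytest.approx(0.5)


def test_mask_below_current_fraction_is_an_error(small_simulated):
    sm, _ = small_simulated
    masked = mask_missing(sm, 0.3, seed=2)
    with pytest.raises(PsqcError, match="below"):
        mask_missing(masked, 0.1, seed=2)


# -- the long-branch artifact ------------------------------------------


def test_lba_frequency_nondecreasing_in_long_branch_length():
    profiles = random_sparse_profiles(10, alpha=0.1, seed=7)
    model = SubstitutionModel.profile_mixture(profiles)
    wrong_split = Bipartition.from_sides({"L1", "L2"}, {"S1", "S2"})
    freqs = []
    for long_len in (0.1, 1.0):
        wrong = 0
        for seed in range(8):
            tree = make_lba_tree(long_len=long_len, short_len=0.05, internal_len=0.05)
            sm, _ = simulate(
                SimulationSpec(tree=tree, model=model, sites_per_gene=2000, seed=50 + seed)
            )
            nj = neighbor_joining(p_distance(sm))
            wrong += wrong_split in bipartitions(nj)
        freqs.append(wrong / 8)
    assert freqs[0] <= freqs[1]
    assert freqs[1] > 0.5
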