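# psqc — phylogenomic signal quality control

Large multigene ("supermatrix") phylogenies can be strongly supported and
still wrong: undetected multiple substitutions (saturation), contaminant or
paralogous sequences, sparse taxon sampling and distant outgroups all inject
*non-phylogenetic signal* that competes with the genuine signal during tree
reconstruction — the long-branch attraction (LBA) artifact being the most
notorious outcome. `psqc` is a toolkit for phylogeneticists who want to
quantify and stress-test that noise **before** trusting a topology:

* **Saturation slope.** For an alignment and a tree, regress the uncorrected
  p-distance `p(i,j)` on the patristic distance `d(i,j)` (sum of branch
  lengths on the i–j path) over all taxon pairs, by OLS with free intercept.
  Unsaturated data give slope 1; the more multiple substitutions go
  unobserved, the flatter the saturation plot and the smaller the slope.
  Per-partition slopes rank genes from least to most saturated.
* **Congruence screen.** An a-posteriori orthology check: every bipartition
  of a single-gene bootstrap tree with support ≥ 70% is tested for
  compatibility against the concatenated reference tree restricted to that
  gene's taxa. Supported conflicts point at contamination, xenology,
  paralogy or reconstruction error in that gene.
* **Missing-data profiling** of supermatrices (overall, per taxon, per
  gene-by-taxon block), with `'-'`, `'?'` and `X`/`N` all counted missing.
* **Taxon-sampling experiments.** Named deletion conditions (reduced
  sampling, outgroup pruning series) analyzed with the built-in
  NJ + nonparametric bootstrap engine or with externally supplied Newick
  trees, with focal-clade supports tabulated and contrasted.
* **A sequence simulator with known ground truth**: site-homogeneous models
  and CAT-like profile mixtures (per-site frequency profiles, uniform
  exchangeabilities), discrete-gamma rates, per-gene rate multipliers,
  LBA branch-length geometries, implanted sequence transfers and masked
  missing data — so every diagnostic can be validated against a generating
  process you control.

The inference engine is deliberately desk-scale (s-state Poisson/gamma
distance corrections and neighbor joining); heavyweight ML/Bayesian trees
are ingested as Newick files, never run.

## Worked example

```python
import numpy as np
from psqc import (
    DistanceModel, SimulationSpec, SubstitutionModel, bootstrap_support,
    congruence_screen, corrected_matrix, implant_transfer, make_balanced_tree,
    missing_fraction, neighbor_joining, saturation_slope, simulate,
)

# simulate 6 genes of 500 amino-acid sites on an 8-taxon tree,
# then contaminate gene3: taxon H's sequence is replaced by taxon A's
tree = make_balanced_tree(depth=3, edge_length=0.05)
model = SubstitutionModel.homogeneous(n_states=20)
sm, truth = simulate(SimulationSpec(tree=tree, model=model,
                                    sites_per_gene=500, n_genes=6, seed=1))
sm = implant_transfer(sm, "gene3", donor="A", recipient="H")
print(f"missing fraction: {missing_fraction(sm):.3f}")

# saturation diagnostic on the NJ tree
dm = DistanceModel("poisson", n_states=20)
nj = neighbor_joining(corrected_matrix(sm, dm))
res = saturation_slope(sm, nj)
print(f"saturation slope: {res.slope:.3f} (n_pairs={res.n_pairs})")

# congruence screen of per-gene bootstrap trees against the true tree
genes = {p.name: bootstrap_support(sm.extract_partition(p.name),
                                   B=100, seed=2, model=dm)
         for p in sm.partitions}
report = congruence_screen(genes, tree, threshold=70.0)
print(f"conflict rate: {report.conflict_rate:.3f}; "
      f"flagged: {report.flagged_genes()}")
```

Output:

```
missing fraction: 0.000
saturation slope: 0.803 (n_pairs=28)
conflict rate: 0.100; flagged: ['gene3']
```

The slope of 0.80 says roughly a fifth of the inferred substitutions are
invisible in the observed distances (the tree's tip-to-tip length is 0.3
substitutions/site, enough for mild saturation), and the screen pins every
supported conflict on the one gene that actually carries the implanted
transfer.

A command-line interface mirrors the library:
`psqc matrix concat|missing|subset`, `psqc tree splits|patristic`,
`psqc infer nj`, `psqc diag saturation|congruence`, `psqc exp run`.

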