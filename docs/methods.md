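# Methods

## Data model

A **supermatrix** is a rectangular character matrix with named,
contiguous, non-overlapping gene partitions (1-based inclusive column
ranges) that jointly cover every column. Taxa absent from a gene are
padded with `'?'` at concatenation, so extracting a partition and
dropping all-missing taxa recovers the original gene byte-for-byte.
The missing symbols are `'-'`, `'?'`, and the alphabet wildcards `X`
(amino acid) / `N` (nucleotide). Gaps count as missing everywhere in
the missing-data statistics: the pipeline does not distinguish indels
from absent sequence, because both erode the number of comparable
sites in the same way and published missing-data percentages for EST
supermatrices do not separate them either. In mixed
nucleotide+protein matrices the missing mask is evaluated per
partition (an `N` is a valid asparagine in a protein block but missing
in a DNA block).

Trees are DendroPy trees with branch lengths in expected
substitutions per site and optional per-internal-edge supports on the
0–100 scale. On Newick input, an internal node label that parses as a
number in [0, 100] is a support (values ≤ 1 are rescaled ×100 with a
warning, matching tools that emit proportions); missing branch
lengths default to 0 with a warning; negative lengths are rejected.
Newick output uses shortest-round-trip float formatting, so
write→parse is exact. All split operations use the unrooted
interpretation: one bipartition per edge, with the two root-adjacent
edges of a rooted binary tree collapsing to a single split (supports
merged by maximum, a deliberate tie-break for the rare case where the
two edges carry different values).

## Distances and tree inference

Uncorrected (p) distances use **pairwise deletion**: each pair is
compared over the columns where neither sequence is missing. Complete
deletion would often empty a supermatrix with ~50% missing cells;
pairs with zero comparable columns are flagged undefined (NaN) rather
than invented. Corrections belong to the s-state equal-exchangeability
(Jukes–Cantor) family, s ∈ {4, 20}:

* Poisson: `d = -(s-1)/s · ln(1 - s·p/(s-1))`
* Gamma: `d = a·(s-1)/s · ((1 - s·p/(s-1))^(-1/a) - 1)`, shape `a > 0`.

p at or beyond the ceiling `(s-1)/s` yields NaN (a reportable
saturation flag, not an exception). These closed forms are enough to
reproduce the under/over-correction phenomena the diagnostics target;
empirical exchangeability matrices are intentionally out of scope.

Neighbor joining follows the standard Q-criterion with two
deterministic refinements: ties are broken by the lexicographically
smallest pair of cluster names (a cluster is named by its smallest
member taxon), so taxon order never changes the result, and negative
branch lengths are clamped to zero with the deficit moved to the
sibling edge, preserving the joined pair's distance. On additive
matrices NJ reproduces the generating topology and branch lengths to
1e-9 (verified against brute-force path sums and an independent NJ
implementation). One numerical caveat found during development: the
Q matrix computed as `(m-2)·D - r_i - r_j` is asymmetric at the last
ulp because subtraction order differs across the diagonal, so the
minimum is taken over the symmetrized matrix.

The nonparametric bootstrap resamples columns with replacement
(site bootstrap, ignoring partition boundaries), replicate `r` seeded
with `seed + r`. Supports are the percentage of replicate trees
containing each internal bipartition of the point tree. Replicates
occasionally drive a pair past the correction ceiling; such pairs are
capped slightly above the largest defined corrected distance in that
replicate so the replicate still contributes rather than aborting the
run.

## Saturation slope

For an alignment and a tree sharing ≥ 3 taxa, all unordered shared
pairs with defined p-distance enter an OLS fit of **p (y) on
patristic distance (x)** with free intercept — the classic saturation
plot. Slope 1 means every inferred substitution is observed; the
slope decays toward 0 (locally like `exp(-d/b)` with
`b = (s-1)/s` under the equal-rates model) as multiple substitutions
accumulate. The free intercept makes the statistic robust to small
additive biases; for unsaturated data the slope-1 diagnostic is
unaffected. The orientation matters: regressing patristic on p would
make the slope *grow* with saturation and break the "slope 1 = no
saturation, smaller = worse" reading that the per-gene ranking
relies on, so the observed-on-inferred orientation is used
throughout and documented here for users comparing against other
implementations. Per-partition slopes are computed against the same
fixed tree and ranked descending; partitions with fewer than 3 usable
pairs are reported as undefined rather than dropped.

## Congruence screen

For each gene tree, the reference is restricted to the gene's taxa
(degree-2 nodes suppressed, lengths summed, supports merged by max),
and every non-trivial gene split with support ≥ the threshold
(default 70) is tested for split compatibility — two splits are
compatible iff one of their four pairwise side-intersections is
empty. The conflict rate pools genes: total conflicting supported
splits over total supported splits across all gene trees. The
pooled denominator is a design choice (per-gene averaging would weight
small genes equally with large ones); it is monotone non-increasing
in the threshold. Genes sharing < 4 taxa with the reference
contribute no testable branches (logged); a threshold above 100
yields rate 0 with an explicit no-testable-branches flag. Conflicts
are reported with their supports, never auto-classified into
contamination vs. paralogy vs. reconstruction error — that judgment
needs an expert and more context than one screen.

## Taxon-sampling experiments

An experiment is a set of named conditions (taxon keep-sets, each
≥ 4 taxa) over one supermatrix plus named focal clades. Conditions
are validated up front, before any inference. Each condition is
analyzed either with an externally supplied Newick tree (supports
read verbatim; no inference is run) or with the internal
NJ + bootstrap engine; the per-condition seed is
`seed + crc32(condition_name)`, so results are independent of
condition order. A focal clade is evaluated on its surviving members
within each condition — the sampling experiments change member
counts by design — with two labeled non-numeric outcomes: `absent`
(no edge isolates the survivors) and `not evaluable` (< 2
survivors, or the survivors exhaust the condition). Deltas against a
baseline propagate these labels (`lost (was 96)`), never silently
coercing to 0. The outgroup series builds one condition per prefix
of a near→far outgroup list, which is how "does adding the distant
outgroup erode ingroup support?" is asked operationally.

## Simulator

Sequences evolve by a continuous-time reversible process with
off-diagonal rates `q_xy ∝ r_xy · π_y`, normalized so that one unit
of branch length is one expected substitution per site at that
site's rate. Two modes share this machinery:

* **homogeneous** — one frequency vector π for all sites, optional
  symmetric exchangeabilities `r_xy` (uniform by default, giving the
  s-state equal-rates model the distance corrections invert exactly);
* **profile mixture** — each site draws one of K frequency profiles
  (uniform exchangeabilities, so profiles differ only in which
  residues the site accepts). Sparse Dirichlet(α = 0.1) profiles give
  per-site state spaces of a few residues, the regime in which
  observed distances saturate far faster than a site-homogeneous
  model expects — precisely the model-violation mechanism behind the
  long-branch artifact the diagnostics must reproduce.

Transition matrices come from the eigendecomposition of the
symmetrized rate matrix, restricted to the profile's support (states
with zero frequency are never entered; a single-residue profile
yields an invariant site); rows are clipped at 0 and renormalized to
absorb rounding. Rate variation is the 4-category equal-probability
discrete gamma (category rates are conditional means, renormalized
to average exactly 1) times a per-gene multiplier, both rescaling
branch lengths per site. Each (gene, site) owns an independent
random stream (`SeedSequence(seed, spawn_key=(gene, site))`), with a
fixed draw layout (rate category, profile, root state, one draw per
non-root node in preorder), so adding genes or sites never perturbs
previously generated data and every run is byte-reproducible.

Scenario generators: `make_lba_tree` builds the two-long/two-short
quartet (defaults long 1.0, short 0.1, internal 0.02
substitutions/site — inside the classic attraction zone; all lengths
are configuration, since no canonical values exist) with an optional
outgroup attached to the midpoint of the central edge;
`make_balanced_tree` builds the uniform-edge 8-taxon tree used in
saturation experiments, where "tree height 0.05" is read as
tip-to-tip diameter 0.05 — at that depth the saturation slope is
provably within a few percent of 1, which is what "unsaturated
baseline" must mean for the slope-1 anchor to hold;
`implant_transfer` copies a donor's gene block over a recipient's
(contamination/xenology ground truth, logged in the supermatrix's
event metadata); `mask_missing` raises the missing fraction to a
target by masking random cells or whole gene-by-taxon blocks,
landing within one masking unit of the target and never touching
already-missing cells.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the diagnostics
assume: heterogeneous per-gene rates, site-heterogeneous acceptance
profiles, controllable branch-length geometry, implanted xenologs,
masked missing data. It deliberately omits indels and alignment
error, sequencing artifacts and frameshifts, codon structure,
compositional drift across lineages, heterotachy and incomplete
lineage sorting. Passing tests therefore demonstrate that the
statistics behave correctly *given* their model of the nuisance
processes — e.g. that the congruence screen flags implanted
transfers and nothing else on clean simulated genes — not that real
datasets are free of the omitted complications.

## Problem sizes

The validation suite runs at the sizes the analyses are designed
around: 200 random 6–10-leaf trees for the NJ/additivity oracle;
10,000 sites × 3 seeds per branch-length multiplier (×1/×5/×20) for
the saturation sweep; 20 genes × 1,000 sites with 100 bootstrap
replicates for the congruence screen; 50 seeds × 5,000 sites per
long-branch length (0.5/1.0/2.0) for the attraction frequency. These
sizes put Monte-Carlo noise well below every margin being asserted
while keeping a full run in tens of seconds on one core.

## Known limitations

* Distance corrections ignore exchangeability structure and
  compositional heterogeneity; slopes computed against NJ trees
  inherit NJ's biases at deep divergences.
* The bootstrap resamples sites, not genes; gene-level resampling is
  out of scope.
* The congruence screen's pooled denominator is one of several
  defensible conventions; compare rates across tools with care.
* Saturated pairs capped during bootstrap replicates slightly
  compress the deepest replicate branch lengths; supports are
  unaffected in the regimes tested.
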