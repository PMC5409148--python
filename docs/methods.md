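# Methods

This note documents the models implemented in `otudelim`, the choices made
where the methods' published descriptions leave details open, what the
synthetic benchmark does and does not emulate, and the package's known
limitations. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Distances

Distances are computed per pair with pairwise deletion: any column holding
a gap (`-`), missing symbol (`?`), or IUPAC ambiguity code in either
sequence is excluded from that pair's comparison. Pairwise (not complete)
deletion is used because barcode compilations routinely mix full-length and
shorter database sequences; complete deletion would discard the columns the
long sequences do share. Ambiguity codes are treated as missing throughout
(state counting, base composition, distances) — the conservative convention
for Sanger barcode data, where ambiguities are rare call failures rather
than polymorphism evidence.

JC69 and K2P use their closed forms. A pair whose observed divergence
leaves the correction's domain (p ≥ 3/4 for JC69; 1−2P−Q ≤ 0 or 1−2Q ≤ 0
for K2P) is *flagged saturated* and carries NaN: downstream maxima skip
saturated entries with a warning rather than propagating infinities, which
keeps reconciliation thresholds finite. Distances are kept in
substitutions/site internally; percentages appear only in display.

Site statistics: a column is variable when ≥ 2 distinct unambiguous
nucleotides occur in it, parsimony-informative when ≥ 2 states each occur
in ≥ 2 sequences. Codon-position breakdowns assume the caller supplies the
reading-frame offset (default 0, i.e. column 1 is a first position).

## Barcode-gap discovery

The gap rule is deterministic and oracle-checkable. For ascending unique
distances `u_1 < u_2 < …` and prior *P*: the *slope* at candidate *i* is
the maximum consecutive difference among distances ≤ `u_i` (floored at
1e-6 when there is none); the first *i* with `u_{i+1} − u_i > X·slope_i`
and `u_{i+1} > P` defines the gap `(u_i, u_{i+1})`. This is a concrete
rendering of the published method's slope-relative significance criterion;
bit-exact agreement with the original web server is not claimed. The
initial partition is single linkage (connected components of the
distance < threshold graph, via scipy's sparse `connected_components`)
just above the gap's lower bound; recursion re-applies the rule within
each group on intra-group distances until no group splits, capped at depth
10 with a warning.

The prior grid defaults to 50 log-spaced values on [0.001, 0.1] with
relative gap width X = 1.5. Log spacing matches the behavior implied by
published chosen priors that do not sit on a linear grid. Because the
original method's selection of a single working prior is not specified
anywhere, the package uses a *plateau rule*: the partition chosen for
downstream use is the modal recursive partition across the scan, reported
at the largest prior attaining it. Both initial and recursive group counts
are always reported. On data without a global barcode gap (e.g. faunas
with species splits younger than the coalescent noise floor), the scan can
collapse to one or two groups over most priors; this is the gap method's
documented failure mode, and the integrative step is designed to survive
it.

## Neighbor joining

NJ is included as a lightweight stand-in inference for testing and
simulation work; user-supplied trees always take precedence in the
pipeline. Ties in the Q criterion resolve to the lowest-index pair.
A negative branch length is clamped to zero with the deficit moved to its
sibling, preserving the pair's summed length (and hence additive-matrix
recovery). Rooting is on the supplied outgroup (splitting its edge at the
midpoint) or at the midpoint otherwise.

## Single-threshold mixed Yule-coalescent model

Input is a rooted, strictly bifurcating ultrametric tree. Ultrametricity
is checked to a relative tolerance (default 1e-6 of root height,
configurable); tied or zero-separated branching times are perturbed
downward by ≤ 1e-9 with a warning, because the interval likelihood needs
distinct event times.

With events ordered rootward→tipward and `x_i` the waiting time between
events *i* and *i+1*, the rate in interval *i* is
`b_i = λ_Y·n_i^{p_Y} + λ_C·(Σ_j n_{i,j}(n_{i,j}−1))^{p_C}`. Above the
threshold all lineages belong to the species-level class and `n_i` is the
running lineage count; below it, `n_i` freezes at the number of entities
and the coalescent term accumulates per cluster. The scaling exponent is
applied outside the coalescent sum; the independent brute-force oracle in
the tests uses the identical form, so this choice is pinned rather than
hidden. Each of the n−2 inter-event gaps contributes `b_i·exp(−b_i·x_i)`
(the root event is conditioned on); the final gap from the youngest node
to the present contains no event and contributes the survival factor
`exp(−b·x)` only — the statistically complete censoring term, verified
empirically not to alter delimitation behavior.

Threshold candidates sit at midpoints between consecutive branching times
plus one candidate below the youngest node. That last candidate makes the
all-Yule configuration (every tip its own entity) available, so the null
model — a single rate class `λ·n^p` over the whole tree — is exactly
nested and `max logL(mixed) ≥ logL(null)` holds by construction.

Optimization is L-BFGS-B on (log λ_Y, p_Y, log λ_C, p_C) with analytic
gradients, five seeded jittered restarts per candidate plus warm starts
from the previous candidate and from the null fit. Rates are bounded in
log-space at ±25; the scaling exponents are optimized over [0, 5], the
conventional interval for this model — negative exponents (event rate
falling with lineage count) are biologically unmotivated and let the mixed
model overfit pure-birth trees. Setting
`scaling_exponents_free=False` fixes both exponents at 1.

The likelihood-ratio statistic 2·(mixed − null) is referred to χ² with 3
degrees of freedom by default (threshold + second rate + second exponent),
configurable to 1 or 2. Two statistical properties of this model class are
worth knowing and are measured, not hidden, by the benchmarks: the LRT is
mildly liberal under threshold profiling (its type-I error sits near, and
with some seeds above, the nominal 5–10% band), and on two-regime data the
exact entity count is sensitive to the tail of the within-species
coalescent depth distribution — the model sometimes classifies the deepest
within-species coalescences as speciation events and oversplits by one or
two. The acceptance script reports both rates as measured.

## Reconciliation

Order of operations: congruence → similarity merging → geography. Robust
(congruent) OTUs pass through unmodified and never merge. The similarity
threshold τ is derived as the maximum within-OTU K2P distance over the
congruent OTUs (an error instructs the user to set τ manually when all
congruent OTUs are singletons; the pipeline orchestration then falls back
to the conventional 3.2% barcode threshold). Merging is strict
(`K2P < τ`; ties do not merge), requires non-monophyly of at least one
candidate in at least one gene tree, and closes transitively within a
recognized species. OTUs mixing recognized-species labels are flagged
`unresolved_flagged` and never auto-merged. Monophyly is evaluated after
pruning trees to the partition's samples; samples absent from the nuclear
tree abstain from that tree's test (`require_both_gene_trees=False`
downgrades to barcode-tree-only).

"Sister OTUs" for the geography step requires both OTUs and their union to
be clades on the barcode tree. A sister pair is eligible only when both
OTUs carry the same recognized-species labels — a label difference is
itself evidence against lumping, and without this constraint the rule
would cascade up the tree merging distinct species whose ranges happen to
be disjoint. Allopatric eligible sisters merge unless a morphology-distinct
flag links them (then they are kept, with a note in the trail); sympatric
sisters are kept and labelled `split_sympatric`. The rule iterates to a
fixpoint. Any final OTU no rule touched is labelled `unresolved_flagged`
with an explanatory note, so the trail is exhaustive and reruns are
bit-identical.

## Synthetic benchmark

The generator emulates a regional multi-species barcode survey:

- **Species tree**: forward Yule simulation conditioned on the tip count,
  rescaled to a crown age drawn uniformly from 12.8–16.6 My (the
  calibration window for the clade that motivated the package's default
  scales). `min_species_separation` optionally resimulates until the
  youngest split clears a floor — used to construct clean two-regime
  benchmark conditions; the default (0) leaves recent splits in, as real
  faunas have them.
- **Gene tree**: censored multispecies coalescent via msprime (haploid
  sample sets per species population on the species-tree demography), so
  lineages coalesce within their species branch and continue in ancestral
  species; incomplete lineage sorting is controlled by `coalescent_depth`,
  the expected within-species pairwise coalescent time (default 0.1 My).
- **Sequences**: gap-free evolution under the two-parameter (K80) process
  with closed-form branch transition probabilities, transition/transversion
  ratio κ = 4 and clock rate 0.01 substitutions/site/My (≈ 2%/My pairwise,
  a standard fish-COI scale), at 618 bp. The generator deliberately matches
  the model the distance estimator assumes, so estimation bias is excluded
  from pipeline tests; an HKY mode with unequal base frequencies is
  available as explicit misspecification.
- **Regions**: four-region labels per sample. `allopatric_split` gives
  sister units disjoint single regions; `sympatric` gives every sample the
  shared SCS+CT region, so overlap holds for any subsample of any unit
  (not just whole units — delimitation fragments must never look
  allopatric under this scenario); `random` draws one- or two-region sets
  uniformly with samples assigned round-robin over the set.
- **Cryptic-pairs mode** grafts a cherry of two populations (default split
  1.0 My) onto each species tip, with recognized species = the pair. It is
  the scenario that exercises the geography rule: populations are deep
  enough for the threshold model to resolve but their distances sit inside
  the intra-species continuum, so the distance scan stays at (or near)
  species rank and the population OTUs arrive at the geography step
  incongruent.

Default dataset shape is 50 species × 6 samples (≈ 300 sequences, 618 bp),
mirroring a survey-scale compilation. The benchmark experiments in
`otudelim.benchmarks` use the sizes fixed in their docstrings: type-I on
100 pure-birth 50-tip trees; species-count recovery and pipeline ARI on 50
replicates of 10 species × 5 samples with coalescent depth 0.1 My and
youngest species split ≥ 1.0 My; geography scenarios on 8 replicates of 6
species × 2 populations × 4 samples (population split 1.0 My, coalescent
depth 0.05 My, species splits ≥ 3 My).

What passing these benchmarks does *not* show about real data: the
generator has no alignment error, no misidentified or contaminated
database sequences, no rate variation among lineages or sites, no
saturation at deep divergences beyond what the clock produces, equal base
frequencies (unless the misspecification mode is on), and species
boundaries that coincide exactly with gene-tree structure. Real surveys
violate all of these to some degree; the decision-trail design exists
precisely because automatic delimitation on real data needs auditing.

## Numerical choices

- Distance matrices: symmetric by construction; diagonals exactly zero;
  `-0.0` normalized away in NJ branch lengths.
- Gap threshold: single linkage is applied at `lower + min(1e-9,
  width/2)`, which is equivalent to any cut inside the gap.
- Optimizer: `ftol` 1e-8 (configurable), `maxiter` 500; non-convergence
  from every start raises with the offending threshold candidate.
- Tie-breaks: NJ picks the lowest-index pair; the plateau rule breaks
  modal ties toward the plateau reaching the largest prior; threshold
  candidates tie toward the first (deepest) maximizer.
- Degenerate inputs: empty metadata warns and returns an empty list;
  single-group partitions yield an empty inter-OTU table; a pair with zero
  comparable sites is a hard error naming the pair.

## Limitations

- The threshold model fits one global transition time; multiple-threshold
  variants are out of scope.
- The gap scan's plateau rule can select a degenerate coarse partition on
  gapless data (reported honestly; see above).
- NJ is not a substitute for model-based tree inference and is labelled
  accordingly.
- Morphology enters only as pre-annotated pairwise distinctness flags; no
  measurements are computed.
- GenBank-style misidentification detection is out of scope; OTUs mixing
  recognized species are flagged for manual work, as practice requires.
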