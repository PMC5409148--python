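# otudelim

Integrative DNA-barcode species delimitation for multi-species sequence
surveys: automatic barcode-gap discovery on pairwise genetic distances, the
single-threshold generalized mixed Yule-coalescent (GMYC) model on an
ultrametric gene tree, and a reconciliation procedure that resolves the two
methods' disagreements with four supplementary criteria — genetic
similarity, gene-tree monophyly, geography (sympatry on a four-region
frame), and morphological distinctness flags. A coalescent simulator
generates benchmark datasets with known species truth so every stage of the
pipeline can be validated end to end.

It is written for molecular taxonomists and biodiversity researchers who
have a per-locus alignment (typically mitochondrial COI, optionally a
nuclear locus such as RAG1), an ultrametric tree, and sample metadata, and
who want reproducible operational taxonomic units (OTUs) with an explicit
decision trail for every lump and split.

## Models

**Distances.** Pairwise distances use pairwise deletion (columns with a
gap, `?`, or ambiguity code in either sequence are skipped per pair).
With *P* and *Q* the proportions of compared sites differing by a
transition (A↔G, C↔T) and transversion respectively:

- Jukes–Cantor: `d = −(3/4)·ln(1 − 4p/3)` for p-distance *p*,
- Kimura two-parameter (K2P): `d = −(1/2)·ln(1−2P−Q) − (1/4)·ln(1−2Q)`.

Pairs outside the correction's domain are flagged saturated rather than
clamped.

**Barcode-gap discovery (ABGD).** For each prior intraspecific divergence
*P* on a grid (default 0.001–0.1, 50 log-spaced steps), the first jump in
the ranked unique distances that exceeds *X* (default 1.5) times the
largest consecutive difference among the smaller distances, and that ends
above *P*, defines the barcode gap; samples are partitioned by single
linkage below the gap and each group is refined recursively. The
partition selected for downstream use is the modal one across the prior
scan, taken at the largest prior attaining it (the plateau rule).

**Single-threshold GMYC.** On an ultrametric gene tree, branching events
older than a threshold *T* follow a Yule (pure-birth) process and younger
events follow within-species coalescence. With waiting times `x_i` between
successive events, the event rate in interval *i* is

```
b_i = λ_Y · n_i^{p_Y} + λ_C · (Σ_j n_{i,j}(n_{i,j}−1))^{p_C}
```

where `n_i` is the species-lineage count (frozen at the number of entities
below *T*) and `n_{i,j}` the gene-lineage count of cluster *j*. The
threshold is profiled over midpoints between branching times, the four
rate/scaling parameters are optimized by bounded quasi-Newton, and a
likelihood-ratio test (χ², default 3 df) compares the mixed model against a
single-process null. Entities (clusters + singletons) are the delimited
OTUs.

**Reconciliation.** OTUs with identical membership in both methods are
robust. Within a recognized species, incongruent OTUs merge when their
maximum cross K2P distance is strictly below a threshold τ (derived as the
largest within-OTU distance among congruent OTUs, paper-style) *and* at
least one of them is non-monophyletic in at least one gene tree. Sister
OTUs on the barcode tree then merge when their regions (IO, ECS, SCS+CT,
SAS) are disjoint — unless a morphology-distinct flag separates them —
while sympatric sisters stay split. Every final OTU carries one decision
label: `robust_congruent`, `merged_similarity`, `merged_allopatric_sister`,
`split_sympatric`, or `unresolved_flagged`.

## Worked example

Simulate a survey-scale dataset (50 species, 300 samples, 618 bp) and run
the stages from the shell:

```text
$ otudelim simulate --seed 5 --out sim
50 species, 300 samples -> sim

$ otudelim dist sim/alignment.fasta --model k2p --out dm.tsv
300 samples, model k2p -> dm.tsv

$ otudelim abgd sim/alignment.fasta --model k2p --out-prefix abgd
chosen prior 0.1: 1 groups

$ otudelim gmyc sim/gene_tree.nwk --seed 1 --out gmyc.tsv
T = 0.466915  logL(mixed) = 1593.2337  logL(null) = 1523.3162  LR = 139.835
p = 4.102e-30  entities = 52 (clusters = 50)

$ otudelim reconcile --abgd abgd.partition.tsv --gmyc gmyc.tsv \
    --meta sim/metadata.tsv --dist dm.tsv --coi-tree sim/gene_tree.nwk \
    --tau 0.032 --out-prefix rec
{"n_robust": 0, "n_revised": 0, "n_final": 52, "n_matching_recognized": 48,
 "tau": 0.032}

$ otudelim evaluate --inferred rec.partition.tsv --truth sim/truth.tsv
{"adjusted_rand_index": 0.9932, "n_exact_species_matches": 48,
 "n_lumped": 0, "n_split": 2}
```

Reading the output: this fauna includes species pairs younger than the
barcode gap, so the distance scan collapses (1 group at its chosen prior —
the method's documented behavior when no global gap exists), while the
threshold model finds 52 entities at T ≈ 0.47 My with a decisively
significant likelihood-ratio test. Reconciliation at the conventional
τ = 3.2% leaves 52 final OTUs; 48 of the 50 true species are recovered
exactly (adjusted Rand index 0.993), and the two misses are species split
in two (`n_split`). The same analyses are available in Python via
`otudelim.run_pipeline`.

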