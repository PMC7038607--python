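# Methods

## Problem

Whole-metagenome shotgun (WMS) reads carry fragments of microbial genes.
Profiling a community's *metabolic functional capacity* means binning those
reads by the enzymatic function of the protein they came from — indexed by
Enzyme Commission (EC) numbers — rather than by taxon. Alignment-based
annotation is slow and brittle for reads from proteins absent from the
reference; `ecprofiler` instead classifies reads in a compact
locality-sensitive feature space in which remote homologs of a reference
family still look similar.

## Gold-standard reference

The training corpus is a set of protein records, each with exactly one
*complete* EC number (all four fields numeric, no `-` wildcard). Curation
keeps records that are reviewed, have protein- or transcript-level
(experimental) evidence of existence, and carry a single complete EC label;
computationally inferred annotations, incomplete labels, and multi-EC
records are dropped, and byte-identical sequences are collapsed to the
first-seen record. Rejections are counted per filter (a record is charged
to the first filter it fails) so `rejected + retained == input` always
holds. Evidence is an explicit per-record enum in the annotation TSV;
mapping a live database's evidence codes onto it is the caller's job.

Redundancy means byte-identical amino-acid sequence; we deliberately do not
cluster at an identity threshold, because near-duplicates at sub-100%
identity are informative training variation.

Per EC bin *b* the curation also records p_b, the **mean protein length**
of the bin in amino acids. "Effective protein length of a bin" admits
several aggregations; the arithmetic mean is used for stability and is
stored in the model manifest so a trained model is self-describing.

## Even-coverage gapped k-mer hashing

A gapped (k, r)-mer reads r of the k positions of a window; mismatches at
the k−r unselected positions are invisible, which is what makes the
representation tolerant of the substitutions that accumulate between
homologs. The feature id of window *w* under selection function *j* with
positions p_0 < … < p_{r−1} is

    id = j * 20^r + Σ_i code(w[p_i]) * 20^i

with `code` the rank in the fixed alphabetical amino-acid order
`ACDEFGHIKLMNPQRSTVWY` (any fixed order works; this one is stored in the
ensemble manifest). Defaults are k=8, r=4, m=16 functions; m trades
feature-space size against coverage redundancy and is a mandatory manifest
field. Windows containing non-standard residues (B, Z, X, U, O, …) are
skipped for all functions rather than expanded — expansion would be
nondeterministic or exponential.

Choosing the m position subsets uniformly at random covers the k window
positions unevenly unless m is large. The ensemble is therefore built with
an LDPC-style (Gallager) round construction: each round orders the k
positions by ascending current coverage with seeded random tie-breaks, then
splits the first r·⌊k/r⌋ of them into ⌊k/r⌋ disjoint blocks of r. On a
full round over fresh positions this is exactly a random permutation split
into blocks; ordering by coverage is what keeps the global guarantee
`max coverage − min coverage ≤ 1` exact even when a round is cut short at
m functions or when r ∤ k forces k mod r positions to be dropped per round
(the dropped positions are then always the currently most-covered ones).
Reconstruction from (k, r, m, seed) is bit-identical, and the ensemble
serializes to JSON with an exact round-trip.

Optional feature folding maps ids into 2^b buckets (b=26 when enabled)
through a fixed, seedless splitmix64 mixing step, mirroring fixed-width
feature tables in online-learning frameworks; collisions are accepted
silently. Folding is off by default.

## One-vs-all online classifier ensemble

One sparse linear scorer (weights + bias) is trained per EC label, plus one
for an explicit background class. Training is online — one encoded example
in memory at a time — with stochastic gradient descent:

* loss: hinge (linear SVM) by default, logistic available;
* learning rate: inverse scaling, η_t = η₀ / (1 + η₀ λ t) with η₀ = 0.5;
* L2: λ = 10⁻⁶, applied through a lazily maintained per-label scale factor
  so each example costs O(nnz) rather than O(dim);
* deterministic given the stream seed; warm-starting an existing model adds
  fresh weight rows for new labels and continues existing ones.

**Fragment training.** Reference proteins are full-length but the ORFs to
be classified are short (~30 aa at 90–150 bp reads). To match the train
and test feature distributions, each protein contributes c = 10 fragments
of ℓ = 30 aa at seeded uniform start positions. This is a deliberate
interpretation: training on whole proteins and testing on fragments would
mismatch total feature mass per example.

**Background class.** Negative examples are composition-preserving
(seeded Fisher–Yates) shuffles of the reference proteins themselves, one
per protein by default (1:1 with positive proteins); an external background
FASTA (e.g. host proteins) may be supplied instead. Shuffling preserves
residue composition while destroying positional structure, so the
background scorer learns to absorb sequences that merely share composition
with an enzyme family.

**Decision rule.** A fragment receives the argmax EC label only if that
score strictly exceeds both 0 and the background score; otherwise it is
unassigned. Ties break to the lexicographically smallest EC label. Raw
margins are used — no calibration or softmax — since only the argmax and
the reject decision matter downstream. The rule for "all margins negative"
(reject) is an explicit design choice.

Models persist as a directory: `manifest.json` (labels, hyperparameters,
p_b table, SHA-256 of the ensemble JSON), `ensemble.json`, and one
`feature_id<TAB>weight` sparse text file per label. Loading refuses a model
whose ensemble file does not match the manifest hash.

## ORF calling

Reads are mid-gene fragments, so the built-in caller translates all six
frames under the bacterial/archaeal code (table 11), and every maximal
stop-free stretch of ≥ 20 aa is emitted — no start codon required, no
error model. Codons containing N translate to X (the encoder then skips
windows containing X). Intervals are 0-based half-open on the forward
strand; strand is the sign of the frame. min_len_aa = 20 (≈60 bp) because
shorter stretches carry fewer than 13 k=8 windows. Output of an external
probabilistic ORF caller can be imported instead (FragGeneScan-style
`readid_start_end_strand` headers are parsed; other headers are kept with
unknown coordinates); all ORFs of a read are classified and each assigned
ORF contributes one count.

## Abundance normalization

Raw assigned counts r_b favor long proteins. With p_b the bin's mean
protein length (aa) and rl the sample's mean read length (bp):

    e_b = p_b − rl/3 + 1                      (effective protein length)
    ρ_b = (r_b / e_b) · 10⁶ / Σ_b (r_b / e_b) (effective counts per million)

e_b counts the distinct in-protein start positions a read can take and is
clamped below at 1 for proteins shorter than a read (a degenerate case the
formula does not otherwise cover). Σ_b ρ_b = 10⁶ for every sample with at
least one assigned ORF, which makes profiles directly comparable across
sequencing depths; raw counts are always written alongside. rl is computed
per sample as the mean input read length before ORF calling. RPK-style and
raw outputs exist behind a flag for comparison experiments only.

## Pathways

Pathway abundance is the plain sum of member-EC ρ values; an EC in several
pathways contributes to each (standard pathway-mapping behavior). Coverage
is |detected ∩ members| / |members|. The EC→pathway map is user-supplied
TSV — reference maps cannot be redistributed — and a small fictional map
ships with the tests.

## Comparative statistics

* **Differential abundance** — per-feature two-sided Mann–Whitney U;
  exact null enumeration when both groups have n ≤ 8 *and* the feature has
  no ties (the exact method has no tie correction), otherwise the normal
  approximation with tie and continuity corrections; constant features get
  p = 1 by convention. Benjamini–Hochberg step-up across features.
  Fold change is log2 of the ratio of group means with one pseudo
  effective count; log2 chosen because conventional thresholds like 0.58
  correspond to a 1.5× ratio. Significant ⇔ BH-adjusted p < 0.05 and
  |log2 FC| > threshold.
* **Shared significance** — Fisher's combined probability test across
  cohorts: X² = −2 Σ ln p_i with 2·n_cohorts degrees of freedom; a single
  cohort is rejected rather than degenerately "combined"; p = 0 inputs are
  clamped to the smallest positive double with a warning.
* **Co-abundance** — pairwise Kendall τ-b (tie-corrected); constant
  features reported as τ = 0 and flagged; unit diagonal.
* **Clustering** — Ward linkage (scipy) on the rows of the square
  co-abundance (correlation) matrix under Euclidean distance, cut to 2–5
  clusters; when a correlation matrix is derived from sample profiles,
  1 − Pearson is the distance transform used upstream.
* **PERMANOVA** — SS_total = (1/n) Σ_{i<j} d²_ij;
  SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij; pseudo-F =
  (SS_between/(a−1)) / (SS_within/(n−a)); p = (1 + #{F_perm ≥ F_obs}) /
  (1 + n_perm) under seeded unrestricted label permutations. On 1-D data
  with |x_i − x_j| distances this reproduces the classical one-way ANOVA F
  exactly (tested).
* **Diversity** — Shannon–Wiener H = −Σ q ln q (natural log, 0·ln 0 ≡ 0).
* **Ordination** — column-centered SVD; variance fractions from squared
  singular values; loadings exposed for high-weight EC selection.
* **Marker evaluation** — stratified N-fold CV; features screened inside
  each fold by *raw* rank-sum p < 0.05 on training samples only (raw, not
  BH-adjusted, deliberately: screening is not inference, and the two
  thresholds are separate knobs); a seeded random forest per fold
  (n_repeats forests averaged), scored by AUC; 95% CI across folds as
  mean ± 1.96·sd/√N. A leakage-mode flag reproduces whole-dataset
  selection to demonstrate the optimistic bias that fold-internal
  selection avoids.

## Synthetic data generator

The generator defines the study conditions for every end-to-end test:

* **Families** — one uniform-random ancestor per fictional EC (reserved
  9.x.y.z namespace), members by i.i.d. per-site substitution at divergence
  d = 0.15 by default (expected member–member identity per site
  (1−d)² + d²/19 ≈ 0.72); 20 ECs × 8 members, lengths uniform 150–300 aa.
* **Reads** — source protein drawn ∝ weight, back-translated with
  uniformly random synonymous codons (table 11), uniform substring of
  150 bp, strand flipped with probability 1/2, i.i.d. substitution errors
  at 10⁻³ (typical Illumina substitution scale), constant quality FASTQ,
  truth TSV mapping read → source EC.
* **Cohorts** — per-EC baseline abundance log-normal (median 100,
  σ_log = 1); per-sample counts negative-binomial around the baseline with
  dispersion 0.3 (var = μ + 0.3 μ², the overdispersion scale typical of
  metagenomic count data); planted features' case-group means multiplied
  by fold change 4 in both cohorts; 20 samples per group.

What the generator does *not* emulate: taxonomic community structure,
indels and quality-dependent errors, GC/codon bias, compositionality
beyond the per-million rescale, and covariate structure. Tests passing on
this generator therefore demonstrate correctness of the algorithms under
controlled conditions, not performance on real stool metagenomes.

## Evaluation protocols and problem sizes

`ecprofiler.evaluation` fixes the experiment designs (all driven by one
seed):

* held-out recovery: leave the last member of each of 20 families out,
  train on the rest (5 epochs), classify 10 fragments of 30 aa per
  held-out member; compare macro recall against chance (1/20) and against
  a naive exact-8-mer lookup baseline over the same training proteins;
  shuffled-sequence fragments must receive a real label < 10% of the time;
* PERMANOVA calibration: 500 structureless Gaussian replicates (2×10
  samples, 5 features, 199 permutations) — the rejection rate at α = 0.05
  must sit inside the exact binomial 99% interval;
* shared dysbiosis: two independently seeded cohorts, 40 ECs, the same 10
  planted at fold change 4; a shared call needs per-cohort significance
  (BH < 0.05, |log2FC| > 0.58) and Fisher combined p < 0.05; ≥ 8/10
  recovered with zero false shared calls;
* marker CV: planted markers (4/20 features at 6×, 30+30 samples) must
  reach mean AUC > 0.9; with permuted labels the fold-internal mean AUC
  (8 permutation replicates) stays in [0.35, 0.65] and the leakage mode is
  at least as optimistic.

These sizes keep every protocol comfortably within interactive runtimes
while leaving the statistical margins wide (e.g. held-out macro recall
~0.99 vs baseline ~0.91 at the defaults).

## Numerical choices

* Weight updates use float64; the L2 scale factor is folded into the
  weights when it drops below 10⁻⁶ to avoid underflow.
* Encoder indices are int64; folding mixes through splitmix64 before the
  modulo so low-order index structure does not bias buckets.
* BH adjustment delegates to `statsmodels.multipletests` and is verified
  against the step-up definition by brute force in the tests.
* Ward clustering delegates to `scipy.cluster.hierarchy.linkage`; tie
  handling is scipy's; correctness is pinned to an independent
  Lance–Williams recursion on 5-point instances.
* Prediction ties break lexicographically; stream order and all sampling
  use `numpy.random.default_rng` seeded explicitly — no global RNG state.

## Known limitations

* The six-frame caller has no sequencing-error or codon-usage model; a
  probabilistic external caller will do better on error-rich reads.
* Margins are uncalibrated; the reject threshold is implicit in the
  background class rather than tunable per-label.
* The dense per-label weight matrix is memory-hungry at large label
  counts (≈20 MB per 1000 labels per million features); feature folding
  is the intended mitigation.
* Exact rank-sum enumeration is skipped in the presence of ties.
* PERMANOVA assumes exchangeability under unrestricted permutation; no
  strata/blocking support.
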