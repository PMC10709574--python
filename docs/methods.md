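# Methods

## Model

`leukotype` classifies leukemia samples into molecular subtypes with
nearest shrunken centroid (NSC) models over two modalities: DNA
methylation beta values (fractions in [0, 1] per CpG) and log2
GeTMM-normalized gene expression. NSC assumes features are
conditionally independent given the class with common within-class
variance per feature; the pooled standard deviation sᵢ is stabilized by
the offset s₀ (a quantile of the sᵢ, median by default) so that
low-variance features do not dominate. The normalizer is
mₖ = √(1/nₖ − 1/n), the standard error of the class-vs-overall centroid
difference; some formulations print √(1/nₖ + 1/n), and
`m_convention="plus"` switches to it for cross-checking against other
implementations. Posteriors follow the Gaussian discriminant
δₖ(x) = Σᵢ (xᵢ − x̄′ᵢₖ)²/(sᵢ+s₀)² − 2 log πₖ with
pₖ ∝ exp(−δₖ/2), computed in log space with max-subtraction so that
joint underflow degrades gracefully to the prior-weighted argmin of δ.

### Architecture

Each modality trains 13 binary one-vs-rest models — 9 standalone
subtypes, 3 subtype groups (aneuploidies; *ETV6*::*RUNX1* and its -like
signature; *BCR*::*ABL1* and its -like signature), and a CONTROL class
built from non-leukemic samples — plus one within-group model per
group. The aneuploidy group (4 members) uses a multi-class NSC;
two-member groups necessarily use one-vs-one. Binary one-vs-rest
models use uniform priors: the rest class is far larger, and empirical
priors would swamp rare subtypes; within-group models use empirical
priors. CONTROL competes in the step-1 argmax like any class, so a
dominant control signal gates subtype calls in low-blast samples.

A sample is positive for a step-1 class when that class's target
posterior reaches `positive_threshold` (default 0.5, i.e. posterior
majority of the binary model). With no positives the sample is
NO_CLASS; otherwise the highest-scoring positive wins (exact ties break
lexicographically and are flagged, no randomness at prediction time).
A winning group descends to its step-2 model for the final subtype.

### Shrinkage-threshold selection

Each model selects its own Δ on a 30-point grid from 0 to the full-fit
max |dᵢₖ| by stratified 10-fold cross-validation (folds reduced with a
warning when the smallest class is smaller than the fold count),
scoring mean balanced accuracy and taking the **largest** Δ that ties
the maximum (fewest features). Fold assignment is seeded; per-model
seeds are derived deterministically from the training seed and the
class name, so training is reproducible and independent of dictionary
order.

### Consensus tiers

Per-sample calls from the two modalities plus orthogonal molecular
evidence map to a consensus subtype and confidence tier, rules applied
in priority order: tier 1 — a call with score ≥ `high_score` (default
0.8) matching the evidence subtype; tier 4 (conservative) — evidence
contradicting every modality call; tier 2 — both modalities calling the
same subtype; tier 3 — exactly one informative call (single modality,
or one NO_CLASS) with score ≥ `high_score`; tier 4 otherwise. CONTROL
calls count as NO_CLASS here, since a sample predicted non-leukemic
cannot be subtype-annotated. The rule set is total and exclusive over
the truth table of presence × score level × agreement × evidence
(tested exhaustively). Adding matching evidence never increases the
tier; removing a *non-conflicting* call never decreases it — removing
one of two conflicting calls legitimately raises confidence (tier 4 →
3), because a conflict actively argues against the surviving call.

## Preprocessing

- CpG filter: population variance (divide by n) at or above
  `variance_threshold` (default 0.01), optionally intersected with an
  array-manifest whitelist; order and values untouched.
- Gene filter: drop Y and mitochondrial chromosomes, scaffolds
  (anything outside autosomes + X), RPS/RPL ribosomal-protein symbols,
  and non-protein-coding biotypes.
- GeTMM: reads per kilobase, then TMM scaling against a reference
  sample (upper quartile of relative rpk closest to the cohort mean)
  with symmetric trim of 0.30 on M-values and 0.05 on A-values —
  the method's canonical trim fractions — factors renormalized to
  geometric mean 1, then log2(rpk·10⁶ / (Σrpk·factor) + 1). Gene
  weights inside the trimmed mean are delta-method precision weights
  written in relative abundances rather than raw counts, which keeps
  the output exactly (≤1e-9) invariant to scaling any one sample's
  library.
- Missing betas are imputed per feature with the design-set median;
  the imputation values are frozen into the model and reused at
  prediction. Prediction aligns input columns to the model's stored
  feature ids, so feature order never affects results.
- Stratified split: per label, round(n·fraction) (half-up) samples to
  hold-out, at least 1 when n ≥ 2 and 0 for singletons; default
  hold-out fraction 0.33. Discovery-category (B-other) samples must be
  separated by label beforehand.
- Batch correction is an upstream responsibility; matrices are
  consumed as given.

## Synthetic cohorts

The generator emulates the statistical structure the classifier
assumes, at desk scale — defaults: 17 subtypes × 20 samples + 30
controls, 2,000 CpGs, 1,500 genes, 25 informative features per subtype
per modality (disjoint across subtypes), beta-mean shift 0.35,
expression log2 shift 2.0. These sizes keep a full train-and-evaluate
cycle in the tens of seconds while leaving every pathway (groups,
controls, dilution, evidence) exercised; they do not mimic cohort-scale
dimensionality.

Remaining defaults, chosen once as field-realistic values: beta
precision (concentration) 30, giving per-CpG sampling noise of roughly
0.05 standard deviations at the distribution shoulders, comparable to
within-subtype array variability; negative-binomial dispersion 0.1,
typical of bulk RNA-seq biological replicates; gene lengths uniform in
200–10,000 bp; per-sample sequencing depth uniform in 0.5–1.5×;
baseline log2 expression Normal(5, 1.5); evidence emitted for 30% of
leukemic samples; no missing modalities unless configured.

Baseline CpG means follow the array-like bimodal mixture concentrated
near 0.1 and 0.9. Informative shifts are ± in direction but flip away
from the nearer boundary when a random sign would clip (a methylated
CpG hypomethylates, an unmethylated one hypermethylates): clipping
would silently shrink the realized effect far below its stated size
and break the generator's contract that informative features differ
from controls by the configured effect.

Blast-fraction dilution mixes each leukemic sample's mean profile with
the control profile at the signal level before noise — adequate to
exercise the control/no-class pathway, though real low-blast samples
mix at the cell/read level and carry additional heterogeneity.
Structure (baselines, manifests, gene lengths) and sampling noise use
separate child RNG streams of one seed, so cohorts differing only in
blast fraction share identical structure and a model trained at full
blast can score its diluted counterparts.

What passing tests on these cohorts do **not** show: robustness to
batch effects, probe-level array artifacts, correlated features,
subtype signatures of realistic sparsity/overlap, or fusion-read
evidence; the generator's subtypes are cleanly separable by
construction, so synthetic performance is an upper bound, not an
estimate of performance on patient data.

## Numerical choices

- Posterior rows sum to 1 within 1e-12 (log-space softmax).
- Δ = 0 returns the unshrunk class centroids exactly (no
  reconstruction round-off).
- Serialization is JSON text with `%.17g`-style float handling
  (Python's repr), round-tripping float64 bit-exactly; matrices are
  written with `%.17g` and parsed with round-trip float precision.
- PLS canonical: NIPALS with symmetric deflation of both blocks on
  their own scores, tolerance 1e-9, max 500 iterations; variables
  standardized to train-partition mean/sd; test correlations are NaN
  when the test partition has fewer than 2 samples.
- Metrics: NO_CLASS counts against its true class's sensitivity and is
  never a predicted-class match; precision is defined 0 when nothing
  is predicted positive; macro averaging by default, pooled (micro)
  behind a flag.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
default 370-sample, 2,000-CpG / 1,500-gene cohorts (about 15–20 s per
modality per seed on one CPU) and smaller variants for unit tests; the
end-to-end recovery check repeats across five seeds.

## Known limitations

- The 17-subtype vocabulary is fixed to the training cohort's
  subtypes; subtypes absent from a design set are dropped with a
  warning rather than zero-shot predicted.
- Probability scores are raw NSC posteriors, not recalibrated; the
  0.5 positive threshold and 0.8 high-score threshold are heuristics
  exposed as configuration.
- Group membership is hard-coded in the vocabulary; a sample whose
  true subtype is missing from a group's step-2 model resolves to the
  nearest trained member.
- IDAT/array preprocessing, alignment/quantification, fusion calling,
  CNA detection and batch correction are out of scope; inputs are
  consumed as matrices.
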