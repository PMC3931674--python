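# Methods

## Overview

`crcprog` implements a pipeline for inferring colorectal-cancer (CRC) stage
progression from the integration of gene expression and DNA copy-number
alteration (CNA) data. Progression is cast as three *control-vs-case*
classification tasks over tumor stages: II vs III, II vs IV and III vs IV,
with the lower stage as the control group (label 0) and the higher stage as
the case group (label 1). The pipeline asks whether classifiers built on
CNA-informed gene sets — and on *dissimilarity representations* of patients
over those gene sets — keep up with or improve on classifiers built on
differential expression alone.

The stages, in execution order:

1. **simulate** — generate a synthetic multi-cohort study with planted truth;
2. **expression_de** — rank-product differential expression with
   permutation-estimated pfp, intersected across expression cohorts;
3. **cna_calls** — threshold-based gain/loss calls on gene-level log2
   ratios, recurrence within cohorts, verification across cohorts;
4. **signature** — intersection of DE and CNA calls into the up-amplified /
   down-deleted signature;
5. **dissim** — patient-to-prototype dissimilarity representation over the
   signature genes;
6. **infer** — grid-optimized linear-SVM AUC per (criterion, dataset, task);
7. **evaluate** — χ² goodness-of-fit of AUC success/failure counts and
   per-criterion mean ± SEM summaries.

## Synthetic study generator

The generator emulates a multi-cohort CRC study: several expression cohorts
and several CNA cohorts, each with stage II/III/IV patients. It does **not**
model probe-level microarray data, RMA preprocessing, SNP-array intensities,
segmentation, or gene–gene correlation; expression is drawn directly at the
log2 summary level and copy number as gene-level log2 tumor/normal ratios.
Passing tests therefore demonstrate the statistical behaviour of the
pipeline under its own generative assumptions, not performance on real
microarray cohorts.

Gene classes and model, for gene g and sample s:

    x_gs = b_g + u_cg + effect_gs + e_gs,   e_gs ~ N(0, noise_sd)

* baselines `b_g ~ Uniform(4, 12)` log2 units, shared across cohorts;
* cohort batch offsets `u_cg ~ N(0, batch_sd)` per cohort per gene — they
  cancel within a cohort's case/control contrast but make cohorts disagree,
  so the cross-cohort intersection is non-trivial;
* `up_amplified` / `down_deleted` genes: expression shift
  ±`de_effect` × stage step (II→0, III→1, IV→2) applied **only in samples
  carrying the alteration** (dosage coupling); carriers are drawn per sample
  with probability `cna_penetrance` in stages above II;
* `de_only` genes: the same shift in every sample, no CNA; split half
  up-regulated, half down-regulated so the two rank-product directions face
  symmetric competition;
* `cna_only` genes: CNA without expression shift;
* `null` genes: noise only.

CNA cohorts: log2 ratios are `N(0, cna_noise_sd)` plus ±`cna_effect` in
carrier samples. The CNA noise level is a separate parameter
(default 0.15 log2 units, a typical array-level log-ratio dispersion)
because calling thresholds of ±0.3 would be meaningless under the
expression-level noise default of 0.5.

Defaults (the study conditions used by the acceptance checks): 3 expression
and 3 CNA cohorts, 600 genes (50 per planted class), 30 samples per stage
per cohort, `de_effect` 1.0, `cna_effect` 0.8, `cna_penetrance` 0.8,
`noise_sd` 0.5, `batch_sd` 0.5. All randomness flows from a single integer
seed; repeated generation is bit-identical.

## Rank-product differential expression

For a two-class comparison with n1 controls and n2 cases, every one of the
K = n1·n2 case-vs-control sample pairs contributes a fold-change ranking of
all genes (rank 1 = strongest change in the requested direction; ties get
average ranks). The rank product is the geometric mean

    RP_g = ( Π_k rank_gk )^(1/K),

small RP meaning consistent regulation. Significance is the estimated
percentage of false predictions,

    pfp(g) = E_perm[ #{g' : RP*(g') ≤ RP(g)} ] / #{g' : RP(g') ≤ RP(g)},

estimated from class-label permutations (default 100; all C(n, n1)
assignments are enumerated exhaustively when there are at most 10,000).
pfp is made monotone non-decreasing along the RP ranking and clipped to
[0, 1]. Genes pass at `pfp < alpha` with alpha = 0.01 by default
(`alpha = 1` disables filtering and selects every gene). A gene is accepted
only when it passes in the same direction in *every* expression cohort used
for the DE stage (two, in the reference design).

Numerical choices: per-comparison ranks use a fast ordinal path when a
column is tie-free and fall back to average ranks otherwise; RP values are
compared after rounding to 9 decimals so that mathematically tied rank
patterns compare equal regardless of floating-point evaluation order.

Under the global null, pfp behaves like a false-discovery-rate estimate, not
a per-gene p-value: the expected *number* of genes passing `pfp < alpha` is
about alpha, so the per-analysis probability of *any* false selection tracks
the cutoff (~0.01 at alpha = 0.01 with 100 permutations) while the expected
selected *fraction* is alpha/n_genes. The null-calibration checks are
stated in terms of the per-analysis event for this reason.

## Copy-number calling

A gene in a sample is called a gain when its log2 ratio ≥ `gain_thr`
(default +0.3), a loss when ≤ `loss_thr` (default −0.3), neutral otherwise —
a deliberate simplification standing in for a full allele-specific SNP-array
pipeline, which is out of scope; the downstream contract only needs
amplified/deleted gene sets. Within a cohort a gene is recurrently altered
when the call frequency among the task's **case-stage samples** reaches
`min_freq` (default 0.25); the alteration counts overall when it recurs in
the same direction in at least `min_datasets` cohorts (default 2).
Recurrence is evaluated on case-stage samples because the alteration burden
relevant to a progression task is the one acquired by the advanced stage;
the per-task construction (rather than one global CNA set) is a documented
choice, configurable through the task's case stage.

## Combined signature

Per task: `up_amplified = up_set ∩ amplified_set` and
`down_deleted = down_set ∩ deleted_set`. A gene landing in both directions
(possible only with pathological inputs) is dropped from both and logged.
The headline recovery statistic is measured on the full-contrast task
(II vs IV), the task whose case/control gap spans the entire planted
progression; weaker single-step tasks recover fewer coupled genes because
penetrance dilutes their per-step effect.

## Dissimilarity representation

Prototypes P = {y_1 … y_n} are all stage-II patients of the evaluated
cohort (the lowest stage available). Each patient x is represented as

    φ(x, P) = ( D(x, y_1), …, D(x, y_n) ) ∈ R^n

with D computed over the signature genes' expression:

* Euclidean (L2) and Manhattan (L1) distances;
* Kendall τ-distance `(1 − τ_b)/2` with tie-corrected τ_b, in [0, 1];
  undefined (an error) for constant profiles;
* Kullback–Leibler: profiles are mapped back to the linear scale (2^x),
  shifted by a pseudocount of 1e−6, normalized to the probability simplex,
  and compared with the Jeffreys symmetrization ½(KL(p‖q) + KL(q‖p)).

All four are symmetric; the triangle inequality holds (and is tested) only
for L1/L2. For tasks whose control group *is* the prototype stage, control
patients keep their rows — each contains a structural zero at its own
column; prototypes are fixed, not recomputed inside cross-validation folds,
which leaks prototype identity into the representation. This reproduces the
evaluated protocol and is flagged here as a known optimistic bias.

The τ-distance matrix is computed by a vectorized sign-pair product
(identical to per-pair τ_b, which remains the reference path in
`pairwise_distance` and is cross-checked in the tests), falling back to
per-pair evaluation for very long profiles to bound memory.

## Inference and evaluation protocol

Six criteria are compared: NCOMB (expression of DE genes), COMB (expression
of signature genes), and COMBDE/COMBDM/COMBDK/COMBDT (dissimilarity
representation with Euclidean, Manhattan, KL and τ distances). For each
(criterion, dataset, task) cell a linear SVM is scored over a fixed cost
grid — 1101 equally spaced C values from −10 to 10000, non-positive points
floored at 1e−3 (they still count toward the 1101 evaluated models) — by
stratified 10-fold cross-validation (folds shrink to the minority class
size when needed; assignment is seed-reproducible and shared across the
grid). Features are standardized inside each training fold. The per-fold
AUC is computed from the fold's pooled held-out decision scores
(trapezoidal convention for score ties) and averaged over folds; the cell
reports the **maximum over the grid**, reproducing an
optimization-around-cross-validation protocol. This estimate is
optimistically biased by construction; the bias applies equally to every
criterion, and the package's comparisons are always between criteria, never
against an absolute AUC level. Under the null this CV AUC has a standard
deviation of ≈0.07 at 200 samples — folds share training data, so the
spread is wider than the 1/√(12n) binomial intuition — which is the scale
used by the null-behaviour tests.

Evaluation dichotomizes a criterion's AUC cells at cutoffs 0.60 and 0.80
into observed successes/failures (S0, F0) and tests them against the
expected 75%/25% split by a χ² goodness-of-fit with one degree of freedom,

    χ² = (S0 − Se)²/Se + (F0 − Fe)²/Fe,  Se = 0.75·n,  Fe = 0.25·n,

reported with residuals (|Se − S0|, |Fe − F0|); pairwise model comparisons
are read as the two per-criterion tests side by side. No multiple-testing
correction is applied, matching the evaluated protocol. Mean AUC ± SEM per
criterion summarizes the result table (SEM undefined, and reported as NaN,
below two cells).

## Problem sizes used by the acceptance script and heavy tests

* grid cardinality: the full 1101-point grid on one small cell
  (20 samples × 3 features);
* oracle agreement: all matrices up to 5 genes × 6 samples (exhaustive
  label enumeration);
* null calibration: 20 seeds, one cohort of 15 + 15 samples × 300 genes,
  100 permutations;
* signature recovery: 20 seeds at the full default study conditions;
* criterion comparison: 10 seeds of the CNA-concentrated design
  (`n_de_only = 0`, all other defaults), 3 datasets × 3 tasks × 6 criteria
  per seed, with a coarse 11-point C grid — the reported AUC is a grid
  maximum, so a coarser grid can only lower all criteria together and
  leaves the between-criteria comparison unaffected.

## Known limitations

* The generator's genes are independent given the stage; real microarray
  data have correlated blocks, batch-by-stage confounding and heavier
  tails, all of which would lower the pipeline's effective power.
* The threshold CNA caller ignores segmentation and allele-specific copy
  number; `min_freq` is an explicit stand-in for an unstated within-dataset
  recurrence rule.
* The grid-maximal CV AUC is an optimistic estimate; an unbiased variant
  would nest the grid search inside an outer CV loop, which this package
  deliberately does not make the default because the evaluated protocol did
  not.
* Fixed prototypes leak stage-II identity into the representation for tasks
  whose controls are stage II (see above).
* With strong planted effects all criteria saturate near AUC 1.0, so the
  criterion comparison on synthetic data checks a *directional* claim
  (combined/relational criteria keep up with expression-only), not the
  magnitude of any improvement.
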