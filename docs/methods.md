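# Methods

This note documents the generative model, the decoder, the experiment
cases, the map constructions, and the numerical and design choices behind
them.

## Synthetic data model

The generator emulates a slow event-related auditory fMRI study: K = 7
sound categories (English speech, non-English speech, vocal, animal,
mechanical, music, nature) × 6 items per category, each token presented
exactly once per functional run in pseudo-randomized order (orders are
pairwise distinct across runs), 7 runs per subject, TR = 3 s, 5 volumes per
trial, 15 s inter-stimulus interval (42 usable trials and 210 volumes per
run; an equilibration trial is not simulated because real analyses discard
those volumes before estimation).

A sample (the response amplitude pattern of one trial) is

    x = jitter(template_c) * gain_s + offset_s + item_{c,i} + run_{s,r} + noise

with the following components:

| component | default | meaning |
| --- | --- | --- |
| `effect_size` | 1.5 (a.u.) | amplitude of the category template on its informative voxels |
| `n_informative_per_category` | 50 | voxels carrying each category's signal (disjoint by default; `overlap_fraction` shares a common pool) |
| `sigma_item` | 0.6 | sd of item effects, drawn **once per token** on the category's informative voxels and reused across runs and subjects |
| `sigma_run` | 0.3 | sd of a voxelwise offset drawn per (subject, run) |
| `sigma_noise` | 1.0 | iid thermal noise per sample and voxel |
| `spatial_jitter_voxels` | 1 | integer displacement of each category template per subject (imperfect inter-subject alignment); displaced voxels falling outside the mask keep their original location |
| `gain_sd` | 0.25 | sd of the per-subject multiplicative voxel gain field (mean 1) |
| `offset_sd` | 0.1 | sd of the per-subject additive offset map |

Amplitudes are in arbitrary units; the scale that matters is the ratio of
`effect_size` to the noise sds.  Defaults were chosen so that, at the study
design's sample sizes, within-subject decoding is strong while
across-subject generalization is substantially degraded — the regime the
four-case comparison is designed to probe.

Two structural choices matter for interpreting results:

* **Item effects are fixed effects nested within category.**  Because each
  token's pattern perturbation is reused across runs and subjects,
  averaging over items removes exactly this variance component — which is
  what makes the item-averaged case informative.  It also means item
  effects *carry category information by construction* (an item belongs to
  one category), so a dataset with `effect_size = 0` but `sigma_item > 0`
  is **not** a null dataset: a decoder can legitimately classify categories
  from item-specific patterns alone.  Chance-level calibration therefore
  switches off all stimulus-locked components (`effect_size = 0` **and**
  `sigma_item = 0`), leaving run effects and thermal noise.
* **Subject variation = jitter + gain + offset.**  Single-subject recovery
  analyses (does RFE find the planted voxels?) use an unperturbed subject
  (`jitter = 0`, `gain_sd = 0`, `offset_sd = 0`), since with jitter the
  subject's effective informative voxels are displaced relative to the
  group-level ground truth.

The BOLD simulator produces, per voxel, the sum over trials of
`amplitude × HRF(t − onset)` sampled at the TR, plus an optional linear
drift (coefficients ~ N(0, `drift_amp`)) and iid noise.  The HRF is the
canonical double-gamma (shape 6 and 16 gamma densities, undershoot ratio
1/6, peak-normalized; peak ≈ 5 s, h(0) = 0), since the response model of a
given scanner study is rarely stated.  What the generator does **not**
emulate: physiological (cardiac/respiratory) noise, motion, spatial
autocorrelation of noise, field inhomogeneity, or anatomical realism —
the default mask is a ~2000-voxel ellipsoid in a 20×20×10 grid with a
neutral center-origin affine, far smaller than a real temporal-lobe mask.
Passing tests therefore show the *method* behaves correctly under the
assumed variance structure, not that real fMRI meets those assumptions.

## Beta-series GLM

Each run is fitted separately by OLS with one HRF-convolved indicator per
trial (42 columns), an intercept, and Legendre polynomial drift up to order
1 (default) — 44 columns × 210 volumes for the full design.  Per-trial
coding is required because the decoder needs one sample per stimulus per
run.  No prewhitening is applied: the 15 s ISI leaves little trial overlap
and no noise autocorrelation model is assumed.  Rank-deficient designs
(e.g. duplicated onsets) raise a `SingularDesignError`.  Nuisance betas
are discarded; trial betas keep onset order and carry (category, item)
labels.

## MSVM-RFE decoder

* **Binary SVM.**  Soft-margin linear SVM, C = 1 (not tuned; decoding
  studies rarely report C and results here are insensitive at the default
  scale).  The dual is solved by SMO with second-order (maximal-gain)
  working-set selection on a precomputed Gram matrix; stopping rule:
  maximal KKT violation below `tol = 1e-6`.  The bias is recovered from
  free support vectors, or the midpoint of the KKT-feasible interval when
  none are free.  The curvature guard (`eta >= 1e-12`) handles collinear
  pairs.  A generic QP solver (SLSQP on the dual) serves as an independent
  oracle in the tests — the worst primal-objective gap over 100 random tiny
  instances is ~1e-5.
* **Multi-class aggregation.**  One-vs-rest: K binary models sharing one
  active voxel set and one Gram matrix.  Prediction is the argmax of the
  one-vs-rest scores, ties to the earlier class label.  One-vs-rest was
  chosen over one-vs-one for the direct interpretability of its K × p
  weight matrix, which the ranking criterion consumes.
* **Ranking and elimination.**  Voxel score = Σ_c w²_{c,j}.  Each step
  keeps the ceil(p/2) highest-scoring voxels (score ties eliminate the
  lower voxel index first), down to a floor of one voxel — so p = 1024
  yields 11 steps.  Strict halving is used throughout; no switch to
  one-at-a-time elimination near the end.
* **Subset selection.**  Every step records a leave-one-run-out CV error
  (fold-local standardization and training; for pooled multi-subject
  training sets a fold holds out one run index across all subjects).  The
  selected subset minimizes CV error, ties resolved toward the smaller set
  (parsimony), and the final model is refit on the full training set.
  Note the interaction with high SNR: when many redundant informative
  voxels exist, CV error reaches zero over a wide range of subset sizes
  and parsimony picks a small sufficient subset — per-fit recall of *all*
  planted voxels is then bounded by the selected size, which is a property
  of min-CV selection, not a defect.  Recovery is therefore assessed on
  sparse ground truths (~50 informative voxels in total) where the
  error-free band is narrow.
* **Standardization.**  Per-voxel z-scoring with training statistics only;
  test data never influence standardization, elimination, or selection.

## Experiment cases and statistics

* **WithinSub** — per subject: 5 of 7 runs train, 2 test, repeated with
  `n_reps = 5` distinct random partitions (at most C(7,5) = 21 exist).
* **AcrossSub** — leave-one-subject-out; training pools all runs of the
  remaining subjects (run labels still group the inner CV).
* **AvgItem** — voxelwise mean over the 6 items within each
  (subject, run, category), then leave-one-subject-out.
* **AvgSub** — voxelwise mean across subjects for matching
  (run, category, item), then the within-subject scheme on the "averaged
  subject".

Chance level is 1/K.  Case comparisons use pooled-variance two-sample
t tests (df = n1 + n2 − 2; Welch available via flag); accuracy-vs-chance
uses the one-sample t test.  The within-subject accuracy pool for the
two-sample comparison is all subject × repetition values.  No multiple-
comparison correction is applied across the two pairwise case tests.
Subject exclusion is a configuration list, not an automated rule.  Summary
comparisons with zero variance in both groups report NaN statistics rather
than failing.

## Maps and clusters

* **Discriminative map** — per-voxel count of fits whose selected subset
  contains the voxel.
* **Category-selective map** — per (subject, repetition) pair, the set
  difference between the 7-class selection and the matching 6-class
  (category-omitted) selection; a voxel is kept if it appears in ≥ 2
  distinct repetitions **and** ≥ 2 distinct subjects ("more than one"
  on both axes, thresholds exposed as parameters).  The thresholds are
  applied jointly on per-subject and per-repetition counts, before any
  pooling.
* **Conjunction map** — intersection of two survival-thresholded voxel
  sets.
* **Clusters** — connected components under 6- (default), 18- or
  26-connectivity, sorted by size (ties by lowest member voxel index),
  centers as unweighted voxel centers of mass mapped through the grid
  affine.

Voxel linearization everywhere: in-mask voxels ordered by the flat index
`x + nx·(y + ny·z)` (x fastest), 0-based — one fixed, documented map
between matrix columns and grid locations.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the pipeline at sizes chosen
to finish in minutes on one CPU while keeping the study's structure: the
full 7 × 6 × 7-run design with a ~2000-voxel mask for single-subject
calibration and recovery runs, a ~440-voxel mask with 3 subjects and 5
runs for the multi-subject four-case comparison, and 10 simulated cohorts
on a ~200-voxel mask for the paired case-ordering checks.  These are the
package's own default desk-scale settings; all are configurable upward.

## Known limitations

* The across-subject analysis pools training runs rather than averaging
  within subject first; both readings are plausible for such designs.
* No anatomical atlas lookup, surface projection, smoothing, or
  physiological noise modeling.
* The simulator's affine is neutral (origin at volume center); it does not
  take a position on Talairach vs MNI reporting conventions.
* Pooled-variance t tests on accuracies ignore the dependence between
  folds that share training data; they are used here as the field's
  conventional summary, not as exact inference.
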