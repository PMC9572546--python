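# Methods

This note documents the models, estimators and numerical choices behind
`jnkscreen`, the defaults that matter, what the synthetic-data generators
do and do not emulate, and the package's known limitations.

## Curation and splitting

Bioactivity curation collapses records that share a canonical-SMILES
structure key. Where duplicates carry different IC50 values, the package
keeps one record with the **geometric mean** IC50: potency is
log-distributed, so the geometric mean is the order-independent choice and
preserves information a hard "delete duplicates" rule would discard.
Activity labels use a strict threshold — IC50 < 1 µM ⇒ active; a compound
at exactly 1 µM is inactive. Records with no measured activity or an
unparseable structure are removed, but always counted and itemized in the
curation report; curation is idempotent.

The train/test split is 4:1, stratified by label by default. With a
roughly 4:1 active:inactive imbalance, unstratified test sets of ~280
compounds would fluctuate by several percentage points in composition;
stratification removes that variance. A flag restores the plain random
split.

## Descriptor panel and standardization

The default provider computes the classic 208-name RDKit descriptor panel.
Newer RDKit releases append extra descriptors (`AvgIpc`, `SPS`); these are
excluded so the panel composition stays fixed, and the provider exposes its
name list so outputs are self-describing. A file-backed provider serves
precomputed matrices, decoupling the pipeline's mathematics from toolkit
availability.

Standardization is per-descriptor z-scoring with parameters fitted on
training rows only. A column is treated as constant when its maximum
equals its minimum exactly — floating-point variance of a constant column
is not reliably zero — and such columns get scale 1 and map to exactly 0.

## Chemical space and applicability domain

Chemical-space maps use PCA on standardized descriptors (correlation PCA):
descriptor units are wildly heterogeneous, so covariance PCA would be
dominated by large-magnitude descriptors. The applicability domain is the
axis-aligned bounding box of the training projection on the first two
components, optionally widened by a fractional margin; a library compound
is in-domain when it projects inside the box. This is a deliberately
simple formalization of the visual "does the library overlap the training
cloud" check; the overlap fraction it reports is monotone in the margin.

## Three-stage descriptor pruning

The funnel runs in a fixed order: variance → mutual information →
correlation; each stage records every dropped descriptor with the value
that condemned it, so the surviving panel can be reconstructed from the
report alone.

* **Variance.** Columns with variance ≤ ε (default ε = 0, with the exact
  max = min constancy test above) are dropped.
* **Mutual information.** MI between each descriptor and the binary label
  is estimated with the kNN estimator (`mutual_info_classif`), 15
  neighbours. The estimator returns small positive values for genuinely
  independent features, so "zero MI" is operationalized as MI at or below
  a threshold. The default threshold is data-driven: 1.25 × the largest
  MI observed for any feature against shuffled labels (5 seeded
  permutation replicates). At the default study composition this
  threshold sits near 0.02 nats while independent features estimate below
  ~0.015 and informative features above ~0.05, giving clean margins in
  both directions. A fixed `mi_epsilon` can be supplied instead. The
  larger-than-default neighbour count trades a little sensitivity for a
  much tighter null distribution; both choices are exposed as parameters.
* **Correlation.** Pairwise Pearson correlation, strict |r| > 0.8 prunes
  the later column of each offending pair (first-come-first-kept, scanning
  in input order). The policy is deterministic and order-documented;
  permuting input columns can change *which* member of a correlated clique
  survives, never how many survive.

The full selector is idempotent: applied to its own output it drops
nothing.

## Ensemble QSAR models

Three base classifiers — RandomForest, SVM with RBF kernel and probability
outputs, and a single-hidden-layer MLP (max 2000 iterations, fixed seed) —
are tuned by Bayesian optimization and fused two ways:

* **Voting**: the confidence is the weighted mean of the base
  active-class probabilities (equal weights by default; configurable).
  This is closed-form and exact.
* **Stacking**: a logistic-regression meta-learner is trained on k-fold
  (default 5) out-of-fold base confidences. A sample's own in-fold
  prediction is never used as its meta-feature; the fold bookkeeping is
  stored on the fitted estimator so this can be audited.

Bundled reference hyperparameters (RF: 283 trees, depth 25,
max_features 0.231; SVM: C 4.691, γ 0.013; ANN: 201 hidden units,
α 0.155) are used when tuning is skipped; the default search bounds
bracket them (RF trees 50–500, depth 3–30, max_features 0.05–1; C 10⁻²–10²
and γ 10⁻⁴–1 log-scaled; hidden units 16–256, α 10⁻⁴–10 log-scaled;
budget 50 evaluations).

The tuner is an in-package Gaussian-process optimizer: a Matern-5/2 kernel
with a white-noise term over the unit-cube-normalized search space,
expected-improvement acquisition maximized over a seeded 512-point
candidate cloud, 10-point seeded random initial design. The objective is
mean 10-fold stratified-CV AUC — AUC because it is threshold-free and the
class imbalance (~4:1) distorts accuracy. Everything is deterministic
given the seed. Class imbalance is otherwise left untreated by default (a
class-weight flag exists): the imbalance is mild and resampling would
change the meaning of the reported confidences.

## Evaluation

Accuracy, precision, recall and F1 come directly from confusion counts at
a 0.5 classification threshold (the 0.8 screening threshold is a screening
policy, not an evaluation setting). Precision is reported as *missing*
when nothing is predicted active — silently scoring it 0 would deflate
cross-validated means. AUC uses the exact Mann–Whitney statistic with ½
credit for ties, not a trapezoidal approximation, and equals the
brute-force pairwise comparison by construction.

## Screening rules and consensus

The activity filter requires **both** fused confidences ≥ 0.8
(inclusive — the threshold is "set to 0.8"). The drug-likeness filter
requires all of: Lipinski's Rule of Five with zero violations (a
violations-allowed knob exists for sensitivity analysis), −4 ≤ LogS ≤ 0.5,
HIA > 30 %, MCE-18 > 45, BBB permeant, and an empty toxicity-flag set
(mutagenicity, carcinogenicity, hepatotoxicity, oral acute toxicity).
ADMET values are consumed as annotations from an upstream predictor; this
package never predicts toxicity itself.

Consensus scoring: S_ml is the mean of the two fused confidences; S_dock
is the ratio of the compound's docking binding free energy to the
co-crystallized reference ligand's (−10.6 kcal/mol by default), capped at
1 when a compound out-docks the reference (the uncapped ratio would exceed
the documented 0–1 range); a positive (unfavourable) energy scores 0 with
a warning. S_total is the mean of the two sub-scores. Ranking is
descending by S_total with a stable tie-break on compound id, and final
selection uses strict S_total > 0.8 (the activity filter is inclusive at
its threshold, the selection cut is exclusive at its — both conventions
follow the protocol wording they implement). Back-calculating from the
published candidate table suggests the original reference affinity carried
more digits (≈ −10.632) than the printed −10.6; the reference energy is
therefore a parameter, and agreement with published totals is expected at
the ~0.2 % level, not exactly.

Similarity clustering uses 2048-bit Morgan (radius 2) fingerprints,
Tanimoto similarity and average-linkage hierarchical clustering on
1 − similarity.

## Dose–response analysis

Percent inhibition normalizes each sample well between the no-compound
(0 %) and no-kinase (100 %) control means; replicated controls are
averaged, and a collapsed assay window (equal control means) is an error.
The equation is invariant under common rescaling of all ratios.

IC50 fitting is a four-parameter logistic on log10 concentration with
top/bottom box-constrained to [−10, 110] % and the Hill slope to
[0.1, 10]. Initialization takes top/bottom from the data extremes, the
IC50 from linear interpolation of the midpoint crossing, Hill = 1. Two
IC50 estimates are reported because conventions differ: the **relative**
IC50 (the fitted midpoint between top and bottom) and the **absolute**
IC50 (the concentration crossing 50 % inhibition). When the tested range
does not reach the upper plateau the midpoint parameter is poorly
identified — top and IC50 trade off — while the absolute crossing remains
interpolative and well-determined; recovery properties in the test suite
are therefore judged on the absolute crossing. A curve whose observed
maximum inhibition stays below 50 % is censored as "> max tested
concentration" (e.g. "> 50 µM"), and non-convergence yields a censored
result with diagnostics rather than an exception. Fits are invariant to
the ordering of the concentration series. The dilution-series generator
takes the starting concentration, point count and fold-factor explicitly
(defaults 50 µM, 10 points, two-fold; a 9-point series ends at 195 nM).

## Synthetic data: what it emulates, what it does not

* `synth_qsar_dataset` emulates a curated kinase set: default 1138
  actives / 285 inactives × 208 descriptors, with 12 exactly-constant
  columns, 20 exact duplicate columns (copies of informative ones) and 30
  label-independent Gaussian columns planted; all remaining descriptors
  are class-conditional Gaussians whose means differ by `effect_size`
  pooled standard deviations. The default effect size is 1.0: a clearly
  learnable separation that also keeps per-descriptor mutual information
  (≈ 0.05 nats) safely above the MI estimator's null (≈ 0.02), so the
  selection funnel's ground truth is actually recoverable. Synthetic
  SMILES come from a 25-scaffold × substituent template grid — chemically
  valid and deterministic; they exercise parsers and fingerprints, not
  chemistry-space realism.
* `synth_screening_library` plants exact filter outcomes: a chosen count
  of dual-high-confidence compounds (default 343 of 4112) and, within each
  stratum, a chosen fraction of full ADMET passers (defaults shaped so
  ~22 compounds survive both filters); planted rule violations are named
  per compound in the manifest. Docking energies are uniform on a
  configurable interval (default −9.5 to −6 kcal/mol).
* `synth_dose_response` back-computes plate signal ratios from a 4PL
  inhibition curve (controls at ratio 2.0 and 0.5, two replicates each)
  so the assay equation recovers the curve exactly at zero noise;
  multiplicative Gaussian noise of a given fractional sd can be applied
  to every well.

Because descriptors are sampled rather than computed from structures, and
confidences in the screening library are planted rather than predicted,
passing tests demonstrate the correctness of the pipeline's logic and
statistics on data with known truth — they do not certify predictive
performance on real chemistry, where descriptors are correlated in
structured ways, actives are congeneric, and model confidences are
miscalibrated in ways the generators do not imitate.

## Problem sizes used in the test suite

The unit suite runs on a scaled-down composition (240/60 × 60 descriptors;
160/40 for pipeline orchestration; 300–500-compound libraries) chosen so
each planted pathology is still represented many times over. The at-scale
checks — selection-funnel recovery, the screening funnel at 4112/343/22,
and the fused-ensemble cross-validated AUC band — run at the full
1138/285 × 208 composition. The AUC band check cross-validates the voting
ensemble (10-fold); a 10-fold CV of the stacking route would refit every
base model per meta-fold (~6× the cost) and is exercised at reduced scale
instead. Bit-reproducibility of the whole pipeline is checked at the small
composition, since determinism does not depend on n.

## Known limitations

* Descriptor-panel composition is toolkit-release-dependent; the provider
  records its name list, but matrices computed with other RDKit versions
  should be loaded through the file-backed provider.
* The MI permutation-null threshold is calibrated for n in the hundreds to
  thousands; at very small n (≲ 200) the null max over 5 permutations is
  itself noisy.
* The applicability-domain box ignores density — a compound inside the box
  but far from any training point still counts as in-domain.
* Docking energies are inputs throughout; the package neither runs docking
  nor re-scores poses, and molecular-dynamics analyses are out of scope.
* The stacking meta-learner is fixed to logistic regression; voting
  weights default to equal. Both are configuration surface, not claims
  about the optimal fusion.
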