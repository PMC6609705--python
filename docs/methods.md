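# Methods

## The model

`morphnet` predicts the *morphological brain age* of a subject from
multi-view morphological brain networks (M-MBN) and uses the prediction in
two ways: to identify the network edges that most strongly encode age
("fingerprint" edges), and to quantify a subject's deviation from healthy
aging as a brain-age gap.

**Network construction.** The input per subject and hemisphere is a set of
M per-ROI cortical attribute means (default M = 4: maximum principal
curvature, mean cortical thickness, mean sulcal depth, mean average
curvature) over R cortical parcels (default R = 35, the single-hemisphere
Desikan-Killiany parcellation).  For each view *m* the network is

    M_m(i, j) = | a_m(i) − a_m(j) |,

the absolute difference of the attribute's mean value between ROIs *i* and
*j*.  This is a *dissimilarity* network: symmetric, nonnegative, zero
diagonal, invariant to adding a constant to all ROI values and equivariant
under scaling.  It models morphological similarity, not physical
connection.

**Feature extraction and fusion.** The strict lower triangle of each
matrix is read out column-wise (j outer, i = j+1..R inner; the same
linearization MATLAB's `tril` produces), giving R(R−1)/2 = 595 features
per view.  Views are fused either by concatenation (CON, M·595 = 2380
features, view provenance preserved) or elementwise averaging (AVG, 595
features).  The lower-triangle ordering is fixed and recorded in an
explicit `FeatureIndexMap` so every feature index resolves to
(view, ROI_i, ROI_j) — required for reproducible fingerprint reporting.
AVG averages raw values by default even though views carry different
units; a `zscore_views` flag standardizes views first for users who want
the scale-free variant.

**Feature ranking (RFE).** Recursive feature elimination fits a scorer on
the surviving features, removes a batch of the lowest-importance ones and
repeats until every feature is ranked (rank 1 = most relevant).  The
scorer is paired with the downstream estimator: impurity importances of a
regression random forest for the forest pipeline, squared linear-SVR
coefficients for the SVR pipeline.  Batch size defaults to 50 features per
round while more than 500 remain, then 10% of the remainder (min 1);
within an eliminated batch features are ordered by their importance at
elimination time, ties broken by ascending feature index, so the rank
vector is always a permutation of 1..F.

**Regression.** A regression random forest with 150 trees, minimum leaf
size 5 and ⌈F/3⌉ split candidates per node (bootstrap bagging over
subjects; prediction = mean of tree predictions, hence always inside the
training age range).  A tree-sweep utility re-runs the evaluation over
20–200 trees in steps of 20, the protocol under which 150 was fixed.

**Evaluation.** 5-fold cross-validation with a seeded shuffle split.  Per
fold, RFE ranks the training features, a feature count is selected, the
forest is trained and the held-out fold predicted.  Pearson r (two-sided p
from the exact t transform), and MAE in years are computed once over the
pooled out-of-fold predictions; per-fold values are also reported.  The
number of selected features is chosen by nested CV *inside* each training
fold over the grid {50, 100, …, F} (single view / AVG) or {100, 200, …, F}
(CON) — the leakage-free reading; a `legacy_grid` mode that evaluates the
grid on the outer test fold exists for comparison only, and a fixed
`n_features` short-circuits the grid.

**Fingerprint edges.** A feature's relevance score is its RFE rank
averaged across the CV folds; the top-K edges (K ∈ {5, 10, 15} by default)
are exported with 1-based ROI indices and atlas-resolved names, sorted
best-first.

**Brain-age gap.** A second model is fitted on normal controls only (the
healthy baseline); applied to a subject it yields predicted − chronological
age (signed gap; the absolute gap is the biomarker).  NC subjects' own gaps
are computed leave-fold-out within NC so they are not optimistically zero.
Gap-augmented classification appends the signed and absolute gap to the
feature vector and trains a random-forest classifier under stratified
5-fold CV; within each fold the baseline is fitted only on that fold's NC
training subjects.

**Baselines.** SVR (linear kernel, C = 1, ε = 0.1 — the method names no
values, so library defaults are used and exposed), SVR+RFE, RF without
selection, and a deliberately *simplified* CPM: per-edge Pearson
correlation with age, edges with p < 0.01 split by correlation sign into
positive/negative sets, per-subject strength sums, and a linear model on
the two sums.  CPM consumes only matrix-shaped input and therefore refuses
CON fusion.  `rf_rfe` delegates to the primary pipeline and is
bit-identical to it at equal seeds.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes:
`attribute(k, m, i) = baseline[m,i] + slope[m,i]·effective_age(k) + N(0, σ_m)`,
with `effective_age = age + acceleration_years` for the disordered
subgroup.  Signal is planted at the ROI level (slopes), never at the edge
level, so the implied signal edges — pairs with `slope_i ≠ slope_j`, with
strength `|slope_i − slope_j|` — are consistent with the construction
operator; the ground-truth record enumerates them.

The **default recovery scenario** is fixed: N = 300, R = 35, M = 4, ages
uniform on [8, 30] years (even leverage for recovery; a mean/SD-matched
truncated normal is available), signal only in view 2 (cortical
thickness) on six ROIs — insula +0.050, temporal pole −0.050,
frontal pole +0.006, rostral anterior cingulate −0.006, corpus callosum
+0.004, bankssts −0.004 mm/year — so the single strongest implied edge is
insula–temporal pole.  The two strong slopes exceed typical developmental
thickness change; they are amplified so that recovery is decidable at
N = 300.  View-2 intercepts track the slopes (offset 30·slope plus small
deterministic jitter) so signal-edge differences keep one sign across the
age range and |·| stays linear; other views carry no slope and plausible
scales.  View-2 noise SD is 0.34 mm, calibrated once so the planted-edge
linear oracle reaches a pooled 5-fold r of ≈ 0.8.

The **planted-edge oracle** regresses age on the true planted-edge columns
with 5-fold CV.  Edges sharing a signal ROI are near-collinear by
construction, which makes plain least squares numerically erratic, so the
oracle uses ridge regression with a CV-chosen penalty — a linear fit that
is stable under the designed collinearity.

The **accelerated scenario** (gap recovery) halves the view-2 noise and
draws the disordered group's chronological ages from [8, 30 − a] so the
accelerated effective ages stay inside the healthy range: the baseline
model is never asked to extrapolate past the oldest healthy subject, which
is the regime in which gap recovery is a well-posed question.  Random
forests compress the prediction slope (leaf averaging and boundary bias),
so the recovered group difference is expected a little below the planted
value.  The **separable scenario** uses acceleration 10 years and noise at
one sixth of the default for the classification demonstration.

What the generator does *not* emulate: site/scanner effects, non-linear
age trajectories, spatially correlated noise between neighboring ROIs,
missing data, and group differences other than a uniform age-acceleration
offset.  Passing recovery tests therefore shows the machinery is correct
and well-calibrated, not that the method attains any particular accuracy
on real imaging cohorts.

## Numerical choices and degenerate inputs

- Symmetry/zero-diagonal validation tolerance 1e−9 absolute (matrices are
  constructed exactly symmetric; the tolerance only guards text round
  trips).  Floats are serialized in shortest round-tripping repr, so
  write→read is bit-exact.
- ROI indices are 1-based in every file and report; arrays are 0-based
  internally.
- All stochastic components (fold splits, RFE scorer, forests,
  simulations) derive from one run-level seed; equal configs give
  byte-identical outputs.
- Constant targets make ranking undefined and are rejected; constant edges
  are skipped by CPM with a log notice; CPM with no significant edges
  falls back to the training mean age.
- Ties in relevance scores are broken by ascending feature index
  everywhere (stable sorts), so orderings are deterministic.
- `predictors_per_split` rounds up (⌈F/3⌉), avoiding zero candidates at
  tiny F.

## Problem sizes used in the shipped checks

The recovery checks run the CON pipeline with a 50-tree scorer forest for
RFE and a coarse feature-count grid (100/300/600), the view-2 ranking run
with a fixed 50-feature selection, the permuted-age null with 50%-batch
elimination and a 25-tree scorer, and the gap protocol with 20%-batch
elimination and 15 selected features.  These are the package's own scaled
configurations for a 300-subject cohort; the final regressor always keeps
the 150-tree protocol defaults.

## Known limitations

- Impurity-based forest importances dilute over groups of mutually
  redundant informative edges, so late RFE rounds can interleave redundant
  signal edges with surviving noise edges; fold-averaged relevance
  mitigates but does not remove this.  Concatenated fusion inherits the
  effect from the no-signal views.
- No age-bias correction of gaps and no site harmonization: gaps shrink
  toward the cohort mean age exactly as the regressor does.
- The simplified CPM is a sketch of connectome-based predictive modeling
  (sum-threshold summarization + linear model), not a faithful
  reimplementation of the original protocol.
- Hemispheres are modeled as separate cohorts; no cross-hemisphere
  features exist.
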