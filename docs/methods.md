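# Methods

`convoconn` implements a two-sided inference procedure for conversational
neuroimaging studies of two diagnostic groups: (1) a *language-typicality
score* derived from a cross-validated classifier over per-conversation
linguistic feature tables, and (2) a *whole-brain connectedness* analysis
whose group-by-score interaction tests whether atypically elevated
connectivity tracks more typical behavior — the operational signature of
neural compensation. Everything runs on parcellated, desk-scale data; a
synthetic-data module generates cohorts with the statistical structure the
analysis assumes, so the full pipeline is testable without any acquisition.

## 1. Language-typicality phenotype

**Model.** Conversations are rows of a feature table (81 numeric columns by
default, the shape of a dictionary word-count output). Features are z-scored
over the full table (sample SD, ddof = 1), then an L2-regularized hinge-loss
linear classifier (C = 1.0) is trained with each conversation held out in
turn — leave-one-out over conversations, which are treated as independent
observations even though participants contribute several; a
leave-one-participant-out mode (`per_fold_standardize`, participant-grouped
CV) is available for users who prefer strict separation, and the default
whole-table z-scoring mirrors the conventional order of operations (z-score
first, cross-validate second) at the cost of a small, documented leakage of
feature moments.

Pooled cross-validated decision values are mapped to posterior probabilities
with a single two-parameter sigmoid (Platt scaling with the standard
prior-corrected targets, fitted by Newton's method); the posterior is
oriented so that higher values mean more control-like language regardless of
label encoding. A participant's *composite score* is the arithmetic mean of
their conversations' posteriors; a composite strictly below 0.5 classifies
the participant into the case group (a composite exactly at 0.5 is control —
the "lower than 0.5" rule).

**The solver.** The hinge-loss SVM is solved by dual coordinate descent with
shrinking — the same optimization problem liblinear solves, including the
penalized intercept (absorbed as a unit feature column). A compiled
implementation is used because the permutation experiments below refit the
classifier hundreds of thousands of times; tests verify it against both
sklearn's `LinearSVC` (to ~1e-5 in decision values) and a brute-force
convex-QP oracle (SLSQP on the slack formulation, to 1e-4).

**Inference.** Significance of composite accuracy is assessed by permuting
group labels at the participant level (all of a participant's conversations
move together; group sizes are preserved), rerunning the *entire* chain —
LOO fits, Platt calibration, composites — against the permuted labels, and
recording each permutation's accuracy. The primary p-value is the proportion
of null accuracies strictly greater than the observed one; the add-one
smoothed estimator (#{null ≥ observed}+1)/(n+1), which is valid at finite
permutation counts and never exactly zero, is reported alongside and used
wherever a calibrated test is required. Permutation refits use a looser
solver tolerance (1e-4) than the reported scores (1e-6); accuracy, a
1/n-granular statistic, is insensitive to this (verified across tolerances).

**Validation surfaces.** ROC/AUC of the composite (AUC equals the
probability of correctly ordering a random case/control pair, ties ½), and
the Spearman correlation (average-rank ties) between case-group composites
and ordinal severity scores — two-sided p by the t approximation, exact
permutation enumeration at n ≤ 9. A negative-control classifier applies the
identical chain to the conversation partner's features.

## 2. Whole-brain connectedness and ROI selection

**Connectedness.** Per scan, every node is correlated with every other node
(Pearson), the correlations are averaged, and the average is stored at the
node — a weighted-degree summary of global involvement. Raw correlations are
averaged by default; a Fisher-z mode averages atanh(r) and reports on the z
scale (never back-transformed). The two scales cannot be mixed within a
contrast (enforced by a map tag). Constant nodes get NaN and are excluded
from other nodes' averages.

**Group contrast.** Per node, Connectedness ~ Group + Age + Motion with a
per-participant random intercept, fitted by REML (statsmodels `MixedLM`,
default optimizer cascade). The group effect is signed case-minus-control.
t-statistics are referred to participant-level degrees of freedom
(n_participants − n_fixed_effects), matching the convention in which
between-participant effects are resolved at the participant level; a
residual-df option exists. Nodes whose mixed fit fails (singular Hessian at
a boundary variance) fall back to participant-mean OLS and are flagged.
Constant covariate columns are dropped from the design, which makes the
documented closed-form limits exact (with one scan per participant the mixed
fit collapses to OLS; with constant covariates and balanced groups the group
effect is the difference of group means).

**Cluster extents.** Familywise error per voxelwise threshold is controlled
by permutation: group labels are permuted across participants, the one-sided
contrast map is recomputed (participant-mean OLS — fast, exchangeable under
the null), and the maximum supra-threshold cluster size is recorded;
k(α_v) is the smallest extent whose exceedance probability is ≤ 0.05,
capped at the node count in the degenerate all-significant regime. The table
is forced non-increasing along the descending threshold ladder. Externally
supplied extent tables are accepted verbatim.

**Robustness map and ROIs.** The contrast is thresholded at the descending
ladder α_v ∈ {0.005, 0.001, 0.0005, 0.0001, 0.00005, 0.00001} (one-sided,
case > control) with the calibrated extents; binarized surviving masks are
combined into a per-node "most stringent rung survived" map. ROIs are
connected clusters of nodes that survived *every* rung, with at least 10
nodes. An empty ROI set is a legitimate outcome.

## 3. Compensation test and seed-based follow-up

Per ROI, mean ROI connectedness is modeled as
Connectivity ~ Score + Group + Score×Group (+ Age + Motion). Group is coded
1 = control, so the interaction is the control-minus-case slope difference
and compensation appears as a *negative* interaction: the case group's
connectivity rises with more typical language where the control group's does
not. Two observation levels are supported: scan-level with a participant
random intercept (default), and participant-aggregated OLS, whose dfs equal
n_participants − n_fixed (39 participants, no covariates → t on 35 df).
Whether nuisance covariates belong in this model is genuinely open; they are
included by default for consistency with the mapping model, with a flag to
drop them. Per-group Pearson correlations are computed at participant level
(df = n − 2). The three-ROI family is Bonferroni-corrected at 0.05/3
(≈ 0.0167; exact internally, rounded only for display).

The seed-based follow-up correlates every non-seed node with the mean seed
time series, Fisher-z transforms the values for variance stabilization,
fits the same per-node mixed group contrast, thresholds at α = 0.001 with a
permutation-calibrated (or supplied) extent, and counts significant nodes
per hemisphere. The left/right ratio is reported with an explicit infinity
flag when the right count is zero; nodes without hemisphere labels are
excluded from counts (warned) but stay in the significant set.

## 4. Synthetic cohorts

A scalar latent typicality θ drives both sides. Case participants draw
θ ~ N(−d/2, 1), controls N(+d/2, 1), with d = `feature_effect_size`
(default 1.3). Informative features (20 of 81) load on θ with fixed
per-feature loadings (magnitudes U(0.4, 1), random sign), plus a
participant-level random effect (SD 0.5) shared across that participant's
conversations and i.i.d. conversation noise (SD 1). Non-informative features
are pure noise — so zero-signal cohorts are chance-level by construction and
the participant random effect cannot leak group information through null
features. These values were calibrated once so default-scale classifier
accuracy lands in a realistic 70–85% band; they are conditions, not dials.

Severity (case group only) is an ordinal 7–14 score, monotone-decreasing in
θ before binning; the link strength λ (default 0.55) is planted on the
Spearman scale via ρ_pearson = 2·sin(πλ/6), slightly attenuated by the
8-level binning. With λ = 1 and at most 8 case participants the rank map is
injective and the Spearman correlation with θ is exactly −1.

Scans come from a factor model with unit-variance nodes: all nodes load
√0.1 on a global factor; each planted over-connected region has its own
factor, loaded 0.15 by controls and 0.15+0.5 by cases; the compensation
region's factor is shared with a partner node set (2:1 left:right by
default, loading 0.45 in both groups), and the case-group loading on it
additionally grows as 0.06·θ, clipped to keep every node's variance
decomposition valid (validated at construction; violations name the
offending parameters). Planting connectivity through loadings guarantees a
positive-definite joint covariance. The planted structure is invisible to
controls: their loadings are θ-independent constants. Default geometry: 80
nodes in two 40-node hemisphere chains; three 10-node right-hemisphere
regions; scan length 180 timepoints (6 minutes at TR 2 s); ages uniform
14.7–32.0; motion lognormal (median ≈ 0.08) with scan-level jitter. Two
conversations from two distinct control participants are marked as audio
failures (117 → 115 analyzable conversations).

What the generator does *not* emulate: hemodynamics, autocorrelated fMRI
noise spectra, motion artifacts, topic/content structure in the features,
or any dependence of the nuisance covariates on group. Passing tests
therefore demonstrate the statistical machinery — calibration, recovery,
error control — under the assumed generative structure, not performance on
real acquisitions.

## 5. Numerical choices and problem sizes

* All randomness flows from one master seed through named, collision-free
  substreams (stage name CRC mixed into a `SeedSequence`), so stages are
  reproducible in isolation.
* Solver: DCD tol 1e-6/1e-4 (reported/permutation fits); Platt Newton with
  backtracking line search; posteriors clipped to (1e-12, 1−1e-12).
* Connectedness correlations are clipped to [−1, 1] before averaging;
  Fisher-z inputs clipped away from ±1 by 1e-15.
* Tables are UTF-8 TSV with `%.17g` floats and correctly-rounded parsing,
  so read→write→read round-trips are bit-identical.
* The test suite's simulation experiments use reduced problem sizes chosen
  for tight feedback loops: 30–46-node layouts, 120 timepoints, 99–10,000
  permutations, and 50–500 replicates per experiment; the acceptance script
  runs the full default scale (39 participants, 115 conversations, 81
  features, 1000 permutations, 80 nodes).

## Known limitations

* The LOO design shares participants across training folds by construction
  (the independence caveat above); the permutation test inherits and
  thereby correctly penalizes this, but absolute accuracies should be read
  with it in mind.
* Composite accuracy is not centered at 50% under a pure-noise null.
  Leave-one-conversation-out makes each training fold majority-opposite to
  the held-out conversation's class, so null decision values are mildly
  anti-correlated with the labels; the pooled sigmoid calibration, fitted
  against the true labels, can orient itself to that structure and lift
  null composite accuracy to roughly 60% at the default null scale. This
  is why accuracy must be referred to the permutation null — which carries
  the same lift and therefore remains calibrated (verified by simulation)
  — and never to a nominal 50% chance level.
* Mixed-model dfs are a convention (participant-level by default), not a
  Satterthwaite approximation; with 3 scans per participant and
  between-participant effects the difference is small.
* Cluster-extent calibration permutes participant-mean maps; it does not
  model spatial autocorrelation beyond what the maps themselves carry.
* NIfTI export requires integer-grid node coordinates and is sugar for
  visualization; the canonical representation is the node table.
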