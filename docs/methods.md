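# Methods

## The model

`graphpm` implements graph-theoretical predictive modeling (GPM) of
clinical symptom scores from functional connectomes, together with the
statistical machinery needed to validate such a model honestly.

**Connectomes.** For each subject and cognitive state (e.g. a
reinforcement-learning task and rest), regional BOLD time series are
correlated pairwise (Pearson) and Fisher-z transformed into a symmetric
node-by-node matrix with zero diagonal. Multi-run sessions are handled by
demeaning each run per node and concatenating along time before a single
correlation, so inter-run mean offsets cannot inflate correlations.
Correlations are clipped at |r| = 0.999 (configurable) before `arctanh` so
degenerate perfect correlations stay finite.

**Positive weighted graphs.** Graph measures are computed on the positive
part of the connectome: negative Fisher-z values are removed (most
weighted measures are defined for positive weights only) and edge length
is the reciprocal weight, the convention of the standard brain-connectivity
toolboxes. Distances are Dijkstra shortest paths over those lengths.

**Graph measures.** Five global measures (characteristic path length,
global efficiency, mean clustering, mean local efficiency, mean
betweenness) and three nodal measures (clustering, local efficiency,
betweenness) evaluated at named reward-circuit ROI nodes (ACC, caudate,
putamen, NAc, lateral/medial OFC; node indices are configuration inputs,
0-based). Conventions, chosen where the generic definitions leave
freedom:

- *Global efficiency* = mean of 1/d_ij over ordered pairs, 1/inf := 0.
- *Characteristic path length* averages finite distances only and carries a
  connectedness flag when pairs are unreachable; an empty graph records a
  missing value rather than crashing (dense positive connectomes are
  essentially always connected, but synthetic edge cases must not).
- *Clustering* is Onnela's weighted form (geometric mean of triangle
  weights, normalised by the graph-maximum weight, so values lie in [0,1]);
  degree < 2 scores 0.
- *Local efficiency* is the global efficiency of the subgraph induced on a
  node's neighbours with original (restricted) weights — the simpler of
  the published variants; versions weighting by attachment strength are
  deliberately not implemented.
- *Betweenness* uses Brandes accumulation with full shortest-path
  multiplicity counting (tied geodesics split credit) and is normalised by
  (n−1)(n−2) so each unordered pair contributes at most 1/2 and values are
  comparable across graph sizes and densities.
- Multi-node ROIs are reduced by the arithmetic mean of nodal values.

All seven measure implementations are cross-checked in the test suite
against independent brute-force oracles (Floyd–Warshall distances,
exhaustive geodesic enumeration, direct triangle products) on hundreds of
random graphs to 1e-9.

**The GPM.** One prediction problem = one target (symptom scale at a time
point), a transform (`log(x+1)` by default for the right-skewed mania-like
scale; scores are modelled and reported on the transformed scale), the
covariates implied by the design (a baseline target covaries the two other
baseline scales; a follow-up target covaries all three baseline scales;
psychotropic medication load is always included), and a candidate feature
pool spanning the graph metrics of the configured states. Inside each
cross-validation training fold:

1. *selection* — the single candidate metric with the largest |Pearson r|
   with the (transformed) target over training subjects only; covariates
   are excluded from selection; ties break toward the canonical column
   order (state label, then metric name, both alphabetical); zero-variance
   columns are skipped;
2. *model building* — OLS of the target on [selected metric, covariates];
3. *prediction* — the held-out subjects are predicted with their own
   metric and covariate values.

The default scheme is leave-one-out CV (appropriate for modest clinical
samples); seeded (repeated) k-fold is available and gives similar error
estimates. The null model is the identical machinery with the brain term
removed. Selection by absolute correlation is a choice (the alternative,
signed selection, is available via `ModelSpec(selection="signed")`).
Missing data are handled by pairwise deletion per model — a subject
missing the target, any covariate, or any candidate feature is dropped
from that model only — so each fitted model has its own N. A minimum of
10 complete training cases per fold is enforced to guard OLS stability.

**Transfer mode** trains once on one diagnostic group (e.g. unipolar) and
predicts the other (bipolar), with a companion null fitted the same way —
the test of transdiagnostic generalisation.

**Elastic-net variant.** All candidate metrics enter a regularised
regression instead of winner-take-all selection. Within each outer
training fold, features are standardised and the covariates partialled out
of target and features (Frisch–Waugh), which keeps covariates exactly
unpenalised; an inner CV over the full mixing grid alpha = 0, 0.05, …, 1.0
(21 values) times a geometric lambda path (three decades down from the
smallest all-zero lambda, anchored at max|X'y|/(n·max(alpha, 0.05)) because
coordinate-descent path formulas degenerate at alpha = 0) picks the pair
minimising inner CV error. Residualisation is refit per outer fold but not
per inner fold — a deliberate simplification confined to the training data.

**CPM comparator.** Connectome-based predictive modeling with identical
covariate structure, transform, and CV machinery: per training fold, every
edge is correlated with the target; edges with two-sided p < 0.01 enter
the positive- or negative-feature set by correlation sign; each subject's
selected-edge Fisher-z sum (network strength) replaces the graph metric in
the regression. It runs on the signed connectome (as originally published)
or positive-only. Positive and negative sets are evaluated as separate
models (a combined two-predictor mode exists but is off by default); a
fold that selects no edge falls back to the covariates-only
model rather than failing (small training sets at p < 0.01 legitimately
select nothing).

## Validation statistics

- **MSE** over complete observed/predicted pairs, and the relative
  difference `MSE_diff = (MSE_null − MSE_model)/MSE_null` (positive =
  model beats null).
- **Corrected repeated k-fold CV test**: paired t on per-fold MSE
  differences of two models evaluated on identical folds, with the
  Nadeau–Bengio variance factor `1/(k·r) + n_test/n_train` replacing the
  naive `1/(k·r)` — training-set overlap across folds makes the naive
  test grossly anti-conservative (the suite demonstrates both facts by
  simulation). Models fitted by LOOCV are *compared* under a separate
  seeded repeated k-fold scheme (default 10×10), since the correction's
  variance term needs meaningful test-fold sizes; prediction itself is
  still reported under the primary scheme.
- **Permutation inference** for the prediction correlation: targets are
  shuffled among included subjects (covariates travel with the subject),
  the full CV pipeline — including in-fold selection — is re-run per
  permutation, and the one-sided p uses the add-one rule
  `(1 + #{r_perm ≥ r_obs})/(1 + n_perm)`; default 10,000 permutations.
  One-sided because better-than-chance prediction is the directional
  hypothesis.

## The synthetic-cohort generator

The generator exists so every stage is testable without clinical fMRI
data. Node time series follow a latent factor model: one global factor
(setting the between-block correlation level), one factor per community
block, and unit node noise; baseline loadings are solved so population
within-/between-block correlations match the configured levels (defaults
0.35/0.08, typical of Fisher-z functional connectivity). Log-normal
multipliers at subject-by-block (SD 0.25), node (SD 0.20), and
state-by-block (SD 0.10) level create between-subject, node-specific, and
state-specific variation in coupling — hence in graph metrics.

Symptoms: three correlated baseline latents (pairwise r = 0.4) mapped to
questionnaire-like scales (anhedonia ≈ 79.5 ± 12.2, impulsivity ≈ 67.6 ±
11.3); the mania-like scale is `expm1` of its latent (floored at zero), so
`log(x+1)` is its natural transform and the raw scale is right-skewed and
non-negative. Follow-ups are autocorrelated with baseline (default 0.6,
emulating baseline scores capturing most short-term variance). Missingness:
lost-to-follow-up 10% at 3 months and 16% at 6 months (matching 8/80 and
13/80 in the motivating study design), plus 2% scale-level missingness; a
72.5% / 27.5% unipolar/bipolar group split.

**Planting** operates on the metric, not directly on edges: subject-level
coupling modulates the connectome, metrics are computed from the generated
graphs, and the target is `β·z(planted metric) + Σγ·covariates + ε` with β
calibrated from the realised non-brain variance so the brain term explains
the configured R² (verified to converge at large n). Direct inversion of
"metric value → connectome" is not generally possible; this construction
keeps connectomes realistic while guaranteeing a learnable signal. The
default planted feature is the betweenness of a named ROI node in the rest
state: nodal betweenness is strongly node-specific in these graphs
(competitor metrics correlate with it at |ρ| ≲ 0.15), whereas local
efficiency of a node in a dense positive connectome is nearly a global
quantity (its neighbour subgraph is almost the whole graph, competitor
ρ ≳ 0.9) and would make "which feature carried the signal" ill-posed. A
companion generator plants a *diffuse edge-level* signal (a subject latent
added to a random edge subset) for exercising the CPM's home turf.

What the generator does **not** emulate: haemodynamics (no HRF), motion
or physiological artefacts, scanner/site effects, non-Gaussian BOLD noise,
distance-dependent connectivity, or realistic atlas geometry. Passing
recovery tests therefore shows the *estimator machinery* is sound — not
that real connectomes carry such signals.

## Problem sizes used in tests and the acceptance script

Chosen to keep the full simulation studies comfortably runnable on one
CPU while preserving the study conditions that matter (sample size, effect
size, replicate counts):

- recovery and model-comparison experiments: 80 subjects, 24-node 3-block
  connectomes, 2 states, 150 time points, brain-term R² = 0.3, 100
  replicates;
- corrected-test calibration: 500 cohorts of n = 50, two genuinely
  different but equally predictive linear models, 10×10 repeated CV (a
  mean-zero null; comparing a model against its own null is *not*
  mean-zero, since the extra fitted parameter costs accuracy);
- permutation calibration: 200 signal-free cohorts of n = 30 (one state,
  8 nodes) with LOOCV and 200 permutations each;
- metric oracle equivalence: 200 random graphs with 4–8 nodes.

The default `SyntheticConfig` keeps the study-like 216-node, 6-block
connectome for data generation; experiments pass smaller explicit configs.

## Numerical choices and degenerate inputs

- Fold assignment uses seeded shuffled k-fold; identical inputs and seeds
  give bit-identical results end to end. A master seed derives per-stage
  seeds by hashing, so stages are independently reproducible.
- Rank-deficient designs in the direct fitting API raise with the
  collinear column names (QR pivot diagnostics); the CV fast path uses
  least squares, which is exact for full-rank folds.
- Zero-variance candidate features are skipped in selection; an all-
  zero-variance pool raises. Zero-variance edges are skipped (logged) in
  CPM selection.
- Corrected-test edge cases: zero variance with zero mean difference gives
  t = 0, p = 1; zero variance with nonzero mean reports p below machine
  minimum with a warning.

## Known limitations

- The corrected CV test is approximately calibrated for genuinely
  different, comparably accurate models; for nested model-vs-own-null
  comparisons the null distribution is not exactly mean-zero and the test
  is conservative in the no-signal direction.
- LOOCV prediction correlations are slightly negatively biased under the
  null (a well-known property); permutation inference, which re-runs the
  pipeline, accounts for this.
- The elastic-net inner CV residualises covariates once per outer fold,
  not per inner split.
- No harmonisation across sites/scanners, no nonlinear models, no
  interaction terms, no binary/thresholded graph variants, and no
  community-detection measures — all out of scope by design.
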