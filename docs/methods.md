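# Methods

## The spreading model

Regional pathology is a probability `X_i(t) ∈ [0, 1]` (the probability that
region *i* carries abnormal tau signal).  On a connectome with weights
`C_ij ≥ 0`, row-normalized to `Ĉ` (rows sum to 1 where nonzero, so the
neighbor-input term is a weighted average in [0, 1]), the state evolves as

    dX_i/dt = β (1 − X_i) Σ_j Ĉ_ij X_j − δ X_i

Production scales with connectivity-weighted neighbor burden and with the
remaining regional capacity `(1 − X_i)`; clearance is first-order.  When
production and clearance balance, a small seed decays and little spreading
occurs; imbalance accelerates spread.  The model deliberately omits
directional (asymmetric-flow) transport, amyloid-coupled dynamics, and
region-specific vulnerability.

Integration is explicit Euler, default `dt = 0.01` years, with post-step
clamping to [0, 1] and a stability guard that aborts if any single step
changes a state by more than 0.5.  Against a naive fine-step reference
integrator (`dt = 1e-4`) the default integration agrees to better than
1e-3 per region on small systems, and to 1e-6 against the zero-coupling
closed form `X(t) = x₀ e^(−δt)` when run at `dt = 1e-4`.

### Parameters

| parameter | meaning | default |
|---|---|---|
| β | global production rate (1/year) | fit per subject |
| δ | global clearance rate (1/year) | fit per subject |
| t_eff | effective spreading duration (years); encodes scan age − onset age | fit per subject |
| x₀ | epicenter seed amplitude (probability) | 0.1, not fit |
| dt | Euler step (years) | 0.01 (0.05 in coarse grids) |

The full default search grid uses 20 log-spaced values in [0.01, 3] plus 0
for each rate and durations 5–50 years in steps of 5.  The *coarse* grid
(10 log-spaced rates, durations 5–45 in steps of 5, `dt = 0.05`) is the
default for epicenter scans; resolutions much below ten rates cannot
separate adjacent candidate epicenters, whose global-fit margins are of
order 10⁻³.

Because rescaling time maps `(β, δ, t_eff) → (β/k, δ/k, k·t_eff)` without
changing `X(t_eff)`, absolute rates are not identifiable when the duration
is free; the production/clearance **ratio** β/δ is invariant under this
degeneracy and is the quantity the recovery benchmarks assess.

Candidate trajectories depend only on the connectome, epicenter and grid —
not on the subject — so all grid trajectories are simulated once (batched
over rate combinations) and every subject selects by SSE against the same
candidate set.  This is algebraically identical to per-subject simulation.

## Tau-positive probability calibration

Per region, 1- and 2-component Gaussian mixtures are fit across the
population (EM, 10 restarts, k-means++ initialization, variance floor
1e-6) and compared by AIC with the standard univariate parameter counts
(2 and 5); strict inequality AIC₂ < AIC₁ declares bimodality.  Subject
probabilities are the posterior of the upper component evaluated on
held-out folds of repeated five-fold cross-validation (default 10
repeats), averaged over repeats; bimodality and reported component
parameters come from the full-sample fit.  Unimodal regions are still
transformed (forced two-component fit) and flagged; only the
`bimodal_only` region set drops them, preserving both the "discard" and
the "keep all cortical regions" readings of standard practice.  With
well-separated components the posterior is monotone in SUVR up to
numerical noise of order 1e-6 deep in the lower tail.

Confound handling: `residualize` regresses age, sex (coded 0/1) and mean
choroid-plexus signal out of each region across all subjects and adds back
the regional grand mean so mixture fitting stays on the SUVR scale;
`wscore` fits the same per-region model on amyloid-negative cognitively
normal subjects only and standardizes by the reference residual SD.  The
reference-bootstrap ECDF alternative builds the null from the maxima of
40,000 resamples of the 5–95% trimmed reference values and is applied at
region level (the original formulation is voxelwise; no voxel data exist
here).  When the pipeline needs a reference sample and none is supplied it
uses the pooled values of the region with the lowest population mean.

## Connectomics

Template averaging is an elementwise mean.  Thresholding retains the top
10% (configurable) of unique off-diagonal weights — ties broken by stable
index order so the retained count always equals the quota — and min–max
scales survivors to [0, 1]; the operation is idempotent on its own output.
The Euclidean-distance alternative uses centroid distances scaled by the
maximum off-diagonal distance and inverted (coincident → 1, most distant
→ 0).

Null connectomes: binary topology randomized by Maslov–Sneppen double-edge
swaps (10 swaps per edge; degree sequence preserved exactly), then the
original weight multiset is assigned rank-matched by endpoint target
strength and corrected by 20 iterations of proportional strength
rescaling.  Degree preservation is exact by construction; strength
preservation is approximate and logged per null (correlations ≥ 0.9
required, ≈ 1.0 in practice).  Ensembles default to 100 nulls, making the
smallest achievable exceedance p-value 0.01.

## The synthetic-data generator

The generator replaces restricted imaging cohorts.  What it emulates, and
how:

- **Atlas.**  31 DKT cortical labels per hemisphere plus bilateral
  hippocampus and amygdala form the 66-region cortical set; six further
  subcortical structures per hemisphere complete the 78-region set.  Braak
  stage ROIs: entorhinal = 1, hippocampus = 2, remaining cortex
  distributed 3–6 by the conventional scheme.  The mapping is an editable
  approximation.
- **Centroids** are synthetic and mirrored across hemispheres; only
  relative distances matter.  The anterior–posterior coordinate follows
  the Braak-stage gradient — anatomically, staging is a spatial
  progression from medial temporal through association to primary cortex —
  with primary cortex offset further, and the medial temporal cluster is
  anchored tightly with entorhinal cortex positioned as the gateway
  (perforant path) between a comparatively secluded hippocampus and the
  ventral temporal bridge (fusiform, lingual).  These choices are what
  make entorhinal-seeded spread recapitulate the staged ordering, keep
  entorhinal- and hippocampus-seeded patterns distinguishable, and let the
  cascade escape the seed reliably across random layouts.
- **Connectome.**  Edge propensity decays exponentially with distance
  (length constant 25 mm) under multiplicative lognormal noise;
  non-homotopic interhemispheric edges are attenuated ×0.02 (callosal
  connections are predominantly homotopic); the top `density` (default
  10%) of edges is retained and scaled to [0, 1]; every homotopic pair is
  then connected at weight 0.05 on that scale.  Stronger homotopic
  coupling symmetrizes unilateral seeds within years and would erase the
  lateralized-epicenter phenomena the generator must support.
- **Cohorts.**  Demographics default to the pooled marginals of a
  312-subject tau-PET study population (52/28.5/19.5% CN/MCI/AD, age
  71.7 ± 7.1, 53.1% women, education 14.6 ± 3.8, APOE4 51.7%, amyloid
  positivity 42.6/64/100% by diagnosis).  Clearance δ is lognormal around
  0.15/year; the production/clearance ratio is lognormal with diagnosis-
  dependent medians (1.6/2.1/2.6 for CN/MCI/AD) so burden rises with
  severity; durations are uniform on 15–35 years.  Terminal probabilities
  come from the spreading model itself run forward with each subject's
  parameters (batched Euler); amyloid-positive subjects receive an
  additive boost (default +0.2, clamped at 1) in a fixed list of
  classically amyloid-vulnerable regions — the planted signal for the
  residual analysis.
- **SUVR emission** inverts the measurement model: per subject/region a
  Bernoulli(p) component draw selects N(1.0, 0.10) (off-target background)
  or N(1.6, 0.20) (abnormal), with small seeded regional jitter on the
  means (recorded in provenance as the recovery ground truth) and additive
  age/sex/choroid-plexus effects.

All generation flows from one master seed through spawned substreams;
regeneration is bit-identical.

### Benchmark cohorts

Recovery benchmarks do not use the default mixed cohort: subjects with no
spread have patterns that are pure observation noise, and saturated
patterns carry no epicenter information, so either regime benchmarks noise
rather than recovery.  Three designed regimes are used instead, all at
observation noise SD 0.05:

- `recovery_benchmark_spec` — within-subject fit and rate-ratio recovery:
  uniform ratio ≈ 3.5 (log-SD 0.2), durations 8–18 years, so every subject
  carries a partial, graded wave.
- `epicenter_ranking_spec` — planted-pair ranking: same rates, durations
  10–25 years, so spread escapes the seed's neighborhood in most subjects.
- `lateralization_benchmark_spec` — unilateral seeds with narrow duration
  (16–22 years) and rate spreads, so the hemispheric class effect is not
  swamped by disease-stage heterogeneity.

What passing these benchmarks shows: the fitting, ranking and statistical
machinery recovers known ground truth under the generator's assumptions.
What it does not show: performance on real tau-PET data, whose off-target
binding structure, connectome measurement error, demographic covariance
and regional vulnerability are all richer than the generator's.

## Statistics

Fit accuracy is the squared Pearson correlation; a zero-variance vector
makes it undefined (flagged, excluded from means with the count logged —
note a perfectly anticorrelated pattern also scores 1.0).  Null-model
significance is the one-sided exceedance count over the ensemble, floored
at 1/n_null, with percentile 95% intervals.  The amyloid-residual analysis
classifies regions by the sign of mean observed − mean predicted, compares
group-mean amyloid between classes by Welch's two-sided t-test, correlates
residuals with amyloid (Pearson, parametric p), and fits OLS of residual
on amyloid + regional tau.  Asymmetry analysis classifies subjects
(left-limbic / right-limbic / other, limbic = entorhinal, hippocampus,
amygdala, parahippocampal), relates the class to the laterality index
(mean left − right across cortical regions) and demographics by OLS GLMs
adjusting for disease status, and fits per-region GLMs (adjusting for
disease status, age, sex) corrected across regions by Benjamini–Hochberg
FDR at q < 0.05.  Per-region GLMs run through a closed-form OLS path
(numerically identical to the statsmodels fit used for the headline GLMs)
so the 200-simulation calibration loops stay fast.  Cohort matching is
greedy nearest-neighbor without replacement on z-scored features under
Euclidean distance, walking the reference in order; an exact
distance-matrix implementation stands behind the contract (tree structures
are an implementation freedom).

## Pipeline

The methodological grid crosses six axes — connectome template (4), region
set (3), tau transformation (3), PVC provenance flag (2), confound
strategy (3), amyloid-negative MCI inclusion (2) — for 432 configurations;
the Euclidean-distance baseline is exposed by flag but excluded from the
grid, and PVC selects input provenance only (partial-volume correction
happens upstream of regional tables and is out of scope).  `run_pipeline`
executes subject filtering → confound regression → transformation →
region-set selection → spreading-model fit → summaries, fully determined
by the configuration's seed, and embeds the configuration and package
version in every results bundle.  Configs serialize to YAML (JSON
accepted); matrices to CSV/TSV with subject/region headers, validated and
reordered against the region table on read.

## Numerical and degenerate-input policy

Zero-variance regions fail mixture fitting explicitly; EM non-convergence
after restarts raises with diagnostics.  All-zero subjects fit to
near-zero predictions with r² flagged undefined.  Empty W-score reference
groups, rank-deficient covariates, thresholds not strictly decreasing,
empty region sets, misaligned connectomes and non-numeric or duplicate
table entries raise immediately.  Acceptance-scale runs use reduced
problem sizes (coarse grids, 20–60-subject calibration cohorts, 100-null
ensembles), chosen as the smallest sizes at which the benchmarked
quantities are stable.
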