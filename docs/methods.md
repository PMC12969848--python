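# Methods

## Design

The package analyses a paired diagnostic accuracy and agreement study of
burn assessment. The analytic unit is the region-case — one anatomically
distinct burn region (Lund–Browder area) on one patient — rated by (i) a
single multimodal model, (ii) a group of emergency physicians, and (iii) an
expert panel whose consensus is the reference standard. Patients can
contribute several region-cases, so observations are clustered by patient and
every inferential statement uses patient-level resampling; no model-based
standard errors or mixed-effects models are used anywhere.

Two analysis populations are built from the validated tables. The full
analysis set keeps region-cases with a usable model rating, at least one
usable physician rating and at least one assessable panelist rating; the
per-protocol set additionally drops cases rated non-assessable by two or more
panelists. TBSA entries outside [0, 100] are retained in the data model with
an entry-error flag and a log line but excluded from every computation —
exclusion is the conservative choice when the downstream handling of such
errors is not otherwise constrained.

## Reference and comparator consensus

Panel consensus per region-case: median TBSA and majority depth, with a
three-way depth tie defaulting to deep partial. A case is auto-accepted when
the panel TBSA range is ≤ 2 p.p. **and** a strict (> n/2) depth majority
exists; otherwise the same median/majority consensus is still computed but
flagged `needs_adjudication` — the human re-score round that would resolve
such cases in a live study cannot be executed by software, so the flag keeps
them auditable instead of silently resolved. "Majority" is strict rather than
plurality; both the threshold (2 p.p.) and the tie rule are overridable
parameters.

Physician consensus: median TBSA across raters (midpoint convention for even
counts — relevant with 18 raters) and modal depth with ties broken toward the
deeper class, by analogy with the panel's tie default; the deliberate
asymmetry errs on the side of clinical caution. Pre-consensus agreement is
summarized by ICC(2,1) for TBSA and, for depth, the mean pairwise
quadratic-weighted kappa — a simple, transparent multi-rater generalization
chosen because no single canonical one exists for weighted kappa.

## Primary endpoint

For region-case *i*, Δᵢ = |model − panel| − |physician-median − panel| in
percentage points. The location estimate is the Hodges–Lehmann median of all
Walsh averages (self-pairs included), robust to the skewed, spiky error
distributions typical of small-region TBSA data. Its one-sided 95% upper
bound comes from the cluster bootstrap: patients are drawn with replacement
(n_patients draws per replicate) and every region-case of a drawn patient is
kept, so replicate sample sizes vary and duplicated patients contribute
duplicated regions — the standard cluster bootstrap. Intervals are percentile
intervals (inclusive/type-7 quantiles of the replicate vector); percentile
was chosen over BCa/studentized as the transparent default. Decisions:
`superior` if the upper bound < 0, else `non_inferior` if ≤ margin
(default 3 p.p.), else `not_demonstrated`; superior implies non-inferior and
the strongest label is reported.

Replicate b's cluster draws are row b of an index matrix generated by a
Philox counter-based generator keyed by the seed, and clusters are sorted
canonically before sampling — the replicate vector is therefore a fixed
function of (seed, data multiset), independent of input row order or
execution strategy. Replicates on which a statistic is undefined (possible
for kappa on degenerate resamples of a small study) are recorded and counted;
more than 1% undefined aborts with diagnostics. Primary-endpoint bootstraps
use 5000 replicates, agreement-metric CIs 2000.

A sensitivity analysis re-runs the primary analysis on one randomly selected
region-case per patient (default 200 repeats), reporting the maximum and
median upper bound and decision stability.

## Agreement and calibration statistics

* Absolute-error tolerance bands are inclusive (error ≤ 3 counts as "within
  ±3 p.p.").
* Lin's CCC uses population (1/n) moments, the original definition; at n = 64
  the 1/(n−1) variant changes the third decimal, so the convention is fixed
  and documented.
* Bland–Altman limits are bias ± 1.96·SD with the sample (n−1) SD.
* Weighted kappa uses agreement weights 1 − (i−j)²/(k−1)²; expected agreement
  comes from the margin product. Degenerate margins (chance agreement 1)
  raise an explicit error rather than returning NaN.
* ICC(2,1) is computed from two-way ANOVA mean squares,
  (MS_R − MS_E)/(MS_R + (k−1)MS_E + k(MS_C − MS_E)/n), and requires a
  complete case × rater matrix (complete-case restriction upstream).
* Calibration is OLS of estimate on reference; a constant estimate returns
  slope 0 with R² 0 rather than an error.
* ROC AUC uses midranks (ties get half credit); the paired AUC comparison is
  DeLong's method via placement values, not bootstrap. Threshold
  discrimination is computed at the patient level (regional TBSA summed per
  patient; the panel sum defines the binary truth) because the clinical
  cut-points — adults ≥ 20%, pediatrics ≥ 10% (configurable up to 15) — are
  whole-body quantities; region-level computation is selectable. Scores enter
  as distance to the age-specific threshold so pediatric and adult patients
  share one ROC.
* The depth confusion matrix can be reconstructed from row totals, column
  totals and the diagonal sum by exhaustive search over non-negative integer
  matrices; the result is returned only when unique, otherwise the number of
  solutions is reported. Marginal constraints are re-verified post hoc.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, so the whole
pipeline is testable without any external data:

* 52 patients; regions per patient 1/2/3 with probabilities 43/52, 6/52,
  3/52 (expected 64 region-cases); pediatric fraction 35/64; site
  probabilities 7/64, 6/64, 21/64, 30/64 (face/head, torso, upper, lower
  extremity); true depth 47/64, 16/64, 1/64 (SP/DP/FT).
* True regional TBSA ~ 15·Beta(1.5, 4): right-skewed on (0, 15], small
  regions dominating. No empirical regional TBSA distribution is available
  for this design, so this family is a modelling choice, config-exposed, and
  deliberately not treated as estimated from data.
* Ratings follow rating = intercept + slope·true + b_rater + ε, clipped to
  [0, 100], with b_rater ~ N(0, σ²_rater) shared across a rater's cases and
  ε ~ N(0, σ²_resid) per rating. For a slope-1 group the generating-model
  ICC is var(true)/(var(true) + σ²_rater + σ²_resid); the preset solves this
  closed form so physician noise lands exactly on ICC 0.71 (30% of the noise
  variance assigned to the rater effect) and panel noise on ICC 0.97.
* The model rater has intercept 1.05 and slope 0.71 (compression of extremes
  toward the centre), residual SD 1.5 p.p., and a depth confusion matrix that
  downgrades severity: P(SP | true DP) = 13/16, P(SP | true FT) = 1, never
  reporting full thickness. The panel confusion matrix's diagonal reliability
  is solved in closed form so the expected pairwise quadratic-weighted kappa
  between two independent panelists (from the joint distribution
  J_ij = Σ_t p_t C_ti C_tj at the default prevalence) equals 0.86; the
  physician confusion matrix is a plausible choice giving substantial depth
  agreement and is not a calibrated target.
* Depth errors are conditionally independent across raters given the true
  class; a case-difficulty random effect is a noted extension, not in v1.
* Randomness: one global seed; cohort and each rater group draw from separate
  Philox substreams so adding a rater group never perturbs the others.

What passing tests on this generator do **not** show: performance on real
photographs, behaviour under image-quality degradation, skin-tone and
lighting generalization, or any property of a particular model version — the
generator reproduces summary structure (clustering, prevalences, rater
agreement levels, calibration compression), not images or case difficulty.

## Problem sizes and numerical choices

Simulation-based checks use: 500 simulated studies for bootstrap coverage
(n = 200 singleton clusters, B = 2000) and for null error control (52-patient
clustered studies, B = 5000); 200 replicates for ICC and calibration
parameter recovery at 64 cases. The one-region-per-patient sensitivity in the
scripted analyses uses 1000-replicate bootstraps per repeat, a simulation-size
choice; the primary analysis itself always uses 5000. Quantiles are type-7;
kappa/CCC degeneracies raise typed errors that the bootstrap counts as
undefined replicates (1% cap).

## Known limitations

* ICC requires complete case × rater matrices; incomplete designs are
  rejected with a complete-case suggestion rather than estimated.
* The physician-consensus depth agreement implied by the preset confusion
  matrices is higher than a real physician group would show, because modal
  voting over 18 conditionally independent raters removes most noise; only
  the explicitly calibrated targets should be read quantitatively.
* Percentile intervals can undercover for strongly biased statistics at small
  cluster counts; BCa is not implemented in v1.
* The adjudication flag marks, but does not emulate, human re-scoring.
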