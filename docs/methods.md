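# Methods

This note documents the statistical procedures implemented in `vaprot`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and known limitations.

## 1. Paired venoarterial screen

For protein *p* and participant *i* with both vessels of a pair sampled, the
test quantity is the paired difference on the log2 RFU scale,
d\_{ip} = log2(RFU_vein) − log2(RFU_artery). Pairing is complete-case per
vessel pair: a participant missing one vessel is excluded from that pair but
still contributes to other pairs.

**Median normalization.** Plasma-water movement between artery and vein
rescales every protein of a sample by a common factor — an additive
per-sample constant on the log2 scale. For each participant the median of
d\_{ip} across the protein panel is subtracted from all of that
participant's differences, which removes any per-sample additive constant
exactly (tested as an algebraic invariant). The justifying assumption is
that the majority of proteins are not exchanged, so the panel median of the
differences estimates the sample's global bias. Normalization is applied per
vessel pair, after QC filtering, and requires ≥ 10 proteins.

**Testing and classification.** Per protein, a two-sided one-sample t-test
of H₀: E[d] = 0 (minimum 3 complete pairs), Benjamini–Hochberg adjustment
across all non-degenerate tested proteins of one vessel pair (one BH family
per pair). A protein is classified *released* when the adjusted p-value is
below α and t > 0, *taken up* when below α and t < 0. Zero-variance
difference vectors are flagged degenerate and classified `none` rather than
propagating NaN p-values. α defaults to 0.05 (the analysis threshold) and is
configurable; the screen's power guarantee at the design sample size of 75
holds at FDR 0.1. Differences are also reported as percent higher RFU in
vein than artery: (meanᵢ 2^{d_{ip}} − 1) × 100.

**Diagnostics.** A 20-bin p-value histogram with a chi-square uniformity
test (level 0.01) on the bins above p = 0.5: a well-calibrated screen shows
a spike near zero over a flat tail. The check is flagged degenerate when the
tail expects fewer than 5 counts per bin.

## 2. Placenta-specificity

The arm pair AV − RA is a proxy for a generic systemic venoarterial
difference. Only proteins classified released in UV − RA are eligible.
Criterion 1: the per-participant contrast (UV−RA) − (AV−RA), computed on
participants with all three vessels, is significantly positive (paired t,
BH across the contrast family, same α). Criterion 2: the protein's arm
screen shows t ≤ 0 or an adjusted p ≥ α (degenerate arm tests count as
null). A protein is placenta-specific if either criterion holds, which
guarantees structurally that the specific set is a subset of the released
set.

Design choices: criterion 2 uses the arm's *FDR-adjusted* p at the same α as
the release screen (a single FDR level throughout); the contrast tests form
their own BH family, separate from the release and arm families.

## 3. Gestational trajectories

Per protein, the mixed model

y\_{ij} = β₀ + Σₖ βₖ Bₖ(GA\_{ij}) + b\_i + ε\_{ij},  b\_i ~ N(0, σ\_b²), ε ~ N(0, σ²)

with Bₖ a cubic B-spline basis of gestational age, fitted by REML
(statsmodels MixedLM). Defaults: spline df = 3 (cubic basis, boundary knots
at the observed GA extremes, no interior knots — with three visit windows
per participant, higher df risks rank deficiency), half-week prediction
grid over the observed GA range. The mean trajectory is the fixed part on
the grid.

Numerical handling: optimizer non-convergence triggers retries with L-BFGS
and Powell; a fit that still reports non-convergence but has finite
estimates is accepted with the message "variance at boundary" (typical when
σ\_b or σ is estimated at zero; the mean curve is unaffected). An exactly
constant response is returned in closed form. Fits with non-finite
coefficients are excluded from curve assembly with a warning. All-identical
gestational ages raise a rank-deficiency error.

**Clustering.** Pairwise curve distance 1 − Pearson correlation across grid
points (location/scale-free, so curves are compared by shape), complete
linkage, candidate k = 2..8. For each k the dendrogram is cut and the mean
silhouette width computed on the same correlation distance (internal
consistency of the selection criterion); degenerate cuts (fewer distinct
labels than k) are never optimal. Constant curves have undefined correlation
and are rejected by name. For display, curves can be shifted to start at
zero (first grid value subtracted), preserving within-curve changes.

## 4. Proteomic gestational-age clock

**Split.** Participants (never samples) are split 2/3 train : 1/3
validation, seeded; all visits of a participant stay on one side.

**Stability selection.** Defaults: π = 0.6, 100 subsamples of ⌊n/2⌋
*training participants*, elastic-net mixing weight 0.5, 50-alpha
regularization path, per-family error bound PFER = 1 giving a per-subsample
active-set cap q = ⌊√(PFER·(2π−1)·p)⌋ for p candidates. Subsampling is by
participant because repeated visits are exchangeable only at the participant
level. Mandatory covariates (maternal age, BMI, nulliparity; nulliparity
coded 1 = nulliparous) are kept unpenalized via Frisch–Waugh partialling-out:
within each subsample the response and every candidate are residualized on
the covariates by OLS and the penalized path is fitted on the residuals.
Candidates are standardized within each subsample, so selection frequencies
are invariant to column rescaling. A protein counts as selected in a
subsample if it enters the active set at any penalty where the active set is
within the cap; the stable set is {p : frequency ≥ π}. The method names and
their recommended defaults are used because the analysis this package
re-implements does not report its settings; all are configurable.

**Final model and evaluation.** OLS of GA (weeks) on the stable proteins
plus covariates, coefficients on original scales (weeks per log2 RFU, weeks
per covariate unit), collinear designs rejected. Leave-one-participant-out
CV refits the OLS model per fold and pools held-out predictions; the frozen
model is also evaluated on the validation third. Both Pearson r and RMSE
(weeks) are reported, since the source analysis is ambiguous about which
split its headline correlation refers to. Constant prediction vectors make
r undefined; they are flagged degenerate while RMSE is still returned.

## 5. Preprocessing

* **log2 transform** of raw RFU, with non-positive values rejected by
  row/column coordinates.
* **Winsorization** of extreme-abundance trajectories: the unit is a
  (participant, protein) trajectory; its mean across that participant's
  visits is compared with the q-th quantile (default 0.98, type-7 linear
  interpolation) of all trajectory means pooled over participants and
  proteins; trajectories above the threshold are shifted down so their mean
  equals the threshold, preserving visit-to-visit changes exactly. Whether
  the pooling should instead be per protein is genuinely open; the pooled
  reading is implemented. The winsorization map is idempotent at a fixed
  fitted threshold; re-estimating the threshold from already-winsorized data
  can move it slightly below the original (interpolation across the clamped
  point mass), so the estimator (fit once, transform) is the supported
  idempotent form.
* **Atypical samples**: a sample's across-protein median log2 RFU is
  compared with the cohort median of sample medians; deviations beyond
  mad_threshold (default 5) robust SDs (MAD × 1.4826) flag the sample. This
  replaces by-eye exclusion of whole-sample distributional outliers with a
  reproducible rule; it is invariant to global additive shifts.
* **QC filter**: protein columns restricted to `qc_pass` metadata, order
  preserved.

## 6. Synthetic-data generator

The generator states a world in which every downstream stage has known
ground truth; it does not model the assay.

**Four-vessel cohort.** Per-protein baseline means ~ N(10, 2) on the log2
scale (an aptamer-panel-like dynamic range giving realistic winsorization
tails), per-participant level offsets ~ N(0, 0.3). RA is the baseline; UV
and AV add an independent per-sample water shift ~ N(0, water_shift_sd), the
planted effect, and within-pair noise ~ N(0, pair_noise_sd). Defaults mirror
the screening design point: 75 participants, 4564 proteins, 5% released at
+0.5 and 2% taken up at −0.5 with pair_noise_sd = 1.0 (so effects read as
standardized paired effect sizes), water_shift_sd = 0.1, plus 10% of
proteins with an arm (AV−RA) effect of +0.5, all plant sets disjoint.
Missing vessels are missing completely at random. The spec field list has no
arm-effect size, baseline spread, or participant-offset spread; the three
values above are the package's choices and are configurable.

**Longitudinal cohort.** 70 participants, one visit per gestational window
(defaults 12–18, 21–26, 29–33 weeks, uniform within window, recorded to 0.1
week), participant random intercept SD 0.3 and residual SD 0.05 per protein.
Clock proteins follow intercept + 0.1·(GA − 22) log2 RFU; two trajectory
families share fixed shapes with per-protein amplitudes ~ U(0.5, 1.5):
family 1 a monotone logistic rise, family 2 a rise-then-fall quadratic with
an interior maximum — chosen to exercise cluster separability, not
biological fidelity. Covariates: age ~ N(32.1, 3.6), BMI ~ N(24.1, 2.9)
(clipped at 17), nulliparity ~ Bernoulli(0.5), matching the longitudinal
cohort's demographics.

**What a green test does not establish.** The generator has independent
proteins, Gaussian noise, a single additive bias per sample, and no plate,
batch, or cross-reactivity structure. Recovery results therefore validate
the statistical machinery, not robustness to correlated proteins or
assay artifacts.

## 7. Known limitations

* **Median normalization bias under asymmetric exchange.** If planted (or
  real) effects are predominantly one-sided, the per-sample median of the
  differences is shifted by the plants themselves, giving every null protein
  a small opposite-sign bias after normalization. At the design point
  (5% released at +0.5, 2% taken up at −0.5, n = 75) the residual bias is
  ~0.014 log2 units and the empirical false-discovery proportion of the
  classification sits at ≈ 0.046–0.051 against the nominal 0.05 — adequate,
  but expect inflation when exchange is strongly one-directional. This is an
  inherent property of median normalization, not of this implementation.
* The uterine vein drains decidua and myometrium as well as placenta; no
  attempt is made to separate their contributions, and the arm is only a
  proxy for "any systemic" venoarterial difference.
* The clock's stability-selection settings (π, subsamples, mixing weight,
  PFER) are canonical defaults, not values recovered from the analysis this
  package re-implements; headline protein identities and coefficients from
  that analysis are not reproducible without its cohort data.
* Atypical-sample detection only screens global level shifts (median-based);
  a sample atypical in shape but not level would pass.
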