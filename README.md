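# vaprot — venoarterial plasma proteomics

`vaprot` implements a pipeline for identifying proteins exchanged between an
organ and the circulation from paired vein/artery plasma proteomics, and for
turning the organ-derived proteins into longitudinal reference trajectories
and a gestational-age predictor. It is written for the uteroplacental
setting: simultaneous samples from the radial artery (RA), antecubital vein
(AV) and uterine vein (UV) of pregnant participants, plus a longitudinal
cohort of antecubital-vein samples across gestation, all quantified as
relative fluorescence units (RFU) on an aptamer panel and analyzed on the
log2 scale.

## What it computes

**Release/uptake screen.** For each protein, the per-participant paired
difference d = log2(RFU_vein) − log2(RFU_artery). Net plasma-water movement
between artery and vein ("water shift") concentrates or dilutes every
protein in a sample at once, so the per-participant median of d across the
panel is subtracted first (median normalization; valid when most proteins
are not exchanged). The screen is a two-sided one-sample t-test of
H₀: E[d] = 0 per protein with Benjamini–Hochberg FDR control across the
panel; a significant protein is *released* (t > 0) or *taken up* (t < 0).
Effects are also reported as percent higher RFU in vein than artery,
(mean(2^d) − 1) × 100.

**Placenta-specificity.** The arm difference (AV − RA) is a systemic
negative control. A released protein is *placenta-specific* if the paired
contrast (UV−RA) − (AV−RA) is significantly positive (criterion 1), or the
arm difference is negative or not significantly different from zero
(criterion 2).

**Gestational trajectories.** Per protein, a linear mixed model of log2
abundance on a cubic B-spline basis of gestational age (fixed effects) with
a participant random intercept, fitted by REML; the fixed part on a
half-week grid is the protein's mean trajectory. Mean curves are clustered
with complete linkage on the distance 1 − Pearson correlation; the number of
clusters maximizes the mean silhouette width on the same distance.

**Proteomic gestational-age clock.** Stability selection over elastic-net
regularization paths — repeated half-cohort subsamples drawn at the
participant level, mandatory clinical covariates (age, BMI, nulliparity)
kept unpenalized by partialling-out, per-subsample active sets bounded to
control the per-family error rate — yields the proteins selected in ≥ π of
subsamples. The clock is an OLS fit of gestational age (weeks) on those
proteins plus the covariates, evaluated by leave-one-participant-out CV and
on a held-out validation third.

A synthetic-data module generates both cohort types with known ground truth
(planted release/uptake/arm effects, water shifts, trajectory families,
clock proteins), so every stage is testable by parameter recovery.

## Worked example

```python
from vaprot import (SimConfig, simulate_four_vessel, venoarterial_diffs,
                    median_normalize, paired_exchange_test)

cfg = SimConfig(n_participants=75, n_proteins=1000, frac_released=0.05,
                frac_uptake=0.02, release_effect=0.5, uptake_effect=-0.5,
                water_shift_sd=0.1, seed=42)
table, truth = simulate_four_vessel(cfg)
diffs = median_normalize(venoarterial_diffs(table, "UV", "RA"))
result = paired_exchange_test(diffs, alpha=0.05)
print(f"released: {len(result.released)}, uptake: {len(result.uptake)} "
      f"(planted: {len(truth.released_set)} / {len(truth.uptake_set)})")
print(result.table.nsmallest(3, "p_fdr")[
    ["mean_diff", "t_stat", "p_fdr", "pct_change", "exchange_class"]]
    .round(4).to_string())
```

prints

```
released: 47, uptake: 20 (planted: 50 / 20)
           mean_diff  t_stat  p_fdr  pct_change exchange_class
seq_id
seq_00147     0.7209  7.0868    0.0     98.3570       released
seq_00029    -0.6837 -6.5807    0.0    -24.3411         uptake
seq_00398    -0.7035 -6.4809    0.0    -22.1786         uptake
```

i.e., at FDR 0.05 the screen recovers 47 of the 50 planted released proteins
and all 20 planted uptake proteins; `mean_diff` is the normalized mean
paired log2 difference, and `pct_change` the corresponding percent
difference in RFU between vein and artery (e.g., seq_00147 is ~98% higher in
the uterine vein).

The same stages are available from a shell:

```bash
vaprot simulate --kind four-vessel --out fv.tsv --truth-out truth.json --seed 1
vaprot exchange --input fv.tsv --vein UV --artery RA --alpha 0.05 --out screen.tsv
vaprot run --four-vessel fv.tsv --longitudinal long.tsv --out-dir out/
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch on synthetic cohorts with
known ground truth:

* **t1** — average detection power (%) of the paired screen at its design
  point (75 participants, 4564 proteins, 5% released at standardized paired
  effect 0.5, BH FDR 0.1), over 20 simulated cohorts;
* **t2** — the empirical false-discovery proportion of the release/uptake
  classification at FDR 0.05, over 50 cohorts;
* **t3** — the Pearson correlation of predicted vs true gestational age from
  the full clock workflow (2/3 participant split, stability selection, OLS
  clock, LOPO-CV and held-out validation), reporting the smaller of the CV
  and validation correlations.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the statistical model, default parameters, and
known limitations.
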