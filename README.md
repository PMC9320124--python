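# bandcoda

Compositional analysis of the physical-activity **intensity spectrum** in
school-aged youth: nine-band time-use compositions from wrist-worn
accelerometer data, pivot-coordinate log-ratio regression of BMI z-score on
the composition, and "one-for-remaining" compositional isotemporal
substitution with delta-method confidence intervals.

It is written for physical-activity epidemiologists who want to analyse the
full acceleration intensity spectrum instead of collapsing it to a few
cut-point categories (sedentary / light / MVPA), and for methodologists who
want a tested, seeded reference pipeline for compositional time-use
regression.

## The method

Each participant's waking day (07:00–23:00, 960 min) is summarised as a
nine-part composition **x** = (x₁, …, x₉): average minutes per day in nine
ENMO acceleration bands (0–50, 50–100, …, 300–350, 350–700, ≥700 mg), closed
so that Σxⱼ = 960. ENMO is the Euclidean norm of the three accelerometer axes
minus 1 g, negatives truncated to zero, averaged over 1-s epochs.

Because a composition carries only relative information, it enters the model
through isometric log-ratio (ILR) *pivot coordinates*. For the rotation
leading on band j, the first coordinate is

  z₁⁽ʲ⁾ = √(8/9) · ln( xⱼ / g(x₋ⱼ) ),

the time in band j relative to the geometric mean g(x₋ⱼ) of the remaining
eight bands. BMI z-score is regressed by OLS on the eight ILR coordinates
plus covariates (sex, school-mean-centred age, EIMD deprivation decile,
device model, sampling frequency); the model is refit nine times, once per
leading band, and the nine β_ILR1 coefficients are reported with t-based 95%
CIs. All nine rotations span one column space, so their fitted values are
identical and Σⱼ β_ILR1⁽ʲ⁾ = 0 — both serve as built-in correctness oracles.
An omnibus F-test compares the full model with the covariates-only model.

Isotemporal substitution moves t minutes into one band and takes t/8 from
each remaining band, starting from the sample's geometric-mean composition.
Covariates cancel in the predicted difference, which reduces to
Δ(t) = **β**ᵢₗᵣ·(ilr(x·t) − ilr(x)); its standard error is √(dᵀVd) from the
coefficient covariance V, giving delta-method CIs. Δ(t) is nonlinear and
asymmetric in t: removing minutes from a small high-intensity band is a far
larger relative change than adding them.

A seeded generator produces synthetic cohorts calibrated to the published
descriptive structure (girls' share 57.5 %, outcome SD 1.24, per-sex
geometric-mean compositions, a 1803 → 67/233/50 → 1453 exclusion cascade),
with the outcome genuinely linear in clr coordinates so that parameter
recovery and CI coverage are exactly testable.

## Worked example

```python
import bandcoda as bc

cfg = bc.GeneratorConfig()                       # calibrated defaults
roster = bc.inject_missingness(bc.generate_cohort(cfg, seed=1), cfg, seed=2)
sample, report = bc.exclusion_cascade(roster)
sample = bc.center_age_by_group(sample)
print(report)
# {'n_roster': 1803, 'missing_outcome': 67, 'wear_criteria': 233,
#  'missing_ses': 50, 'n_retained': 1453}

scan = bc.pivot_scan(sample)
print(scan.omnibus)
# {'F': 48.3, 'df1': 8, 'df2': 1438, 'p': 2.8e-69}
print(scan.table[["band", "beta_ilr1", "ci_lo", "ci_hi", "p"]].round(3))
#       band  beta_ilr1  ci_lo  ci_hi      p
# 0     0-50      0.015 -0.694  0.724  0.967
# ...
# 8     700+     -0.602 -0.735 -0.470  0.000
```

The omnibus test says the intensity-band composition is strongly associated
with BMI z-score; the ≥700 mg row says time in the highest band, relative to
all remaining bands, is inversely associated with it. Substituting time
around the girls' geometric-mean composition:

```python
girls = sample[sample.sex == "girl"].reset_index(drop=True)
m = bc.fit_model(girls, covariates=("age_centred", "eimd_decile",
                                    "accel_model", "sampling_freq"),
                 lead_band="700+")
base = bc.geometric_mean_composition(girls[list(bc.BAND_LABELS)].to_numpy())
print(bc.predicted_difference(m, base, "700+",  5.0).delta)   # -0.30
print(bc.predicted_difference(m, base, "700+", -5.0).delta)   # +0.76
```

Adding 5 min/day to the ≥700 mg band predicts a 0.30-unit lower BMI z-score,
while removing the same 5 min predicts a 0.76-unit increase — the
characteristic asymmetry of compositional reallocations out of a small band.

The same pipeline runs from the shell:

```bash
bandcoda all --seed 1 --out-dir run/   # simulate → filter → fit → substitute → report
```

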