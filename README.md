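# graftage

Epigenetic-age analysis for lung-allograft methylation cohorts.

After lung transplantation, the graft's airway epithelium carries the
*donor's* biology. Two clinical questions follow: does the graft's biologic
(epigenetic) age track the donor's chronologic age rather than the
recipient's, and do early injuries — severe primary graft dysfunction
(PGD), an ischemia-reperfusion injury in the first post-transplant days —
accelerate that biologic age? `graftage` implements the full statistical
pipeline for answering these questions from CpG methylation array data,
together with a synthetic-cohort generator that reproduces the data's
statistical structure with known ground truth, so that every stage is
verifiable by parameter recovery without any patient data.

The package is aimed at transplant-epigenomics analysts: it starts from a
beta-value matrix (samples × CpGs, β ∈ [0, 1]) and a clinical sample sheet,
and ends at publication-shaped tables.

## What it computes

**Epigenetic clock.** A penalized linear clock in the multi-tissue style:
chronologic age *a* is mapped through the calibration

```
F(a) = log(a + 1) − log(adult_age + 1)        a ≤ adult_age
F(a) = (a − adult_age) / (adult_age + 1)      a > adult_age
```

(`adult_age` = 20 by default; F is strictly increasing with a closed-form
inverse), and F(a) is regressed on CpG betas with an elastic-net penalty
chosen by seeded 10-fold cross-validation (1-SE rule). Predicted age is
`F⁻¹(b₀ + Σⱼ wⱼ βⱼ)`; missing probes are imputed with training means.

**Association models.** Pearson correlation of methylation age with graft
age (brush date − donor birthdate) and recipient age; the methylation/graft
age ratio (median, IQR); Mann-Whitney and linear models for the PGD effect;
and a sequential-covariate ladder (PGD + batch → + donor age → + donor
sex/BMI/CMV/ethnicity → + recipient characteristics and indication) with
ANOVA F-tests between nested fits. Batch is a fixed-effect covariate in
every model.

**Survival.** Cox proportional hazards for CLAD-or-death, left-truncated at
the airway brush (subjects enter the risk set at `entry_time`), Efron ties;
methylation age enters as a continuous predictor, an ordinal tertile, or a
top-tertile indicator. Kaplan-Meier curves are truncation-aware. Power for
a given hazard ratio is estimated by simulation: redraw the predictor from
its observed moments, simulate event times from the Nelson-Aalen baseline
under each HR on a grid, and read power off a logistic fit to the
rejection outcomes.

**Differential methylation.** Genome-wide mean beta comparison; CpG→promoter
aggregation (unweighted means); within-batch location normalization of
promoter values; per-promoter Welch t-tests with Benjamini-Hochberg
adjustment; and a two-sample Kolmogorov-Smirnov comparison of each gene
set's promoter t-statistics against all out-of-set promoters (GMT gene
sets, BH across sets) — the design that detects coordinated pathway-level
hypomethylation even when no single promoter survives FDR.

## Worked example

```python
import numpy as np
from graftage import (SimulationConfig, simulate_cohort,
                      simulate_training_cohort, train_clock, predict_age,
                      correlate, ratio_summary, fit_linear, fit_cox,
                      tertile_assign)

cfg = SimulationConfig(seed=1)                      # 28 subjects, 13 PGD
train_betas, train_ages = simulate_training_cohort(cfg, 500)
model = train_clock(train_betas, train_ages, seed=1)
print(f"clock keeps {model.n_nonzero} of {len(model.cpg_ids)} CpGs")

betas, samples, promoters, gene_sets, truth = simulate_cohort(cfg)
meth_age = predict_age(model, betas)
donor = samples.data["donor_age"].to_numpy()
r, r2, p = correlate(donor, meth_age)
print(f"graft age vs methylation age: R^2 = {r2:.2f}, p = {p:.1e}")
med, (q1, q3) = ratio_summary(meth_age, donor)
print(f"methylation/graft age ratio: median {med:.2f} [IQR {q1:.2f}-{q3:.2f}]")

fit = fit_linear(meth_age, samples.data[["pgd"]],
                 always_adjust=samples.data[["batch"]])
lo, hi = fit.ci("pgd")
print(f"PGD effect (batch-adjusted): {fit.coef('pgd'):.1f} y "
      f"(95% CI {lo:.1f} to {hi:.1f})")

tert = tertile_assign(meth_age)
cox = fit_cox(samples, (tert == 3).astype(float), name="top_tertile")
lo, hi = cox.hr_ci.loc["top_tertile"]
print(f"CLAD-or-death HR, oldest tertile: {cox.hr['top_tertile']:.2f} "
      f"(95% CI {lo:.2f}-{hi:.2f}), {cox.n_events} events")
```

prints

```
clock keeps 128 of 761 CpGs
graft age vs methylation age: R^2 = 0.72, p = 1.2e-08
methylation/graft age ratio: median 0.43 [IQR 0.37-0.45]
PGD effect (batch-adjusted): 1.9 y (95% CI -2.6 to 6.3)
CLAD-or-death HR, oldest tertile: 1.42 (95% CI 0.53-3.76), 18 events
```

Reading the output: the clock's age predictions correlate strongly with
graft (donor-derived) age but sit well below it — the median ratio of 0.43
reflects the systematic "younger" read-out of a clock trained on other
tissues (the generator's attenuation, 0.38, is set to mirror that
behavior). The 28-subject PGD contrast on the attenuated methylation-age
scale is small against its confidence interval, and the survival hazard
for the oldest tertile is imprecise at 18 events — the small-cohort
uncertainty the pipeline's power machinery quantifies.

The same stages are available from a shell via the `graftage` console
script (`graftage simulate`, `clock-train`, `clock-predict`, `associate`,
`survive`, `power`, `diffmeth`); run `graftage --help` for details.

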