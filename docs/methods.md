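# Methods

This note documents the models behind `graftage`, the defaults and why
they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical decisions a maintainer would want written down.

## The epigenetic clock

The clock is a penalized linear predictor of a calibrated age transform.
With `adult_age` A (years, default 20), the calibration is

    F(a) = log(a + 1) − log(A + 1)   for a ≤ A
    F(a) = (a − A) / (A + 1)         for a > A,

continuous and strictly increasing on (−1, ∞), anchored at F(A) = 0, with
the obvious closed-form inverse. The logarithmic limb reflects the fast
epigenetic drift of development, the linear limb the steady adult ticking.
Training regresses F(age) on CpG betas with an elastic net
(mixing `l1_ratio` = 0.5). Penalty strength is selected on a 50-point
log-spaced path by 10-fold cross-validation with a seeded fold shuffle;
among strengths within one standard error of the CV minimum, the strongest
is kept (the 1-SE rule), which biases toward sparser, more stable clocks.
The p > n regime is routine — a reference panel smaller than the candidate
CpG panel still yields a usable sparse model.

Prediction is `F⁻¹(b₀ + w·β)` per sample, so it is invariant to CpG column
order and identical whether samples are predicted pooled or per batch
subset (asserted by a test). Model CpGs absent from a matrix are imputed
with per-CpG training means carried in the serialized model — never with
zero, which is an extreme beta — and prediction refuses to run below a
configurable 90% probe-overlap floor.

## Synthetic cohorts

The generator produces the structure the analysis assumes, each piece with
a tunable magnitude and a recorded ground truth:

* **True epigenetic age.** `A_i = donor_age_i + δ·pgd_i + η_i`,
  η ~ N(0, τ²). Defaults: donor ages uniform on 18–65 y, δ = 6.5 y of
  PGD acceleration, τ = 8 y of biological dispersion. τ was fixed once so
  that the cohort-level methylation-age/graft-age R² lands near 0.7 —
  strong but visibly noisy, as airway data at one year post-transplant
  would be.
* **Clock CpGs.** Logit-scale betas `a_j + b_j·F(s·A_i + c) + batch + ε`,
  ε ~ N(0, σ²) with σ = 0.1; intercepts a_j ~ N(−0.2, 1), slope magnitudes
  0.5–1.5 with random sign. The **attenuation** s = 0.38 (offset c = 0)
  composes the clock signal with a shrunken apparent age: a clock trained
  on the reference panel (see below) then reads airway samples
  systematically "young", with slope ≈ s per graft-age year and a
  methylation/graft-age ratio near 0.4. This emulates tissue mismatch
  between a multi-tissue reference panel and airway epithelium by the
  simplest mechanism that reproduces the observed slope, rather than by
  actually training on mismatched tissue.
* **Reference (training) panel.** Ages uniform on 1–90 y; betas from the
  same (a_j, b_j) but with the *un-attenuated* transform F(age), no batch
  shifts and no PGD — the clean, large panel an external clock comes from.
* **Batches.** Two processing batches with additive logit offsets (0 and
  0.2), randomly assigned half/half — the magnitude of a modest array
  processing-site shift.
* **Promoters and gene sets.** A synthetic catalogue of 500 genes on one
  chromosome (TSS every 10 kb, promoter window [TSS−1500, TSS+500)
  strand-aware, 0-based half-open), 3 CpGs per promoter, and 50 named gene
  sets of 25 genes sampled with overlap, Hallmark-style. Promoter CpGs
  carry a subject-level random effect shared across a promoter's CpGs
  (logit SD 0.4 ≈ 0.09 beta SD) on top of probe noise. That subject-level
  variance is what limits per-promoter testing power: with the default
  hypomethylation Δ = 0.05 (beta scale, applied to affected-set promoters
  in PGD subjects only), single promoters rarely survive FDR while the
  set-level KS procedure detects the coordinated shift reliably — the
  qualitative regime the pipeline is designed for.
* **Survival.** Exponential proportional hazards on true age: hazard
  λ₀·exp(β_surv·A_i) with λ₀ = 5×10⁻⁵/day and β_surv = 0.05/year, entry at
  the brush (uniform 360–380 d), administrative censoring at 2000 d.
  Because the exponential is memoryless, drawing the residual time from
  entry is exactly the left-truncated draw. λ₀ yields roughly half the
  cohort with events — enough for Cox fits whose intervals are still
  honestly wide at n = 28.

Everything derives from `config.seed` through three independent streams
(structure / study subjects / training subjects), so a clock trained on
the panel applies to the cohort, identical configs are bitwise
reproducible, and a `subject_seed` can redraw panel subjects against fixed
structure for held-out evaluation.

**What the generator does not emulate:** probe-type chemistry and
detection noise, cell-composition shifts, CNV/SNP artifacts, correlated
CpGs beyond the single-factor age signal, non-proportional or
non-exponential hazards, and informative censoring. Passing recovery tests
therefore demonstrates correctness of the *statistics*, not robustness to
those real-data complications.

## Association statistics

Ordinary least squares with Wald t intervals; categorical covariates are
dummy-coded with the alphabetically first level as reference; batch enters
every model, including the "unadjusted" PGD model, as a fixed effect.
Rank-deficient designs fail loudly, naming the aliased columns. The
sequential ladder fits PGD+batch, then adds donor age, donor
characteristics, and recipient characteristics plus indication; successive
models are compared by the RSS-based F-test. Missing covariates are an
error — silently dropping subjects from some rungs would break the
nesting.

The characteristics table routes each continuous variable by a
Shapiro-Wilk test at α = 0.05 on *group-centered residuals* (a single
pooled test rather than one per group, so the nominal routing error stays
at 5%): normal → Student's t with mean (SD); non-normal → Mann-Whitney
with median [IQR]. Categoricals use chi-squared, Yates-corrected only for
2×2 tables. No multiplicity adjustment is applied across table rows.
Quantiles throughout are linear-interpolation (R type-7). Mann-Whitney
p-values are exact for combined n ≤ 20 without ties, otherwise
normal-approximated with tie correction; an all-tied comparison returns
p = 1 by convention (no evidence, not an error).

## Survival analysis

Cox partial likelihood with Efron tie handling and delayed entry: risk
sets contain subjects with `entry < t ≤ time`. Convergence is tightened to
1e-10 so small worked examples agree with closed-form solutions to
machine-level precision. A zero-variance predictor returns the null fit
(HR 1, p 1) rather than an optimizer failure; a monotone likelihood
surfaces as a typed convergence error with the diverging direction.
Tertiles cut at the 33⅓ and 66⅔ percentiles, ties going down; the tertile
model is fit both as an ordinal slope and as a top-tertile indicator,
since both contrasts are standard.

Power is simulated rather than computed from a formula because left
truncation plus a fixed censoring pattern has no clean closed form. The
procedure holds the observed scaffold fixed — Nelson-Aalen baseline
cumulative hazard, entry times, per-subject administrative censoring at
the observed follow-up — and redraws only the predictor, from a normal
with the observed mean and SD. Event times come from inverse-transform
sampling on the step-function baseline under the grid hazard ratio;
replicates are fit and `p < α` recorded; a logistic regression of
rejection on HR over all pooled replicates smooths the curve, and power
at the query HR is read off the fit. Redrawing event indicators as well
(rather than only predictor values) would be the other defensible reading
of "simulating predictor variable distributions"; the predictor-only
design was chosen because it holds the observed information content
(event count) fixed, which is what an a-posteriori power statement should
condition on.

## Differential methylation

Promoter methylation is the unweighted mean of a promoter's CpGs per
sample; a CpG inside two overlapping promoter windows contributes to both.
Batch normalization is per-promoter location adjustment — subtract batch
mean, add back grand mean, clip to [0, 1] — deliberately leaving scale
untouched as the minimal intervention that makes batches poolable;
quantile normalization would be the stronger alternative but alters
within-batch contrasts. Per-promoter comparisons use Welch's t (unequal
variances are the default expectation for beta-scale data near
boundaries), BH-adjusted with promoters that are constant in both groups
excluded from the family size. The gene-set stage compares in-set promoter
t-statistics to all *out-of-set* t-statistics (not to the full pooled set,
which would include the tested set in its own reference) by a two-sided
two-sample KS test, exact for sets of ≤ 10 promoters, asymptotic
otherwise; BH runs across tested sets, sets with fewer than 3 mapped
promoters are skipped with a warning, and direction is the sign of the
median in-set t (zero median → "none"). Genes in multiple sets are tested
in each.

Under the global null the in-set/out-of-set statistics are dependent
across sets; the per-set p-values are treated as approximately uniform for
BH purposes, which in simulation behaves conservatively (no set passes
q < 0.01 in ~100% of null replicates).

## Problem sizes and determinism

The test suite and acceptance script run at deliberately modest sizes —
761 clock CpGs, 500-sample reference panels, 28-subject cohorts, 200
replicates for coefficient recovery, 100 seeds for gene-set detection,
1000 simulations for the power null — chosen so a full run completes in a
few minutes on a single CPU while leaving Monte-Carlo error comfortably
inside the asserted tolerances. All randomness flows from explicit seeds;
hypothesis-based property tests are derandomized by fixed example budgets.

## Known limitations

* The clock's CV training is the slowest stage (tens of seconds at
  761 × 500); no warm-start path reuse is attempted.
* `fit_cox` delegates to lifelines; likelihood-ratio intervals and firth
  correction for separation are not offered.
* The KS gene-set test treats promoters as exchangeable units; correlation
  between promoters of neighboring genes (absent in the synthetic
  catalogue) would inflate its significance on real genomes.
* Left truncation assumes entry is independent of risk given covariates;
  the generator satisfies this by construction, real cohorts may not.
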