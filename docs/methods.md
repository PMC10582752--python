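# Methods

This note documents the generative model behind the synthetic cohort, the
estimation procedures, the numerical choices, and the limitations of what
the simulations can show.

## Synthetic cohort

The generator emulates a two-year observational study of 62 MS participants
and 41 healthy controls (HC) with visits every 6 months (indexed 0–4), each
visit containing a six-minute walk (6MW) with gait speed recorded per
minute (indexed 0–5, feet/min), clinical tests (EDSS, T25FW, 9HPT, SDMT,
PASAT, accelerometer activity counts) and patient-reported outcomes (SF-36,
MSIS-29, MFIS, FSS). MS subjects belong to one of two latent classes —
low-risk progressors (LRP, n = 47 by default) and high-risk progressors
(HRP, n = 15).

### Gait speed

Speed for subject *i* (group *g*), visit *j*, minute *t*:

    y_ijt = a_g + b_g·t + c_g·t² + s_g·j + γ·(BMI_i − BMI_ref,g)
            + u_i + e_ijt,
    u_i ~ N(0, σ_b²),  e_ijt ~ N(0, σ_ε²).

Each group's quadratic (a, b, c) is the unique curve matching three
published group summaries — mean minute-0 speed, mean minute-5 speed, and
mean 6MW total distance:

| group | a (ft/min) | b | c | visit slope s |
|---|---|---|---|---|
| HC  | 357 | −12.2  | 2.2  | +2.18 |
| LRP | 317 | −8.3   | 1.5  | +0.30 |
| HRP | 245 | −6.45  | 0.85 | −5.14 |

so the HC/LRP curves are U-shaped (terminal re-acceleration) and the HRP
curve is flattened and slower — the qualitative signature the clustering is
meant to detect. Visit slopes come from the published longitudinal model
(HC gain 2.18 ft/min per visit; LRP and HRP interactions −1.88 and −7.32).

**BMI centering.** The BMI coefficient is −3.65 ft/min per kg/m². The
published model's intercept (≈348 ft/min) is only consistent with the
published group mean speeds if BMI was centered, so the generator applies
the effect to centered BMI — by default at each group's own mean BMI, which
reproduces the published group means exactly in expectation even though the
groups differ in BMI (LRP 28.2, HRP 25.4 kg/m²). Models are still *fitted*
on raw BMI; only the intercept is affected.

**Variance components.** Defaults σ_b = 35 ft/min (subject random
intercept) and σ_ε = 10 ft/min (minute-level residual). Together with the
BMI effect these reproduce the published within-group dispersion of minute
speeds (SDs ≈ 32–45 ft/min). A consequence worth stating plainly: the
between-class gap (≈ 73 ft/min in subject mean speed) is then only ≈ 2
within-class SDs — see "What the simulations show" below.

### Clinical and PRO outcomes

Each outcome follows a linear-drift model per subject:
value(j) = baseline_i + drift_i·j + noise, with baseline_i drawn from the
group's published mean/SD, drift_i ~ N(group drift, group drift SD), and
i.i.d. visit noise. By default only the HRP group worsens: T25FW
+0.25 s/visit (SD 0.15), 9HPT +1.0 s/visit (SD 0.5), SF-36 −1, MSIS-29 +2,
MFIS +1.5, FSS +1.2 per visit; SDMT carries a practice ("learning") effect
of +1.2 (HC) and +1.0 (LRP) but only +0.1 (HRP) points per visit; EDSS has
no drift anywhere (it is generated as an insensitive measure, matching its
observed two-year behaviour in mild-to-moderate cohorts); activity declines
in both MS groups, more in HRP. The T25FW/9HPT drift magnitudes were chosen
so that roughly half the HRP subjects cross the 20% worsening threshold by
visits 3–4, which puts the confirmed-progression prevalence near one third
of the MS cohort (measured ≈ 31% on average); they were fixed from this
reasoning, not adjusted afterwards.

EDSS values are snapped to the 0.5-point grid and clipped to [0, 10];
times are clipped positive. Activity counts are 7-day totals by default
(`activity_period="week"`); the same quantity is sometimes reported as a
daily average, so `activity_period="day"` divides by 7.

### Missingness

Follow-up visits are removed completely at random with per-visit rates
(7, 15, 16, 21)% for visits 1–4; baseline is never removed. Dropping is by
whole subject-visit (all six minutes and the clinical row vanish together
when the gait and visit tables are thinned with the same seed), emulating
missed study visits. MCAR is an explicit simplification: no informative
dropout.

### What real-data features the generator does NOT have

Within-class heterogeneity of curve *shape* (every subject in a class
shares b_g, c_g), relapses and treatment effects, non-Gaussian tails,
learning effects in the walk itself, and informative missingness. Passing
tests therefore certify the estimation machinery and the stated operating
characteristics under this idealized model, not performance on real
cohorts.

## Trajectory growth mixture model

K-class mixture of linear mixed models on the six baseline minute speeds,
with class-specific quadratic minute trends, a class-common covariate
effect (default BMI), a subject random intercept and i.i.d. residuals;
class membership is multinomial with intercept-only weights π.

*Estimation.* EM treating class label and random intercept as missing
data. E-step: responsibilities from the marginal 6-dimensional Gaussian
(compound-symmetric covariance, closed-form inverse/determinant) and
conditional moments of u_i per class. M-step: one joint weighted
least-squares solve for all class curves plus γ, then closed-form variance
updates; finally π is iterated to its fixed point so that at convergence
π_k equals the posterior column mean. Every step is an exact EM update, so
the marginal log-likelihood is non-decreasing — asserted on every test fit.

*Choices.* Random intercept only (6 observations per subject at baseline
keeps richer random effects weakly identified); BMI class-common
(adjustment, not a class discriminator); convergence when the relative
log-likelihood change < 1e-8, cap 6000 iterations; residual-variance floor
1e-6·Var(y) (flagged when hit); initialization by K-means on per-subject
OLS quadratic coefficients with near-hard (1−1e-4) initial
responsibilities — a soft start biases the first M-step's class means
toward each other and, in near-noiseless data, parks EM on a slow ridge
where the random intercepts absorb the misfit; jittered restarts (default
10, fewer in the Monte-Carlo studies where restarts rarely change the
selected optimum), best log-likelihood kept.

*Selection and stratification.* K = 1..K_max fits; BIC selects K (sample
size = number of subjects; AIC reported alongside). With K = 2, the class
with the lower mean model-implied speed over the six minutes is HRP;
subjects are assigned by posterior with ties (p = 0.5) to HRP, and exactly
equal class curves break to the lower class index.

## Confirmed disease progression

A follow-up visit is an event visit when EDSS rises ≥ 1.0 from a baseline
≤ 5.5 (or ≥ 0.5 from ≥ 6.0 — the 0.5 grid makes the branches exhaustive),
or T25FW or 9HPT worsens ≥ 20% (inclusive thresholds, with a 1e-9 relative
guard so an exact 20% worsening counts despite float rounding). CDP is
confirmed on event visits at ≥ 2 of the 4 follow-ups, or any single
terminal visit (18/24 months). The two-of-four clause counts event
*visits*, not repeated events on the same measure — published EDSS-plus
variants differ here, so this reading is stated prominently. A single 9HPT
column is used (no hand laterality). Missing components yield missing (not
negative) flags via three-valued logic; missing visits contribute nothing.

## Longitudinal mixed models

The gait model (all visits, minute-level speed) has fixed effects
group (HC reference) + minute + minute² + visit + BMI + group×minute +
group×minute² + group×visit, subject random intercept, ML estimation (not
REML, keeping likelihoods comparable with the mixture module),
normal-approximation Wald CIs and p-values, complete-case rows. Minute and
visit enter as continuous covariates. Age, sex and smoking are generated
but not modelled, mirroring the final published model in which only BMI
remained.

Change-from-baseline models per outcome are linear in visit with
group×visit interactions and subject random intercepts; the 2-year change
for a group is 4 × its visit slope, with Wald CIs from the coefficient
covariance. EDSS and MSIS-29 are modelled on MS groups only (LRP
reference). All outcome×group tests form a single Benjamini–Hochberg FDR
family (boundary configurable); marginal (fixed-effects-only) predictions
are used for any plotted trajectories.

## Benchmarking against CDP

Positive = predicted HRP, truth = CDP-confirmed. Accuracy/PPV/NPV/
sensitivity/specificity carry Wilson 95% CIs; AUROC is the Mann-Whitney
statistic (ties ½) with a DeLong CI. The mixture's ROC score is the
posterior HRP probability; K-means baselines (two clusters on standardized
features; the cluster with worse walking performance — lower total
distance, else higher T25FW, else higher EDSS — labelled HRP) use the
signed projection on the inter-centroid axis, a choice documented here
because hard clusterings have no canonical score. K-means features are
complete-case.

## Pipeline

`gaitmix run` executes simulate → stratify → CDP → LME → evaluate; each
stage reads and writes only files, one global seed derives per-stage seeds
via SHA-256("seed:stage") mod 2³¹, and the manifest hashes every artifact
so a rerun is byte-identical. The GMM stage aborts when BIC does not
support two classes, since the high/low-risk split is undefined otherwise
(this is how a cohort with no high-risk stratum, e.g. n_hrp = 0, is
rejected). Optional figures are off by default.

## What the simulations show — and an honest negative result

With the calibrated defaults, the *true-parameter* posterior classifier
separates the two classes with ≈ 92% accuracy. The *fitted* two-class
model at the study's n = 62 averages ≈ 84% permutation-optimal accuracy
over 100 simulated cohorts, and BIC prefers K = 1 on most such cohorts
(expected two-class log-likelihood gain ≈ 0–11 nats against a BIC penalty
of 4·ln 62 ≈ 16.5). This is a property of maximum likelihood at this
sample size, not of the optimizer: EM started *at the true parameters*
moves to higher-likelihood, lower-accuracy solutions in which class
separation is absorbed into an inflated random-intercept variance, while
at 10× the sample size the same code recovers the truth (accuracy 0.91,
σ_b² within 1%, π within 0.01). In short: when the between-class gap is
~2 within-class SDs, n = 62 is not enough for a trajectory mixture to
reliably certify two classes, and the package reports that honestly rather
than simulating from a more separated world.

## Problem sizes used

The Monte-Carlo studies use 100 cohorts × 62 subjects (classification
validity; 5 EM restarts each) and 50 replicates × 200 subjects × 30
observations (parameter recovery); class-selection replicates use K ≤ 3
and 3 restarts. These sizes give Monte-Carlo SEs of ≈ 2% (accuracy) and
≈ 0.8 ft/min (group offsets).
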