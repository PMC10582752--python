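# gaitmix

Progression-risk stratification for multiple sclerosis (MS) from the
six-minute walk (6MW) gait-speed trajectory.

MS disease progression is heterogeneous and hard to predict from baseline
clinical variables. One physiological signature that *is* visible at
baseline is the shape of the minute-by-minute gait-speed curve within a
single 6MW: most walkers slow mid-walk and speed up near the end (a "U"
shape), while patients at higher risk of progression walk slower and show a
"flattened" curve with no terminal acceleration. `gaitmix` implements, end
to end and on fully synthetic data, the analysis that turns this signature
into a risk stratification:

1. **simulate** a two-year observational cohort (62 MS + 41 healthy
   controls, 5 visits at 6-month spacing, 6 minute-level gait speeds per
   walk, clinical and patient-reported outcomes, visit-level missingness);
2. **cluster** the baseline gait-speed trajectories with a growth mixture
   model (GMM) and stratify MS subjects into low-/high-risk progressors
   (LRP/HRP) by posterior probability;
3. **score** two-year confirmed disease progression (CDP) with a composite
   EDSS-plus rule;
4. **model** the longitudinal outcomes with linear mixed-effects models and
   Benjamini–Hochberg FDR correction;
5. **benchmark** the stratification against CDP (AUROC, accuracy, PPV, NPV,
   sensitivity, specificity) alongside two-cluster K-means baselines.

## The model

For subject *i* with baseline minute speeds `y_i = (y_i0 … y_i5)` (feet/min)
the GMM is a K-class mixture of linear mixed models,

    y_i | class k ~ N₆( Xβ_k + γ·BMI_i·1 , σ_b²·11ᵀ + σ_ε²·I ),
    X = [1, t, t²],   P(class k) = π_k,

fitted by maximum likelihood with an EM algorithm that treats both the
class label and the subject random intercept as missing data (all updates
closed-form; the marginal log-likelihood is non-decreasing by
construction). K is selected by BIC; with K = 2 the class with the lower
model-implied mean speed is the HRP stratum.

The longitudinal gait model (all visits *j*, groups HC/LRP/HRP, HC
reference) is

    speed ~ group + t + t² + j + BMI + group×t + group×t² + group×j
            + (1 | subject),

estimated by ML via `statsmodels` MixedLM, with Wald intervals.

CDP is confirmed when a worsening event — EDSS +1.0 from a baseline ≤ 5.5
(or +0.5 from ≥ 6.0), or a ≥ 20% increase in T25FW or 9HPT — occurs at any
two of the four follow-up visits, or at a single terminal visit (18 or
24 months).

## Worked example

The numbered scripts under `analysis/` run the study in order and write
their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py --seed 13
python analysis/02_fit_trajectory_gmm.py --seed 13
python analysis/03_score_progression.py
python analysis/04_longitudinal_models.py
python analysis/05_benchmark_stratification.py --seed 13
```

`02_fit_trajectory_gmm.py` prints, for this seed:

```
K   loglik      AIC        BIC   converged
1    -1531.5    3074.9    3087.7   True
2    -1514.3    3048.5    3069.8   True
3    -1510.2    3048.5    3078.2   True
BIC-selected number of latent classes: 2

two-class stratification: {'LRP': 43, 'HRP': 19} -> results/strata.csv
agreement with simulation truth: 0.90
```

i.e. BIC prefers two latent trajectory classes, and the posterior
stratification labels 19 of 62 MS subjects HRP, agreeing with the simulated
class for 90% of subjects. `03_score_progression.py` then reports 19/62
CDP-confirmed progressors (31% prevalence; 67% of the simulated HRP group
vs 19% of LRP), `04_longitudinal_models.py` prints the fixed-effect table
of the gait model (here HRP subjects walk ~110 ft/min slower than HC at
baseline and lose a net ~3.9 ft/min per visit while HC gain ~2.7) and the
FDR-significant outcome changes (T25FW and 9HPT worsen only in HRP; the
SDMT practice effect appears in HC and LRP but not HRP), and
`05_benchmark_stratification.py` prints the method × metric comparison
against CDP (for this seed the trajectory stratification reaches accuracy
0.74, sensitivity 0.58, NPV 0.81, AUROC 0.69).

The same five stages can be run as one seeded, manifest-hashed pipeline:

```sh
gaitmix run --out results/run --seed 13
```

`analysis/06_simulation_studies.py` runs the two Monte-Carlo studies
(classification validity of the mixture at the study's sample size, and
parameter recovery of the longitudinal model).

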