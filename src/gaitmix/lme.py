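"""Longitudinal linear mixed-effects models for gait speed and outcomes.

The gait model regresses minute-level 6MW speed (feet/min) on risk group
(HC reference; LRP/HRP dummies), minute-time (linear + quadratic), visit
(linear), BMI, and group interactions with the time and visit terms, with a
subject random intercept:

    speed ~ LRP + HRP + t + t^2 + j + BMI
            + LRP:t + HRP:t + LRP:t^2 + HRP:t^2 + LRP:j + HRP:j
            + (1 | subject)

fitted by maximum likelihood (not REML, so log-likelihoods are comparable
across mean structures); inference is Wald/normal.  Minute and visit both
enter as continuous covariates, and rows with any missing field are dropped
(complete-case analysis).

The change-from-baseline models per clinical/PRO outcome are linear in
visit with group-by-visit interactions; the 2-year change for a group is
4 x (that group's visit slope).  The family of group x outcome tests is
corrected with Benjamini-Hochberg false-discovery-rate adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import MS_ONLY_OUTCOMES, OUTCOME_COLUMNS

GAIT_TERMS = (
    "Intercept", "LRP", "HRP", "Time", "Time2", "Visit", "BMI",
    "LRP:Time", "HRP:Time", "LRP:Time2", "HRP:Time2",
    "LRP:Visit", "HRP:Visit",
)

_FORMULA_MAP = {
    "Intercept": "Intercept", "LRP": "lrp", "HRP": "hrp",
    "Time": "minute", "Time2": "minute2", "Visit": "visit", "BMI": "bmi",
    "LRP:Time": "lrp:minute", "HRP:Time": "hrp:minute",
    "LRP:Time2": "lrp:minute2", "HRP:Time2": "hrp:minute2",
    "LRP:Visit": "lrp:visit", "HRP:Visit": "hrp:visit",
}


class LMEError(ValueError):
    pass


@dataclass
class LMEFit:
    """Fixed-effect table plus variance components of a fitted mixed model."""

    fixed: pd.DataFrame  # index term; columns estimate, ci_low, ci_high, p
    sigma_b2: float
    sigma_e2: float
    loglik: float
    n_obs: int
    n_subjects: int

    def to_dict(self) -> dict:
        return {
            "fixed_effects": {
                term: {k: float(v) for k, v in row.items()}
                for term, row in self.fixed.iterrows()
            },
            "sigma_b2": float(self.sigma_b2),
            "sigma_e2": float(self.sigma_e2),
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "n_subjects": int(self.n_subjects),
        }


def _group_labels(subjects: pd.DataFrame,
                  strata: pd.DataFrame | None) -> pd.Series:
    """Per-subject group label HC / LRP / HRP.

    MS subjects take their stratification label when ``strata`` is given,
    otherwise their simulated true class.
    """
    lab = pd.Series("HC", index=subjects["subject_id"].to_numpy(),
                    dtype=object)
    ms = subjects["cohort"] == "MS"
    if strata is not None:
        m = strata.set_index("subject_id")["label"]
        lab.loc[subjects.loc[ms, "subject_id"]] = m.reindex(
            subjects.loc[ms, "subject_id"]).to_numpy()
    else:
        lab.loc[subjects.loc[ms, "subject_id"]] = subjects.loc[
            ms, "true_class"].to_numpy()
    if lab.isna().any():
        raise LMEError(
            f"MS subjects without a risk label: "
            f"{sorted(lab.index[lab.isna()])}")
    return lab


def _wald_table(result, terms: dict[str, str]) -> pd.DataFrame:
    ci = result.conf_int()
    rows = {}
    for name, key in terms.items():
        rows[name] = {
            "estimate": float(result.fe_params[key]),
            "ci_low": float(ci.loc[key, 0]),
            "ci_high": float(ci.loc[key, 1]),
            "p": float(result.pvalues[key]),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def fit_gait_lme(
    gait: pd.DataFrame,
    subjects: pd.DataFrame,
    strata: pd.DataFrame | None = None,
) -> LMEFit:
    """Fit the full longitudinal gait-speed model (all visits, all groups)."""
    lab = _group_labels(subjects, strata)
    df = gait.merge(subjects[["subject_id", "bmi"]], on="subject_id")
    df["group"] = lab.reindex(df["subject_id"]).to_numpy()
    df = df.dropna(subset=["speed_ft_min", "bmi", "group"]).copy()
    counts = df.groupby("group")["subject_id"].nunique()
    for g in ("HC", "LRP", "HRP"):
        if counts.get(g, 0) < 2:
            raise LMEError(f"group {g} has fewer than 2 subjects")
    df["lrp"] = (df["group"] == "LRP").astype(float)
    df["hrp"] = (df["group"] == "HRP").astype(float)
    df["minute"] = df["minute"].astype(float)
    df["minute2"] = df["minute"] ** 2
    df["visit"] = df["visit"].astype(float)
    df = df.rename(columns={"speed_ft_min": "speed"})

    formula = ("speed ~ lrp + hrp + minute + minute2 + visit + bmi"
               " + lrp:minute + hrp:minute + lrp:minute2 + hrp:minute2"
               " + lrp:visit + hrp:visit")
    model = smf.mixedlm(formula, df, groups=df["subject_id"])
    exog = np.asarray(model.exog)
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # report the columns whose removal restores full rank
        collinear = [
            name for i, name in enumerate(model.exog_names)
            if np.linalg.matrix_rank(np.delete(exog, i, axis=1)) == rank
        ]
        raise LMEError(f"rank-deficient design; collinear columns {collinear}")
    result = model.fit(reml=False, method="lbfgs", maxiter=500)
    fixed = _wald_table(result, _FORMULA_MAP)
    return LMEFit(
        fixed=fixed,
        sigma_b2=float(result.cov_re.iloc[0, 0]),
        sigma_e2=float(result.scale),
        loglik=float(result.llf),
        n_obs=int(len(df)),
        n_subjects=int(df["subject_id"].nunique()),
    )


@dataclass
class OutcomeChange:
    """Model-implied 2-year (visit-4) change from baseline for one group."""

    outcome: str
    group: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float


def fit_outcome_lme(
    outcome: str,
    visits: pd.DataFrame,
    subjects: pd.DataFrame,
    strata: pd.DataFrame | None = None,
) -> list[OutcomeChange]:
    """Linear-in-visit mixed model for one outcome; per-group 2-year change.

    EDSS and MSIS-29 are administered to MS participants only, so their
    models include LRP/HRP with LRP as reference; all other outcomes span
    the three groups with HC as reference.  The change from baseline at the
    final visit for group g is 4 x slope_g where slope_g is the group's
    visit slope (visit main effect plus the group interaction); Wald CIs and
    p-values follow from the fixed-effect covariance.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise LMEError(f"unknown outcome {outcome!r}; "
                       f"expected one of {OUTCOME_COLUMNS}")
    lab = _group_labels(subjects, strata)
    df = visits[["subject_id", "visit", outcome]].copy()
    df["group"] = lab.reindex(df["subject_id"]).to_numpy()
    ms_only = outcome in MS_ONLY_OUTCOMES
    if ms_only:
        df = df[df["group"].isin(("LRP", "HRP"))]
    df = df.dropna(subset=[outcome, "group"]).rename(columns={outcome: "y"})
    if df.empty:
        raise LMEError(f"outcome {outcome}: no observed values")
    df["visit"] = df["visit"].astype(float)
    df["hrp"] = (df["group"] == "HRP").astype(float)
    if ms_only:
        formula = "y ~ hrp + visit + hrp:visit"
        groups = ("LRP", "HRP")
        slope_terms = {"LRP": ["visit"], "HRP": ["visit", "hrp:visit"]}
    else:
        df["lrp"] = (df["group"] == "LRP").astype(float)
        formula = "y ~ lrp + hrp + visit + lrp:visit + hrp:visit"
        groups = ("HC", "LRP", "HRP")
        slope_terms = {"HC": ["visit"], "LRP": ["visit", "lrp:visit"],
                       "HRP": ["visit", "hrp:visit"]}

    model = smf.mixedlm(formula, df, groups=df["subject_id"])
    result = model.fit(reml=False, method="lbfgs", maxiter=500)
    params = result.fe_params
    cov = result.cov_params().loc[params.index, params.index]
    out = []
    final_visit = 4.0
    for g in groups:
        c = pd.Series(0.0, index=params.index)
        for term in slope_terms[g]:
            c[term] = final_visit
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        z = est / se if se > 0 else np.nan
        p = float(2 * stats.norm.sf(abs(z))) if se > 0 else np.nan
        out.append(OutcomeChange(
            outcome=outcome, group=g, estimate=est,
            ci_low=est - 1.959963984540054 * se,
            ci_high=est + 1.959963984540054 * se, p=p))
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise LMEError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise LMEError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def outcome_test_family(
    visits: pd.DataFrame,
    subjects: pd.DataFrame,
    strata: pd.DataFrame | None = None,
    outcomes: tuple[str, ...] = OUTCOME_COLUMNS,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Change-from-baseline tests across outcomes x groups, BH-corrected.

    All tests form one FDR family.  Returns a tidy table with raw and
    adjusted p-values and a significance flag at ``fdr_level``.
    """
    rows = []
    for outcome in outcomes:
        try:
            changes = fit_outcome_lme(outcome, visits, subjects, strata)
        except LMEError:
            continue
        for ch in changes:
            rows.append({
                "outcome": ch.outcome, "group": ch.group,
                "change": ch.estimate, "ci_low": ch.ci_low,
                "ci_high": ch.ci_high, "p_raw": ch.p,
            })
    table = pd.DataFrame(rows)
    if table.empty:
        raise LMEError("no outcome could be modelled")
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_adj"] < fdr_level
    return table
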