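"""Synthetic two-year MS / healthy-control cohort generator.

Emulates the structure of a prospective observational study in which 62
multiple-sclerosis (MS) participants and 41 healthy controls (HC) perform a
six-minute walk (6MW) every 6 months for 2 years (visits 0..4), with gait
speed recorded minute by minute (minutes 0..5, feet/min), alongside clinical
outcomes (EDSS, T25FW, 9HPT, SDMT, PASAT, accelerometer activity) and
patient-reported outcomes (SF-36, MSIS-29, MFIS, FSS).

The MS cohort is a two-class mixture: "low risk progressors" (LRP) with a
faster, U-shaped within-walk speed profile, and "high risk progressors" (HRP)
with a slower, flattened profile and genuine longitudinal worsening.  Each
group's within-walk mean curve is a quadratic in minute; gait speed for
subject i at visit j, minute t is

    y_ijt = a_g + b_g t + c_g t^2 + s_g j + gamma_bmi (BMI_i - BMI_ref)
            + u_i + e_ijt,
    u_i ~ N(0, sd_random_intercept^2),  e_ijt ~ N(0, sd_residual^2).

Default curve coefficients are solved so that the group means of minute-0
speed, minute-5 speed and 6MW total distance match the published cohort
descriptives (HC 357/351 ft/min, 2080 ft; LRP 317/313, 1860; HRP 245/234,
1420).  Clinical/PRO outcomes follow a linear-in-visit drift model with
subject-level drift heterogeneity; by default only the HRP group worsens.

Missingness of follow-up visits is missing-completely-at-random with
visit-specific rates (default 7/15/16/21% at visits 1..4); the baseline visit
is never removed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("HC", "LRP", "HRP")
MS_GROUPS = ("LRP", "HRP")
N_MINUTES = 6
N_VISITS = 5
MINUTES = np.arange(N_MINUTES, dtype=float)
FOLLOWUP_VISITS = (1, 2, 3, 4)

OUTCOME_COLUMNS = (
    "edss", "t25fw", "hpt9", "sdmt", "pasat",
    "activity", "sf36", "msis29", "mfis", "fss",
)
#: outcomes administered to MS participants only
MS_ONLY_OUTCOMES = ("edss", "msis29")

SUBJECT_COLUMNS = (
    "subject_id", "cohort", "true_class", "age", "sex", "bmi",
    "smoking", "disease_duration", "ms_type",
)
GAIT_COLUMNS = ("subject_id", "visit", "minute", "speed_ft_min")
VISIT_COLUMNS = ("subject_id", "visit") + OUTCOME_COLUMNS


class CohortConfigError(ValueError):
    """Raised for invalid generator configurations."""


class CohortParseError(ValueError):
    """Raised when a cohort CSV violates the schema or an invariant."""


@dataclass(frozen=True)
class GroupCurve:
    """Quadratic within-walk mean curve plus a linear visit slope.

    Units: intercept feet/min, linear feet/min per minute, quadratic
    feet/min per minute^2, visit_slope feet/min per visit (6 months).
    """

    intercept: float
    linear: float
    quadratic: float
    visit_slope: float

    def mean_speeds(self, visit: int = 0) -> np.ndarray:
        """Group mean speed at each of the six minutes of a given visit."""
        return (self.intercept + self.linear * MINUTES
                + self.quadratic * MINUTES ** 2 + self.visit_slope * visit)


@dataclass(frozen=True)
class OutcomeModel:
    """Linear-drift generative model for one clinical/PRO outcome.

    value_ij = baseline_i + drift_i * j + noise, with baseline_i drawn from
    the group's (mean, sd) and drift_i ~ N(drift[g], drift_sd[g]).
    ``baseline`` maps group -> (mean, sd) or None when the outcome is not
    administered to that group (e.g. EDSS for healthy controls).
    """

    baseline: Mapping[str, tuple[float, float] | None]
    drift: Mapping[str, float]
    drift_sd: Mapping[str, float]
    resid_sd: float
    lower: float | None = None
    upper: float | None = None


def _default_curves() -> dict[str, GroupCurve]:
    # Quadratics solved from the printed group means of minute-0 speed,
    # minute-5 speed and total distance; visit slopes from the longitudinal
    # model (HC +2.18, LRP +0.30, HRP -5.14 ft/min per visit).
    return {
        "HC": GroupCurve(357.0, -12.2, 2.2, 2.18),
        "LRP": GroupCurve(317.0, -8.3, 1.5, 0.30),
        "HRP": GroupCurve(245.0, -6.45, 0.85, -5.14),
    }


def _default_covariates() -> dict[str, dict]:
    return {
        "HC": {"age": (34.7, 12.0), "bmi": (25.6, 5.49), "female": 0.707,
               "smoking": (2.0, 5.0), "duration": None, "ms_type": None},
        "LRP": {"age": (40.7, 8.97), "bmi": (28.2, 5.11), "female": 0.766,
                "smoking": (3.45, 6.77), "duration": (12.6, 5.83),
                "ms_type": {"RR": 0.915, "PP": 0.043, "SP": 0.042}},
        "HRP": {"age": (44.5, 8.18), "bmi": (25.4, 4.99), "female": 0.80,
                "smoking": (8.27, 15.6), "duration": (17.5, 8.42),
                "ms_type": {"RR": 0.867, "PP": 0.133, "SP": 0.0}},
    }


def _default_outcomes() -> dict[str, OutcomeModel]:
    def om(hc, lrp, hrp, drift, drift_sd, resid, lower=None, upper=None):
        return OutcomeModel(
            baseline={"HC": hc, "LRP": lrp, "HRP": hrp},
            drift=dict(zip(GROUPS, drift)),
            drift_sd=dict(zip(GROUPS, drift_sd)),
            resid_sd=resid, lower=lower, upper=upper,
        )

    return {
        # EDSS is stable by design: over two years it is an insensitive
        # progression measure in a mild-to-moderate cohort.
        "edss": om(None, (2.30, 0.78), (3.13, 0.67),
                   (0.0, 0.0, 0.0), (0.0, 0.0, 0.0), 0.30,
                   lower=0.0, upper=10.0),
        # Walking / hand-function times (seconds; larger = worse).  Only the
        # HRP group drifts upward; the drift SD puts roughly half of HRP
        # subjects past a 20% relative worsening by the later visits.
        "t25fw": om((3.8, 0.5), (4.04, 0.732), (5.41, 1.09),
                    (0.0, 0.0, 0.25), (0.0, 0.0, 0.15), 0.30, lower=1.0),
        "hpt9": om((18.5, 3.0), (20.2, 4.73), (24.6, 5.45),
                   (0.0, 0.0, 1.0), (0.0, 0.0, 0.5), 1.0, lower=5.0),
        # Cognitive tests (higher = better); SDMT carries a practice
        # ("learning") effect that is attenuated in HRP.
        "sdmt": om((60.0, 10.0), (56.9, 13.7), (44.3, 12.0),
                   (1.2, 1.0, 0.1), (0.3, 0.3, 0.3), 3.0, lower=0.0),
        "pasat": om((53.0, 8.0), (51.9, 9.03), (45.8, 10.5),
                    (0.5, 0.3, -0.3), (0.2, 0.2, 0.2), 3.0,
                    lower=0.0, upper=60.0),
        # 7-day accelerometer counts (see CohortConfig.activity_period).
        "activity": om((298e3, 153e3), (210e3, 110e3), (160e3, 90e3),
                       (0.0, -5e3, -10e3), (0.0, 2e3, 2e3), 30e3, lower=0.0),
        "sf36": om((105.0, 5.0), (102.0, 6.10), (99.9, 7.29),
                   (0.0, 0.0, -1.0), (0.0, 0.0, 0.4), 2.0, lower=0.0),
        "msis29": om(None, (49.4, 19.4), (61.0, 26.1),
                     (0.0, 0.0, 2.0), (0.0, 0.0, 0.8), 5.0, lower=29.0),
        "mfis": om((15.0, 10.0), (28.9, 18.2), (42.0, 15.5),
                   (0.0, 0.0, 1.5), (0.0, 0.0, 0.6), 4.0, lower=0.0),
        "fss": om((14.0, 8.0), (20.5, 10.6), (30.1, 7.53),
                  (0.0, 0.0, 1.2), (0.0, 0.0, 0.5), 3.0, lower=9.0),
    }


@dataclass
class CohortConfig:
    """Full generative configuration for one synthetic cohort.

    ``bmi_reference`` controls centering of the BMI effect in the gait mean
    structure: a float centers every subject at that value; None (default)
    centers each subject at their own group's configured mean BMI, so the
    group mean curves are reproduced exactly in expectation.
    """

    n_hc: int = 41
    n_lrp: int = 47
    n_hrp: int = 15
    curves: dict[str, GroupCurve] = field(default_factory=_default_curves)
    bmi_effect: float = -3.65
    bmi_reference: float | None = None
    sd_random_intercept: float = 35.0
    sd_residual: float = 10.0
    covariates: dict[str, dict] = field(default_factory=_default_covariates)
    outcomes: dict[str, OutcomeModel] = field(default_factory=_default_outcomes)
    missingness: tuple[float, float, float, float] = (0.07, 0.15, 0.16, 0.21)
    activity_period: str = "week"  # "week" (7-day totals) or "day"
    seed: int = 0

    def group_sizes(self) -> dict[str, int]:
        return {"HC": self.n_hc, "LRP": self.n_lrp, "HRP": self.n_hrp}

    def validate(self) -> None:
        for name, n in self.group_sizes().items():
            if n < 0:
                raise CohortConfigError(f"negative group size for {name}: {n}")
        if self.n_hc + self.n_lrp + self.n_hrp == 0:
            raise CohortConfigError("empty cohort: all group sizes are zero")
        if self.sd_random_intercept < 0 or self.sd_residual < 0:
            raise CohortConfigError("variance-component SDs must be >= 0")
        if len(self.missingness) != len(FOLLOWUP_VISITS):
            raise CohortConfigError("missingness needs one rate per follow-up visit")
        for r in self.missingness:
            if not 0.0 <= r <= 1.0:
                raise CohortConfigError(f"missingness rate {r} outside [0, 1]")
        if self.activity_period not in ("week", "day"):
            raise CohortConfigError("activity_period must be 'week' or 'day'")
        for g in GROUPS:
            if g not in self.curves:
                raise CohortConfigError(f"missing mean curve for group {g}")
        for name, om in self.outcomes.items():
            if om.resid_sd < 0:
                raise CohortConfigError(f"{name}: negative residual SD")
            for g in GROUPS:
                base = om.baseline.get(g)
                if base is not None and base[1] < 0:
                    raise CohortConfigError(f"{name}/{g}: negative baseline SD")
                if om.drift_sd.get(g, 0.0) < 0:
                    raise CohortConfigError(f"{name}/{g}: negative drift SD")

    @classmethod
    def longitudinal_truth(
        cls,
        n_hc: int = 80,
        n_lrp: int = 90,
        n_hrp: int = 30,
        seed: int = 0,
    ) -> "CohortConfig":
        """Config whose gait mean structure equals the published longitudinal
        model's fixed effects, for parameter-recovery experiments.

        The HC curve is (347.65, -9.74, 1.84) with visit slope 2.18; LRP and
        HRP curves add the group offsets (-23.48 / -105.63 on the intercept,
        +0.01 / +1.56 on the linear term, -0.27 / -0.70 on the quadratic,
        -1.88 / -7.32 on the visit slope).  BMI ~ N(27, 5) identically in all
        groups with effect -3.65 ft/min per kg/m^2 centered at 27.
        """
        curves = {
            "HC": GroupCurve(347.65, -9.74, 1.84, 2.18),
            "LRP": GroupCurve(347.65 - 23.48, -9.74 + 0.01,
                              1.84 - 0.27, 2.18 - 1.88),
            "HRP": GroupCurve(347.65 - 105.63, -9.74 + 1.56,
                              1.84 - 0.70, 2.18 - 7.32),
        }
        cov = _default_covariates()
        for g in GROUPS:
            cov[g]["bmi"] = (27.0, 5.0)
        return cls(n_hc=n_hc, n_lrp=n_lrp, n_hrp=n_hrp, curves=curves,
                   covariates=cov, bmi_reference=27.0,
                   missingness=(0.0, 0.0, 0.0, 0.0), seed=seed)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int,
               lo: float | None = None, hi: float | None = None) -> np.ndarray:
    x = rng.normal(mean, sd, size=size)
    if lo is not None or hi is not None:
        x = np.clip(x, lo, hi)
    return x


def _snap_edss(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(x * 2.0) / 2.0, 0.0, 10.0)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one complete cohort (no missingness applied).

    Returns (subjects, gait, visits):
      subjects: one row per subject with demographics and simulation truth;
      gait: one row per subject x visit x minute with speed in feet/min;
      visits: one row per subject x visit with clinical/PRO outcomes.

    Fully deterministic given ``config`` (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sub_rows = []
    sid = 0
    for group in GROUPS:
        n = config.group_sizes()[group]
        if n == 0:
            continue
        cov = config.covariates[group]
        age = _truncnorm(rng, *cov["age"], n, 18.0, 64.0)
        bmi = _truncnorm(rng, *cov["bmi"], n, 16.0, 40.0)
        female = rng.random(n) < cov["female"]
        smoking = _truncnorm(rng, *cov["smoking"], n, 0.0, None)
        if cov["duration"] is not None:
            duration = _truncnorm(rng, *cov["duration"], n, 0.0, None)
        else:
            duration = np.full(n, np.nan)
        if cov["ms_type"] is not None:
            types = list(cov["ms_type"])
            probs = np.array([cov["ms_type"][t] for t in types], dtype=float)
            probs = probs / probs.sum()
            ms_type = rng.choice(types, size=n, p=probs)
        else:
            ms_type = np.full(n, "NA", dtype=object)
        for i in range(n):
            sub_rows.append({
                "subject_id": f"S{sid:04d}",
                "cohort": "HC" if group == "HC" else "MS",
                "true_class": "NA" if group == "HC" else group,
                "age": age[i],
                "sex": "F" if female[i] else "M",
                "bmi": bmi[i],
                "smoking": smoking[i],
                "disease_duration": duration[i],
                "ms_type": str(ms_type[i]),
            })
            sid += 1
    subjects = pd.DataFrame(sub_rows, columns=list(SUBJECT_COLUMNS))

    group_of = {
        row.subject_id: (row.true_class if row.cohort == "MS" else "HC")
        for row in subjects.itertuples()
    }
    bmi_of = dict(zip(subjects.subject_id, subjects.bmi))

    # gait speeds
    gait_rows = []
    for sid_, g in group_of.items():
        curve = config.curves[g]
        ref = (config.bmi_reference if config.bmi_reference is not None
               else config.covariates[g]["bmi"][0])
        bmi_adj = config.bmi_effect * (bmi_of[sid_] - ref)
        u = rng.normal(0.0, config.sd_random_intercept)
        for j in range(N_VISITS):
            mean = curve.mean_speeds(j) + bmi_adj + u
            eps = rng.normal(0.0, config.sd_residual, size=N_MINUTES)
            speeds = mean + eps
            speeds = np.where(speeds <= 0, 1e-6, speeds)
            for t in range(N_MINUTES):
                gait_rows.append((sid_, j, t, speeds[t]))
    gait = pd.DataFrame(gait_rows, columns=list(GAIT_COLUMNS))

    # clinical / PRO outcomes
    visit_rows = {
        (sid_, j): {"subject_id": sid_, "visit": j}
        for sid_ in group_of for j in range(N_VISITS)
    }
    for name, om in config.outcomes.items():
        for sid_, g in group_of.items():
            base = om.baseline.get(g)
            if base is None:
                for j in range(N_VISITS):
                    visit_rows[(sid_, j)][name] = np.nan
                continue
            b0 = rng.normal(*base)
            drift = rng.normal(om.drift.get(g, 0.0), om.drift_sd.get(g, 0.0))
            vals = b0 + drift * np.arange(N_VISITS) \
                + rng.normal(0.0, om.resid_sd, size=N_VISITS)
            if name == "edss":
                vals = _snap_edss(vals)
            else:
                vals = np.clip(vals, om.lower, om.upper)
            if name == "activity" and config.activity_period == "day":
                vals = vals / 7.0
            for j in range(N_VISITS):
                visit_rows[(sid_, j)][name] = vals[j]
    visits = pd.DataFrame(list(visit_rows.values()), columns=list(VISIT_COLUMNS))

    return subjects, gait, visits


def apply_missingness(
    table: pd.DataFrame,
    rates: Sequence[float],
    seed: int,
) -> pd.DataFrame:
    """Remove whole follow-up visits completely at random.

    ``rates`` gives the drop probability for visits 1..4; the baseline visit
    is never removed.  Every row of a dropped subject-visit disappears, so
    the same call works for the per-minute gait table and the per-visit
    outcome table; using the same seed for both drops the same visits,
    mimicking a missed study visit.  Deterministic given the seed.
    """
    rates = list(rates)
    if len(rates) != len(FOLLOWUP_VISITS):
        raise ValueError("need one missingness rate per follow-up visit")
    for r in rates:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"missingness rate {r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = (table[["subject_id", "visit"]].drop_duplicates()
             .sort_values(["subject_id", "visit"]))
    drop = set()
    for sid_, j in pairs.itertuples(index=False):
        if j == 0:
            continue
        if rng.random() < rates[int(j) - 1]:
            drop.add((sid_, int(j)))
    if not drop:
        return table.copy()
    keep = ~table.apply(
        lambda r: (r["subject_id"], int(r["visit"])) in drop, axis=1)
    return table.loc[keep].reset_index(drop=True)


_FILES = {"subjects": SUBJECT_COLUMNS, "gait": GAIT_COLUMNS,
          "visits": VISIT_COLUMNS}
_STR_COLS = {"subject_id", "cohort", "true_class", "sex", "ms_type"}
_INT_COLS = {"visit", "minute"}


def write_cohort(path: str | Path, subjects: pd.DataFrame,
                 gait: pd.DataFrame, visits: pd.DataFrame) -> None:
    """Write the three cohort tables as subjects/gait/visits.csv under path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in (("subjects", subjects), ("gait", gait),
                     ("visits", visits)):
        expected = list(_FILES[name])
        if list(df.columns) != expected:
            raise CohortParseError(
                f"{name} table columns {list(df.columns)} != {expected}")
        df.to_csv(path / f"{name}.csv", index=False)


def _read_table(path: Path, name: str) -> pd.DataFrame:
    expected = list(_FILES[name])
    try:
        # only empty fields are missing ("NA" is a legitimate category level)
        df = pd.read_csv(path, dtype={c: "string" for c in _STR_COLS},
                         keep_default_na=False, na_values=[""],
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise CohortParseError(f"{path}: {exc}") from exc
    if list(df.columns) != expected:
        unknown = [c for c in df.columns if c not in expected]
        missing = [c for c in expected if c not in df.columns]
        raise CohortParseError(
            f"{path}: unknown columns {unknown}, missing columns {missing}")
    for c in df.columns:
        if c in _STR_COLS:
            df[c] = df[c].astype(object)
        elif c in _INT_COLS:
            df[c] = df[c].astype(np.int64)
        else:
            df[c] = df[c].astype(np.float64)
    return df


def _validate_cohort(subjects: pd.DataFrame, gait: pd.DataFrame,
                     visits: pd.DataFrame) -> None:
    edss = visits["edss"]
    off = edss.notna() & (np.abs(edss * 2 - np.round(edss * 2)) > 1e-9)
    if off.any():
        row = int(np.flatnonzero(off.to_numpy())[0])
        raise CohortParseError(
            f"visits row {row} (subject {visits.iloc[row]['subject_id']}, "
            f"visit {visits.iloc[row]['visit']}): EDSS {edss.iloc[row]} is "
            "not on the 0.5-point grid")
    bad_speed = gait["speed_ft_min"].notna() & (gait["speed_ft_min"] <= 0)
    if bad_speed.any():
        row = int(np.flatnonzero(bad_speed.to_numpy())[0])
        raise CohortParseError(f"gait row {row}: non-positive speed")
    for col in ("t25fw", "hpt9"):
        bad = visits[col].notna() & (visits[col] <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(f"visits row {row}: non-positive {col}")


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame,
                                           pd.DataFrame]:
    """Read and validate a cohort directory written by :func:`write_cohort`."""
    path = Path(path)
    subjects = _read_table(path / "subjects.csv", "subjects")
    gait = _read_table(path / "gait.csv", "gait")
    visits = _read_table(path / "visits.csv", "visits")
    _validate_cohort(subjects, gait, visits)
    return subjects, gait, visits


def total_distance(gait: pd.DataFrame) -> pd.DataFrame:
    """Per subject-visit 6MW total distance (feet): sum of minute speeds."""
    td = (gait.groupby(["subject_id", "visit"])["speed_ft_min"]
          .agg(["sum", "count"]).reset_index())
    td = td[td["count"] == N_MINUTES]
    return td.rename(columns={"sum": "total_distance_ft"})[
        ["subject_id", "visit", "total_distance_ft"]]
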