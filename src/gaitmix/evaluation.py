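"""Benchmarking risk stratifications against confirmed disease progression.

Each clustering method produces a hard HRP/LRP label and a continuous risk
score per MS subject; both are compared against the CDP verdict (positive =
CDP-confirmed progressor).  Reported metrics: confusion counts, accuracy,
PPV, NPV, sensitivity, specificity (Wilson 95% CIs) and AUROC (Mann-Whitney
with ties counted 1/2; DeLong 95% CI).

Baseline methods are two-cluster K-means over standardized baseline feature
sets; the cluster with the worse walking performance is labelled HRP and the
risk score is the signed projection onto the inter-centroid axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.proportion import proportion_confint

from .synthetic import N_MINUTES


class EvalError(ValueError):
    pass


FEATURE_SETS: dict[str, tuple[str, ...]] = {
    # total distance + first-minute speed + within-walk speed change + demographics
    "kmeans_6mw": ("six_mw_td", "six_mw_min1", "delta_6mw", "age", "bmi"),
    # MSFC component tests + demographics
    "kmeans_msfc": ("t25fw", "hpt9", "sdmt", "pasat", "age", "bmi"),
    # EDSS + demographics
    "kmeans_edss": ("age", "bmi", "edss"),
}


def compute_features(
    gait: pd.DataFrame,
    subjects: pd.DataFrame,
    visits: pd.DataFrame,
) -> pd.DataFrame:
    """Per-subject baseline feature table for the K-means baselines.

    six_mw_td = total 6MW distance (feet); six_mw_min1 = minute-0 speed;
    delta_6mw = minute-5 minus minute-0 speed.  Missing inputs propagate as
    missing features (an incomplete walk yields missing distance/delta).
    """
    ms = subjects[subjects["cohort"] == "MS"]
    base = gait[(gait["visit"] == 0)
                & gait["subject_id"].isin(ms["subject_id"])]
    wide = base.pivot(index="subject_id", columns="minute",
                      values="speed_ft_min")
    feats = pd.DataFrame(index=ms["subject_id"])
    complete = (wide.notna().sum(axis=1) == N_MINUTES) \
        if not wide.empty else pd.Series(dtype=bool)
    feats["six_mw_td"] = wide.sum(axis=1).where(complete)
    feats["six_mw_min1"] = wide[0] if 0 in wide.columns else np.nan
    if 0 in wide.columns and 5 in wide.columns:
        feats["delta_6mw"] = wide[5] - wide[0]
    else:
        feats["delta_6mw"] = np.nan
    feats["age"] = ms.set_index("subject_id")["age"]
    feats["bmi"] = ms.set_index("subject_id")["bmi"]
    vb = visits[visits["visit"] == 0].set_index("subject_id")
    for col in ("edss", "t25fw", "hpt9", "sdmt", "pasat"):
        feats[col] = vb[col].reindex(feats.index)
    return feats.reset_index()


@dataclass
class ClusterLabels:
    """Hard labels plus a continuous HRP-leaning score per subject."""

    table: pd.DataFrame  # subject_id, label, score
    degenerate: bool = False


def kmeans_baseline(
    features: pd.DataFrame,
    feature_set: str,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterLabels:
    """Two-cluster K-means risk stratification on a named feature set.

    Complete cases only; features are standardized to zero mean / unit
    variance.  The cluster with the worse walking performance (lower mean
    6MW total distance when in the set, else higher T25FW, else higher
    EDSS) is labelled HRP.  The score is the signed projection onto the
    centroid-difference axis, oriented so that higher = more HRP-like.
    """
    if feature_set not in FEATURE_SETS:
        raise EvalError(f"unknown feature set {feature_set!r}; "
                        f"expected one of {sorted(FEATURE_SETS)}")
    cols = list(FEATURE_SETS[feature_set])
    df = features[["subject_id"] + cols].dropna().reset_index(drop=True)
    if len(df) < 2:
        raise EvalError("fewer than 2 complete cases for clustering")
    X = df[cols].to_numpy(float)
    sd = X.std(axis=0)
    if np.all(sd == 0):
        return ClusterLabels(
            table=pd.DataFrame({"subject_id": df["subject_id"],
                                "label": pd.NA, "score": np.nan}),
            degenerate=True)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    centers = km.cluster_centers_

    def _mean_of(col):
        i = cols.index(col)
        return [Z[labels == c, i].mean() for c in (0, 1)]

    if "six_mw_td" in cols:
        m = _mean_of("six_mw_td")
        hrp_cluster = int(np.argmin(m))  # slower walkers
    elif "t25fw" in cols:
        hrp_cluster = int(np.argmax(_mean_of("t25fw")))
    elif "edss" in cols:
        hrp_cluster = int(np.argmax(_mean_of("edss")))
    else:
        raise EvalError("feature set has no walking-performance anchor")

    axis = centers[hrp_cluster] - centers[1 - hrp_cluster]
    norm = np.linalg.norm(axis)
    mid = centers.mean(axis=0)
    score = (Z - mid) @ (axis / norm) if norm > 0 else np.zeros(len(Z))
    out = pd.DataFrame({
        "subject_id": df["subject_id"],
        "label": np.where(labels == hrp_cluster, "HRP", "LRP"),
        "score": score,
    })
    return ClusterLabels(table=out)


def auroc_mann_whitney(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUROC as the normalized Mann-Whitney statistic (ties count 1/2)."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    pos, neg = scores[truth], scores[~truth]
    if len(pos) == 0 or len(neg) == 0:
        raise EvalError("AUROC needs at least one positive and one negative")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _delong_ci(scores, truth, level=0.95):
    """DeLong variance / CI of the empirical AUROC via placement values."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    pos, neg = scores[truth], scores[~truth]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n
                    for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m
                    for q in neg])
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = np.sqrt(var)
    z = stats.norm.ppf(0.5 + level / 2)
    return auc, max(auc - z * se, 0.0), min(auc + z * se, 1.0)


@dataclass
class EvalReport:
    """Confusion-matrix metrics and AUROC of one method vs CDP truth."""

    method: str
    tp: int
    fp: int
    fn: int
    tn: int
    prevalence: float
    metrics: pd.DataFrame  # index metric; columns estimate, ci_low, ci_high
    auroc: float | None
    auroc_ci: tuple[float, float] | None
    auroc_missing_reason: str | None = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "confusion": {"tp": self.tp, "fp": self.fp,
                          "fn": self.fn, "tn": self.tn},
            "prevalence": self.prevalence,
            "metrics": {m: {k: float(v) for k, v in row.items()}
                        for m, row in self.metrics.iterrows()},
        }
        if self.auroc is None:
            d["auroc"] = None
            d["auroc_missing_reason"] = self.auroc_missing_reason
        else:
            d["auroc"] = float(self.auroc)
            d["auroc_ci"] = [float(x) for x in self.auroc_ci]
        return d


def evaluate(
    predictions: pd.DataFrame,
    cdp: pd.DataFrame,
    method: str = "method",
) -> EvalReport:
    """Score predicted HRP labels (+ scores) against CDP verdicts.

    ``predictions`` must have subject_id, label (HRP/LRP) and score;
    ``cdp`` must have subject_id and confirmed.  Subjects are matched 1:1
    on subject_id; subjects missing from either side are dropped.
    """
    merged = predictions.merge(cdp[["subject_id", "confirmed"]],
                               on="subject_id").dropna(subset=["label"])
    if merged.empty:
        raise EvalError("no overlapping subjects between predictions and CDP")
    pred = (merged["label"] == "HRP").to_numpy()
    truth = merged["confirmed"].astype(bool).to_numpy()
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    n = tp + fp + fn + tn

    def _prop(k, m):
        if m == 0:
            return np.nan, np.nan, np.nan
        lo, hi = proportion_confint(k, m, alpha=0.05, method="wilson")
        return k / m, lo, hi

    rows = {
        "accuracy": _prop(tp + tn, n),
        "ppv": _prop(tp, tp + fp),
        "npv": _prop(tn, tn + fn),
        "sensitivity": _prop(tp, tp + fn),
        "specificity": _prop(tn, tn + fp),
    }
    metrics = pd.DataFrame.from_dict(
        rows, orient="index", columns=["estimate", "ci_low", "ci_high"])

    auroc = ci = reason = None
    if truth.all() or not truth.any():
        reason = "single-class truth: AUROC undefined"
    elif merged["score"].isna().any():
        reason = "missing scores"
    else:
        auroc, lo, hi = _delong_ci(merged["score"].to_numpy(), truth)
        ci = (lo, hi)
    return EvalReport(
        method=method, tp=tp, fp=fp, fn=fn, tn=tn,
        prevalence=float(truth.mean()), metrics=metrics,
        auroc=auroc, auroc_ci=ci, auroc_missing_reason=reason,
    )


def comparison_table(reports: list[EvalReport]) -> pd.DataFrame:
    """Method x metric comparison table (one row per clustering method)."""
    rows = []
    for r in reports:
        row = {"method": r.method,
               "auroc": r.auroc if r.auroc is not None else np.nan}
        for m in ("accuracy", "ppv", "npv", "sensitivity", "specificity"):
            row[m] = r.metrics.loc[m, "estimate"]
        rows.append(row)
    return pd.DataFrame(rows)
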