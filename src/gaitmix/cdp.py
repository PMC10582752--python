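"""Confirmed disease progression (CDP) from longitudinal clinical visits.

Implements a composite "EDSS-plus" progression rule over EDSS, T25FW and
9HPT.  A follow-up visit is an *event visit* when any of:

  * EDSS increased >= 1.0 point from a baseline of <= 5.5, or >= 0.5 point
    from a baseline of >= 6.0 (the EDSS grid has no values strictly between
    5.5 and 6.0, so the two branches are exhaustive);
  * T25FW time increased >= 20% from baseline;
  * 9HPT time increased >= 20% from baseline.

Progression is *confirmed* when event visits occur at any two of the four
follow-up visits, or at any single terminal visit (18 or 24 months, visits 3
and 4).  A criterion whose inputs are missing at a visit yields a missing
(not false) flag, and a missing visit contributes no events.

Note on the two-of-four clause: an event visit counts regardless of which
criterion fired, i.e. the two confirming visits need not worsen on the same
measure.  Published EDSS-plus variants differ on this point; this reading
treats progression as a visit-level state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FOLLOWUPS = (1, 2, 3, 4)


class CDPError(ValueError):
    pass


@dataclass(frozen=True)
class CDPRule:
    """Thresholds of the composite progression rule (all inclusive, >=)."""

    edss_step_low: float = 1.0    # required EDSS step when baseline <= pivot_low
    edss_step_high: float = 0.5   # required step when baseline >= pivot_high
    edss_pivot_low: float = 5.5
    edss_pivot_high: float = 6.0
    walk_pct: float = 0.20        # relative worsening for T25FW / 9HPT
    confirm_n: int = 2            # event visits needed among follow-ups
    terminal_visits: tuple[int, ...] = (3, 4)

    def __post_init__(self):
        if min(self.edss_step_low, self.edss_step_high, self.walk_pct) <= 0:
            raise CDPError("thresholds must be strictly positive")
        if not set(self.terminal_visits) <= set(FOLLOWUPS):
            raise CDPError("terminal visits must be follow-up visits (1-4)")


@dataclass
class CDPResult:
    """Per-subject progression verdict with per-visit event flags."""

    subject_id: str
    events: pd.DataFrame  # index: visit 1..4; columns edss/t25fw/hpt/any (object: bool or NaN)
    confirmed: bool
    qualifying_rule: str  # two_of_four | terminal_visit | none
    n_event_visits: int


def _check_edss_grid(value: float, where: str) -> None:
    if not np.isnan(value) and abs(value * 2 - round(value * 2)) > 1e-9:
        raise CDPError(f"{where}: EDSS {value} not on the 0.5-point grid")


def detect_events(baseline: pd.Series, followup: pd.Series,
                  rule: CDPRule = CDPRule()) -> dict:
    """Event flags for one follow-up visit against the subject's baseline.

    ``baseline`` / ``followup`` are visit rows with fields subject_id,
    visit, edss, t25fw, hpt9.  Each flag is True/False, or NaN when its
    inputs are missing.
    """
    if baseline["subject_id"] != followup["subject_id"]:
        raise CDPError(
            f"subject mismatch: {baseline['subject_id']} vs "
            f"{followup['subject_id']}")
    if int(baseline["visit"]) != 0:
        raise CDPError("baseline row must be visit 0")
    if int(followup["visit"]) not in FOLLOWUPS:
        raise CDPError("follow-up row must be visit 1-4")

    def _flag_edss():
        e0, ej = float(baseline["edss"]), float(followup["edss"])
        if np.isnan(e0) or np.isnan(ej):
            return np.nan
        _check_edss_grid(e0, f"{baseline['subject_id']} baseline")
        _check_edss_grid(ej, f"{followup['subject_id']} visit {followup['visit']}")
        if e0 <= rule.edss_pivot_low:
            return bool(ej - e0 >= rule.edss_step_low)
        return bool(ej - e0 >= rule.edss_step_high)

    def _flag_pct(col):
        v0, vj = float(baseline[col]), float(followup[col])
        if np.isnan(v0) or np.isnan(vj):
            return np.nan
        rel = (vj - v0) / v0
        # inclusive ">=" robust to float rounding at the exact threshold
        return bool(rel >= rule.walk_pct
                    or np.isclose(rel, rule.walk_pct, rtol=1e-9, atol=0.0))

    flags = {"edss_event": _flag_edss(),
             "t25fw_event": _flag_pct("t25fw"),
             "hpt_event": _flag_pct("hpt9")}
    # three-valued OR: True dominates, all-False gives False, else missing
    vals = [f for f in flags.values() if not _is_na(f)]
    if any(vals):
        flags["any_event"] = True
    elif len(vals) == 3:
        flags["any_event"] = False
    else:
        flags["any_event"] = np.nan
    return flags


def _is_na(x) -> bool:
    return isinstance(x, float) and np.isnan(x)


def confirm_cdp(events: pd.DataFrame, subject_id: str = "",
                rule: CDPRule = CDPRule()) -> CDPResult:
    """Progression verdict from per-visit event flags (visits 1..4).

    ``events`` is indexed by visit with an ``any_event`` column whose values
    are True/False/NaN; missing visits may be absent entirely.  The
    two-of-four clause takes precedence in ``qualifying_rule`` when both
    clauses hold.
    """
    def _truthy(x) -> bool:
        return (not _is_na(x)) and bool(x)

    any_event = {}
    for j in FOLLOWUPS:
        if j in events.index:
            any_event[j] = events.loc[j, "any_event"]
        else:
            any_event[j] = np.nan
    n_events = sum(1 for v in any_event.values() if _truthy(v))
    terminal = any(_truthy(any_event[j]) for j in rule.terminal_visits)
    if n_events >= rule.confirm_n:
        verdict, why = True, "two_of_four"
    elif terminal:
        verdict, why = True, "terminal_visit"
    else:
        verdict, why = False, "none"
    return CDPResult(subject_id=subject_id, events=events, confirmed=verdict,
                     qualifying_rule=why, n_event_visits=n_events)


def cdp_for_subject(visits: pd.DataFrame,
                    rule: CDPRule = CDPRule()) -> CDPResult:
    """CDP verdict for one subject's visit rows (must include visit 0)."""
    visits = visits.sort_values("visit")
    base = visits[visits["visit"] == 0]
    if base.empty:
        raise CDPError(
            f"subject {visits['subject_id'].iloc[0]} has no baseline visit")
    baseline = base.iloc[0]
    rows = {}
    for _, row in visits[visits["visit"] > 0].iterrows():
        rows[int(row["visit"])] = detect_events(baseline, row, rule)
    events = pd.DataFrame.from_dict(rows, orient="index")
    if events.empty:
        events = pd.DataFrame(
            columns=["edss_event", "t25fw_event", "hpt_event", "any_event"])
    return confirm_cdp(events, str(baseline["subject_id"]), rule)


def cdp_table(visits: pd.DataFrame, subjects: pd.DataFrame | None = None,
              rule: CDPRule = CDPRule()) -> tuple[pd.DataFrame, float, list]:
    """Per-subject CDP verdicts and cohort prevalence.

    When ``subjects`` is given, only MS subjects are scored.  Subjects
    lacking a baseline visit are excluded and returned in the skipped list.
    Returns (table, prevalence, skipped): table has one row per subject with
    per-visit any_event flags, the verdict and the qualifying rule;
    prevalence = confirmed / scored subjects.
    """
    if subjects is not None:
        ms_ids = set(subjects.loc[subjects["cohort"] == "MS", "subject_id"])
        visits = visits[visits["subject_id"].isin(ms_ids)]
    rows = []
    skipped = []
    for sid, sub in visits.groupby("subject_id", sort=True):
        try:
            res = cdp_for_subject(sub, rule)
        except CDPError:
            skipped.append(sid)
            continue
        row = {"subject_id": sid}
        for j in FOLLOWUPS:
            flag = (res.events.loc[j, "any_event"]
                    if j in res.events.index else np.nan)
            row[f"event_v{j}"] = flag
        row["n_event_visits"] = res.n_event_visits
        row["confirmed"] = res.confirmed
        row["qualifying_rule"] = res.qualifying_rule
        rows.append(row)
    table = pd.DataFrame(rows)
    prevalence = float(table["confirmed"].mean()) if len(table) else float("nan")
    return table, prevalence, skipped
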