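"""Kaplan–Meier estimation and log-rank comparison across NSS quantile groups.

Estimation and testing are delegated to ``lifelines``; this module adapts
them to the cohort container and the quantile-group workflow.  Ties at an
event time follow the standard convention: deaths are processed before
censorings at the same time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .cohort import CohortTable
from .nss import NSSAssignment


@dataclass
class SurvivalCurve:
    """Product-limit estimate for one group: step function with risk sets."""

    label: str
    times: np.ndarray        # distinct observed times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    survival: np.ndarray     # S(t) just after each time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.label,
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "censored": self.censored,
                "survival": self.survival,
            }
        )


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def km_estimate(times, events, label: str = "") -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator over the distinct observed times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no records")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or None)
    # event_table includes a t=0 anchor row with no observations; keep observed times
    tbl = kmf.event_table
    tbl = tbl[(tbl["observed"] + tbl["censored"]) > 0]
    t = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy()
    return SurvivalCurve(
        label=label,
        times=t,
        at_risk=tbl["at_risk"].to_numpy(),
        events=tbl["observed"].to_numpy(),
        censored=tbl["censored"].to_numpy(),
        survival=surv,
    )


def logrank_test(groups: dict[str, tuple[np.ndarray, np.ndarray]]) -> LogRankResult:
    """k-group log-rank test; chi-square with k−1 degrees of freedom.

    ``groups`` maps label → (times, events).  Raises when fewer than two
    non-empty groups are supplied or the statistic is undefined (no
    variance, e.g. a single shared record per group).
    """
    labels, times, events = [], [], []
    for lab, (t, e) in groups.items():
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            continue
        labels.extend([lab] * t.size)
        times.append(t)
        events.append(e)
    if len(set(labels)) < 2:
        raise ValueError("log-rank test needs >= 2 non-empty groups")
    res = multivariate_logrank_test(
        np.concatenate(times), np.array(labels), np.concatenate(events)
    )
    stat = float(res.test_statistic)
    if not np.isfinite(stat):
        raise ValueError("log-rank statistic undefined (zero variance)")
    return LogRankResult(statistic=stat, df=int(res.degrees_of_freedom), p_value=float(res.p_value))


def survival_by_nss_group(
    cohort: CohortTable,
    assignments: list[NSSAssignment],
) -> dict[str, dict]:
    """Per-stage KM curves by quantile group plus the stage's log-rank test.

    Empty quantile groups are dropped with a warning; a stage with a
    single non-empty group gets its curve but no test.
    """
    by_id = {r.patient_id: r for r in cohort.records}
    staged: dict[str, dict[str, list]] = {}
    for a in assignments:
        r = by_id.get(a.patient_id)
        if r is None:
            continue
        staged.setdefault(a.t_stage, {}).setdefault(a.quantile_group, []).append(r)

    out: dict[str, dict] = {}
    for stage, groups in sorted(staged.items()):
        curves = {}
        test_groups = {}
        for g in ("Q1", "Q2", "Q3", "Q4"):
            recs = groups.get(g, [])
            if not recs:
                warnings.warn(f"stage {stage}: quantile group {g} is empty; dropped")
                continue
            t = np.array([r.survival_months for r in recs])
            e = np.array([r.event for r in recs])
            curves[g] = km_estimate(t, e, label=f"{stage}-{g}")
            test_groups[g] = (t, e)
        test = None
        if len(test_groups) >= 2:
            test = logrank_test(test_groups)
        out[stage] = {"curves": curves, "logrank": test}
    return out
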