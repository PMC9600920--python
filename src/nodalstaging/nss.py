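"""Nodal staging score: curves, minimal node counts, quantile groups.

The nodal staging score (NSS) is the probability that a patient whose
examined nodes are all negative is truly free of nodal disease.  By Bayes'
rule with stage prevalence ``Prev`` and false-negative probability
``ProbFN`` at ``n`` examined nodes,

    NSS(n) = (1 - Prev) / ((1 - Prev) + Prev * ProbFN(n)).

It rises toward 1 as more nodes are examined; how fast depends on the
stage's beta-binomial parameters and prevalence.  The score supports two
clinical readings: a curve per stage (how many nodes make a negative
finding trustworthy) and a per-patient value used for quantile grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .betabinom import BetaBinomParams, fn_probability
from .cohort import CohortTable

QUANTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class NSSCurve:
    """NSS as a function of examined-node count for one T stage."""

    t_stage: str
    nodes: np.ndarray  # 1..n_max
    scores: np.ndarray
    prevalence_used: float
    params_used: BetaBinomParams
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def score_at(self, n: int) -> float:
        idx = np.searchsorted(self.nodes, n)
        if idx >= len(self.nodes) or self.nodes[idx] != n:
            raise KeyError(f"curve has no point at n={n}")
        return float(self.scores[idx])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"t_stage": self.t_stage, "nodes_examined": self.nodes, "nss": self.scores}
        )
        if self.ci_low is not None:
            df["ci_low"] = self.ci_low
            df["ci_high"] = self.ci_high
        return df


@dataclass
class NSSAssignment:
    """A patient's score and quantile group within their T stage."""

    patient_id: str
    t_stage: str
    nodes_examined: int
    score: float
    quantile_group: str
    cutoffs_used: tuple[float, float, float]


def nss_value(prevalence: float, fn_prob: float) -> float:
    """Probability of true nodal negativity given an all-negative exam.

    Defined as 1 whenever ``fn_prob`` is 0 (perfect sensitivity means a
    negative exam is conclusive, whatever the prevalence).
    """
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError("prevalence must be in [0, 1]")
    if not (0.0 <= fn_prob <= 1.0):
        raise ValueError("fn_prob must be in [0, 1]")
    if fn_prob == 0.0:
        return 1.0
    num = 1.0 - prevalence
    return num / (num + prevalence * fn_prob)


def nss_curve(
    params: BetaBinomParams,
    prevalence: float,
    n_max: int = 90,
) -> NSSCurve:
    """Pointwise NSS over ``n = 1..n_max`` examined nodes."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    nodes = np.arange(1, n_max + 1)
    fn = fn_probability(params, nodes)
    num = 1.0 - prevalence
    with np.errstate(invalid="ignore"):
        scores = np.where(fn == 0.0, 1.0, num / (num + prevalence * fn))
    return NSSCurve(
        t_stage=params.t_stage,
        nodes=nodes,
        scores=scores,
        prevalence_used=float(prevalence),
        params_used=params,
    )


def min_nodes_for_score(curve: NSSCurve, target: float) -> int | None:
    """Smallest examined-node count whose score reaches ``target``.

    Returns ``None`` when no point of the curve reaches it (the caller may
    extend ``n_max``).
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("target must be in (0, 1]")
    hits = np.nonzero(curve.scores >= target)[0]
    if hits.size == 0:
        return None
    return int(curve.nodes[hits[0]])


def score_patients(
    cohort: CohortTable,
    params_by_stage: dict[str, BetaBinomParams],
    prevalence_by_stage: dict[str, float],
) -> pd.DataFrame:
    """Per-patient NSS as a function of (T stage, examined-node count).

    All patients receive a score, node-positive ones included: the score
    describes how informative the patient's examination extent is for
    their stage, and the published quantile grouping covers the whole
    cohort.  Stages lacking parameters or prevalence are skipped.
    """
    rows = []
    for r in cohort.records:
        if r.t_stage not in params_by_stage or r.t_stage not in prevalence_by_stage:
            continue
        fn = fn_probability(params_by_stage[r.t_stage], r.nodes_examined)
        s = nss_value(prevalence_by_stage[r.t_stage], float(fn))
        rows.append(
            {
                "patient_id": r.patient_id,
                "t_stage": r.t_stage,
                "nodes_examined": r.nodes_examined,
                "score": s,
            }
        )
    return pd.DataFrame(rows)


def assign_quantile_groups(
    scores: pd.DataFrame,
    mode: Literal["empirical", "fixed"] = "empirical",
) -> list[NSSAssignment]:
    """Assign quartile groups Q1–Q4 within each T stage.

    ``empirical`` (default) computes stage-specific 25/50/75 percentiles of
    the patient scores with linear interpolation between order statistics;
    ``fixed`` uses the absolute 0.25 / 0.50 / 0.75 grid.  Groups use
    half-open intervals ``[low, high)`` with Q4 closed above, so when every
    score ties all patients land in Q4 (a warning is emitted).
    """
    out: list[NSSAssignment] = []
    for stage, grp in scores.groupby("t_stage", sort=True):
        vals = grp["score"].to_numpy()
        if mode == "empirical":
            if len(vals) < 4:
                raise ValueError(f"stage {stage}: insufficient for quartiles (n={len(vals)})")
            q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        else:
            q25, q50, q75 = 0.25, 0.50, 0.75
        if q25 == q75:
            warnings.warn(
                f"stage {stage}: degenerate quantile cutoffs (all scores tie); "
                "every patient assigned Q4",
                UserWarning,
            )
        cutoffs = (float(q25), float(q50), float(q75))
        for _, row in grp.iterrows():
            s = row["score"]
            if s < q25:
                g = "Q1"
            elif s < q50:
                g = "Q2"
            elif s < q75:
                g = "Q3"
            else:
                g = "Q4"
            out.append(
                NSSAssignment(
                    patient_id=row["patient_id"],
                    t_stage=stage,
                    nodes_examined=int(row["nodes_examined"]),
                    score=float(s),
                    quantile_group=g,
                    cutoffs_used=cutoffs,
                )
            )
    return out


def assignments_to_dataframe(assignments: Sequence[NSSAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [a.patient_id for a in assignments],
            "t_stage": [a.t_stage for a in assignments],
            "nodes_examined": [a.nodes_examined for a in assignments],
            "score": [a.score for a in assignments],
            "quantile_group": [a.quantile_group for a in assignments],
            "q25": [a.cutoffs_used[0] for a in assignments],
            "q50": [a.cutoffs_used[1] for a in assignments],
            "q75": [a.cutoffs_used[2] for a in assignments],
        }
    )
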