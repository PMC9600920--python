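"""False-negative imputation and apparent vs adjusted nodal-disease prevalence.

A node-negative patient may be a true negative or a missed (false
negative) case.  Under the beta-binomial model, the sensitivity at
``n`` examined nodes is ``1 - Prob(FN | n)``, so in a stratum where
``#TP`` patients were found positive the expected number of missed cases
is

    #FN = Prob(FN | n) * #TP / (1 - Prob(FN | n)).

Adjusted prevalence re-labels those ``#FN`` patients from the observed
negative pool and recomputes the diseased fraction over the same total:
``sum(#TP + #FN) / sum(#TP + #TN + #FN)``, with ``#TN`` the observed
negatives minus the imputed ``#FN``.  Patients are re-labelled, never
created, so the denominator stays the stage's patient count and the
adjusted prevalence can only exceed the apparent one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .betabinom import BetaBinomParams, fn_probability
from .cohort import NodeCountStratum


class ImputationCapWarning(UserWarning):
    """Imputed false negatives exceeded the observed negatives in a stratum."""


@dataclass
class PrevalenceEstimate:
    """Apparent and false-negative-adjusted prevalence for one T stage."""

    t_stage: str
    apparent: float
    adjusted: float
    fn_total: float
    n_patients: int
    ci: tuple[float, float] | None = None


def impute_false_negatives(
    stratum: NodeCountStratum,
    params: BetaBinomParams,
    cap: bool = True,
) -> float:
    """Expected false-negative count in one (stage, examined-count) stratum.

    Returns ``ProbFN * #TP / (1 - ProbFN)``; zero when the stratum has no
    detected positives.  When ``cap`` is set (default), the imputed count
    is clipped at the stratum's observed negative count — the missed
    patients must physically exist among the observed negatives — and a
    warning is emitted.
    """
    if stratum.nodes_examined < 1:
        raise ValueError("stratum with zero examined nodes: FN probability is 1")
    if stratum.n_node_positive == 0:
        return 0.0
    p_fn = fn_probability(params, stratum.nodes_examined)
    fn = p_fn * stratum.n_node_positive / (1.0 - p_fn)
    if cap and fn > stratum.n_node_negative:
        warnings.warn(
            f"stratum ({stratum.t_stage}, n={stratum.nodes_examined}): imputed "
            f"FN {fn:.2f} exceeds observed negatives {stratum.n_node_negative}; capped",
            ImputationCapWarning,
        )
        fn = float(stratum.n_node_negative)
    return float(fn)


def apparent_prevalence(strata: Sequence[NodeCountStratum]) -> float:
    """Observed node-positive fraction: positive patients / all patients."""
    pos = sum(s.n_node_positive for s in strata)
    tot = sum(s.n_total for s in strata)
    if tot == 0:
        raise ValueError("no patients in stage")
    return pos / tot


def adjusted_prevalence(
    strata: Sequence[NodeCountStratum],
    params: BetaBinomParams,
    cap: bool = True,
) -> PrevalenceEstimate:
    """Stage prevalence after imputing false negatives per stratum."""
    strata = list(strata)
    if not strata:
        raise ValueError("no strata supplied")
    t_stage = strata[0].t_stage
    tp = sum(s.n_node_positive for s in strata)
    total = sum(s.n_total for s in strata)
    fn_total = sum(impute_false_negatives(s, params, cap=cap) for s in strata)
    return PrevalenceEstimate(
        t_stage=t_stage,
        apparent=tp / total,
        adjusted=(tp + fn_total) / total,
        fn_total=fn_total,
        n_patients=total,
    )


def prevalence_by_stage(
    strata: Iterable[NodeCountStratum],
    params_by_stage: dict[str, BetaBinomParams],
    cap: bool = True,
) -> dict[str, PrevalenceEstimate]:
    """Group strata by stage and adjust each stage with its own parameters.

    Stages without fitted parameters get an apparent-only estimate
    (``adjusted`` equal to ``apparent``, ``fn_total`` zero).
    """
    grouped: dict[str, list[NodeCountStratum]] = {}
    for s in strata:
        grouped.setdefault(s.t_stage, []).append(s)
    out: dict[str, PrevalenceEstimate] = {}
    for stage, group in sorted(grouped.items()):
        if stage in params_by_stage:
            out[stage] = adjusted_prevalence(group, params_by_stage[stage], cap=cap)
        else:
            app = apparent_prevalence(group)
            out[stage] = PrevalenceEstimate(
                t_stage=stage,
                apparent=app,
                adjusted=app,
                fn_total=0.0,
                n_patients=sum(s.n_total for s in group),
            )
    return out
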