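"""Bootstrap confidence intervals for parameters, prevalence and NSS curves.

Resampling unit is the patient, within T stage (stage sample sizes are
preserved — every estimand here is stage-specific).  Intervals are 95%
percentile intervals over ``n_boot`` replicates; the replicate stream is
fully determined by ``(data, seed, n_boot)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .betabinom import BetaBinomParams, fit_beta_binomial
from .cohort import CohortTable, stratify_counts
from .nss import NSSCurve, nss_curve
from .prevalence import adjusted_prevalence


class UnstableBootstrapError(RuntimeError):
    """More than 20% of bootstrap refits failed."""


@dataclass
class BootstrapResult:
    """Replicates and percentile CI for one scalar statistic."""

    statistic: str
    point: float
    replicates: np.ndarray
    ci: tuple[float, float]
    n_boot: int
    seed: int
    n_failed: int = 0


def _percentile_ci(reps: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    lo = 100 * (1 - level) / 2
    return (
        float(np.percentile(reps, lo)),
        float(np.percentile(reps, 100 - lo)),
    )


def _stage_arrays(cohort: CohortTable, t_stage: str) -> tuple[np.ndarray, np.ndarray]:
    recs = [r for r in cohort.records if r.t_stage == t_stage]
    n = np.array([r.nodes_examined for r in recs])
    k = np.array([r.nodes_positive for r in recs])
    return n, k


def bootstrap_params(
    cohort: CohortTable,
    t_stage: str,
    n_boot: int = 1000,
    seed: int = 0,
    truncated: bool = True,
    max_fail_frac: float = 0.2,
) -> tuple[BootstrapResult, BootstrapResult]:
    """Percentile CIs for (alpha, beta) by within-stage patient resampling.

    Each replicate resamples the stage's patients with replacement and
    refits on its node-positive subset.  Replicates whose refit fails or
    is degenerate are dropped and counted; more than ``max_fail_frac``
    failures raises :class:`UnstableBootstrapError`.
    """
    n, k = _stage_arrays(cohort, t_stage)
    if n.size == 0:
        raise ValueError(f"no patients in stage {t_stage}")
    pos = k >= 1
    point = fit_beta_binomial(n[pos], k[pos], t_stage=t_stage, truncated=truncated)

    rng = np.random.default_rng(seed)
    a_reps, b_reps = [], []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n.size, size=n.size)
        nb, kb = n[idx], k[idx]
        posb = kb >= 1
        if posb.sum() < 2 or not np.any(kb[posb] < nb[posb]):
            failed += 1
            continue
        try:
            fit = fit_beta_binomial(
                nb[posb], kb[posb], t_stage=t_stage, truncated=truncated, n_restarts=0
            )
        except (RuntimeError, ValueError):
            failed += 1
            continue
        if fit.degenerate:
            failed += 1
            continue
        a_reps.append(fit.alpha)
        b_reps.append(fit.beta)
    if failed > max_fail_frac * n_boot:
        raise UnstableBootstrapError(
            f"{failed}/{n_boot} bootstrap refits failed for stage {t_stage}"
        )
    a_reps = np.asarray(a_reps)
    b_reps = np.asarray(b_reps)
    return (
        BootstrapResult("alpha", point.alpha, a_reps, _percentile_ci(a_reps), n_boot, seed, failed),
        BootstrapResult("beta", point.beta, b_reps, _percentile_ci(b_reps), n_boot, seed, failed),
    )


def bootstrap_curve_ci(
    cohort: CohortTable,
    t_stage: str,
    n_boot: int = 1000,
    seed: int = 0,
    n_max: int = 90,
    prevalence_source: str = "adjusted",
    truncated: bool = True,
    max_fail_frac: float = 0.2,
) -> NSSCurve:
    """NSS curve with a pointwise 95% percentile band.

    Each replicate refits (alpha, beta) and recomputes the stage
    prevalence before re-evaluating the curve, so the band propagates both
    parameter and prevalence uncertainty.
    """
    n, k = _stage_arrays(cohort, t_stage)
    recs = [r for r in cohort.records if r.t_stage == t_stage]
    pos = k >= 1
    point_fit = fit_beta_binomial(n[pos], k[pos], t_stage=t_stage, truncated=truncated)
    point_prev = _curve_prevalence(recs, point_fit, prevalence_source)
    point_curve = nss_curve(point_fit, point_prev, n_max=n_max)

    rng = np.random.default_rng(seed)
    bands = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(recs), size=len(recs))
        rb = [recs[i] for i in idx]
        nb = np.array([r.nodes_examined for r in rb])
        kb = np.array([r.nodes_positive for r in rb])
        posb = kb >= 1
        if posb.sum() < 2 or not np.any(kb[posb] < nb[posb]):
            failed += 1
            continue
        try:
            fit = fit_beta_binomial(
                nb[posb], kb[posb], t_stage=t_stage, truncated=truncated, n_restarts=0
            )
            prev = _curve_prevalence(rb, fit, prevalence_source)
        except (RuntimeError, ValueError):
            failed += 1
            continue
        if fit.degenerate:
            failed += 1
            continue
        bands.append(nss_curve(fit, prev, n_max=n_max).scores)
    if failed > max_fail_frac * n_boot:
        raise UnstableBootstrapError(
            f"{failed}/{n_boot} bootstrap refits failed for stage {t_stage}"
        )
    bands = np.vstack(bands)
    point_curve.ci_low = np.percentile(bands, 2.5, axis=0)
    point_curve.ci_high = np.percentile(bands, 97.5, axis=0)
    return point_curve


def _curve_prevalence(records, fit: BetaBinomParams, source: str) -> float:
    strata = stratify_counts(CohortTable(records=list(records)))
    if source == "apparent":
        pos = sum(s.n_node_positive for s in strata)
        return pos / sum(s.n_total for s in strata)
    if source == "adjusted":
        return adjusted_prevalence(strata, fit).adjusted
    raise ValueError(f"unknown prevalence source {source!r}")
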