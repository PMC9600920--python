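"""Synthetic SEER-like GSRCC cohorts with ground-truth labels.

The generator produces exactly the statistical structure the analysis
assumes, so every pipeline stage is testable without registry access:

* stage drawn from a four-way mix,
* examined-node count ``n`` from a shifted negative binomial,
* true nodal disease ``~ Bernoulli(stage prevalence)``,
* for diseased patients a latent per-node positivity
  ``p ~ Beta(alpha_stage, beta_stage)`` and observed positives
  ``~ Binomial(n, p)`` — a zero draw is a false negative,
* disease-free patients always show zero positives (no false positives),
* exponential survival with a status-dependent hazard, independent
  exponential censoring, and an administrative cutoff.

Default parameter values echo the published GSRCC study scale: stage mix
116/60/176/209 over 561 patients, stage prevalences
0.155/0.583/0.727/0.895, and the published (alpha, beta) pairs.

Randomness: one integer seed; each patient's draws come from a sub-stream
derived from the patient index, so growing the cohort never reshuffles
earlier patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .betabinom import fn_probability
from .cohort import CohortTable, PatientRecord

T_STAGES = ("T1", "T2", "T3", "T4")


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; defaults mirror the study scale."""

    cohort_size: int = 561
    stage_mix: dict[str, float] = field(
        default_factory=lambda: {
            "T1": 116 / 561,
            "T2": 60 / 561,
            "T3": 176 / 561,
            "T4": 209 / 561,
        }
    )
    prevalence: dict[str, float] = field(
        default_factory=lambda: {"T1": 0.155, "T2": 0.583, "T3": 0.727, "T4": 0.895}
    )
    alpha: dict[str, float] = field(
        default_factory=lambda: {
            "T1": 0.06938207,
            "T2": 0.42578161,
            "T3": 0.48686973,
            "T4": 0.80543434,
        }
    )
    beta: dict[str, float] = field(
        default_factory=lambda: {
            "T1": 1.8877199,
            "T2": 2.2180490,
            "T3": 1.2430379,
            "T4": 0.8710085,
        }
    )
    # examined nodes ~ 1 + NegBin(mean, dispersion), truncated at nodes_max
    nodes_mean: float = 14.0
    nodes_dispersion: float = 1.2
    nodes_max: int = 90
    # survival: exponential hazards per true nodal status (per month),
    # independent exponential censoring, administrative cutoff
    hazard_diseased: float = 0.02
    hazard_free: float = 0.01
    censor_rate: float = 0.008
    cutoff_months: float = 120.0
    seed: int = 0

    def validate(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        mix = sum(self.stage_mix.values())
        if abs(mix - 1.0) > 1e-9:
            raise ValueError(f"stage_mix must sum to 1 (got {mix})")
        for st in self.stage_mix:
            if not (0.0 <= self.prevalence[st] <= 1.0):
                raise ValueError(f"prevalence[{st}] outside [0, 1]")
            if self.alpha[st] <= 0 or self.beta[st] <= 0:
                raise ValueError(f"alpha/beta for {st} must be positive")
        if min(self.hazard_diseased, self.hazard_free, self.censor_rate) <= 0:
            raise ValueError("hazard and censoring rates must be positive")
        if self.nodes_mean <= 0 or self.nodes_dispersion <= 0 or self.nodes_max < 1:
            raise ValueError("invalid examined-node distribution parameters")


def _nodes_pmf(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Support and weights of the examined-node count distribution.

    ``n = 1 + m`` with ``m ~ NegBin(size=dispersion, mean=nodes_mean)``;
    the tail mass beyond ``nodes_max`` is lumped onto ``nodes_max``,
    matching the clipping used when sampling.
    """
    r = config.nodes_dispersion
    p = r / (r + config.nodes_mean)
    m = np.arange(0, config.nodes_max)  # n = 1..nodes_max
    w = stats.nbinom.pmf(m, r, p)
    w[-1] += stats.nbinom.sf(m[-1], r, p)
    return m + 1, w


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def simulate_cohort(config: SimulationConfig) -> tuple[CohortTable, pd.DataFrame]:
    """Draw a cohort and its ground truth; deterministic given the seed.

    Returns the :class:`CohortTable` plus a ground-truth frame with one row
    per patient: ``true_diseased`` (latent disease indicator),
    ``p_latent`` (per-node positivity propensity, 0 for disease-free) and
    ``fn_flag`` (diseased but zero positives observed).
    """
    config.validate()
    stages = sorted(config.stage_mix)
    mix = np.array([config.stage_mix[s] for s in stages])
    r = config.nodes_dispersion
    p_nb = r / (r + config.nodes_mean)

    records: list[PatientRecord] = []
    truth_rows = []
    for i in range(config.cohort_size):
        rng = _patient_rng(config.seed, i)
        stage = stages[rng.choice(len(stages), p=mix)]
        n_ex = 1 + min(int(rng.negative_binomial(r, p_nb)), config.nodes_max - 1)
        diseased = bool(rng.random() < config.prevalence[stage])
        if diseased:
            p_i = float(rng.beta(config.alpha[stage], config.beta[stage]))
            k = int(rng.binomial(n_ex, p_i))
        else:
            p_i, k = 0.0, 0
        hazard = config.hazard_diseased if diseased else config.hazard_free
        t_event = rng.exponential(1.0 / hazard)
        t_cens = min(rng.exponential(1.0 / config.censor_rate), config.cutoff_months)
        time = min(t_event, t_cens)
        event = int(t_event <= t_cens)
        records.append(
            PatientRecord(
                patient_id=f"sim-{i:06d}",
                t_stage=stage,
                nodes_examined=n_ex,
                nodes_positive=k,
                survival_months=float(time),
                event=event,
            )
        )
        truth_rows.append(
            {
                "patient_id": f"sim-{i:06d}",
                "t_stage": stage,
                "true_diseased": diseased,
                "p_latent": p_i,
                "fn_flag": diseased and k == 0,
            }
        )
    cohort = CohortTable(records=records, provenance=f"simulated(seed={config.seed})")
    return cohort, pd.DataFrame(truth_rows)


def expected_observed_prevalence(config: SimulationConfig, t_stage: str) -> float:
    """Exact expected fraction of observed node-positive patients in a stage.

    ``Prev_true * (1 - sum_n w(n) * ProbFN(n))`` where ``w`` is the
    examined-node distribution — a closed-form oracle for the generator's
    observed positivity rate.
    """
    config.validate()
    nodes, w = _nodes_pmf(config)
    fn = fn_probability((config.alpha[t_stage], config.beta[t_stage]), nodes)
    return float(config.prevalence[t_stage] * (1.0 - np.sum(w * fn)))
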