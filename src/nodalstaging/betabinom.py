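"""Beta-binomial model of lymph-node positivity and its zero-truncated fit.

The model: a patient with nodal disease has a latent per-node positivity
probability ``p ~ Beta(alpha, beta)``; among ``n`` examined, exchangeable
nodes the number found positive is ``Binomial(n, p)``.  The chance that a
truly diseased patient shows *zero* positive nodes — a false-negative
pathological N0 — is the zero class of this mixture,

    Prob(FN | n) = B(alpha, beta + n) / B(alpha, beta)
                 = prod_{k=0}^{n-1} (beta + k) / (alpha + beta + k),

which decreases in ``n`` like ``n**(-alpha)``: examining more nodes makes
missing disease less likely, at a stage-specific rate.

``(alpha, beta)`` are estimated per T stage by maximum likelihood from
node-positive patients only.  Because that fitting sample is defined by
observing at least one positive node, the default likelihood conditions on
``k >= 1`` (zero-truncated); the untruncated likelihood is available for
sensitivity analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

PARAM_LOWER = 1e-8
PARAM_UPPER = 1e6


class DegenerateFitWarning(UserWarning):
    """The likelihood pushed a parameter to the boundary of its range."""


@dataclass
class BetaBinomParams:
    """Stage-specific beta-binomial intensity parameters.

    ``alpha`` and ``beta`` shape the latent per-node positivity
    distribution; small ``alpha`` concentrates mass near zero (disease
    easy to miss), large ``alpha/(alpha+beta)`` means positive nodes are
    found readily.  Confidence intervals, when present, are 95% bounds.
    """

    t_stage: str
    alpha: float
    beta: float
    alpha_ci: tuple[float, float] | None = None
    beta_ci: tuple[float, float] | None = None
    loglik: float | None = None
    converged: bool | None = None
    n_used: int | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")

    def to_dict(self) -> dict:
        d = {
            "t_stage": self.t_stage,
            "alpha": self.alpha,
            "beta": self.beta,
            "alpha_ci": list(self.alpha_ci) if self.alpha_ci else None,
            "beta_ci": list(self.beta_ci) if self.beta_ci else None,
            "loglik": self.loglik,
            "n_used": self.n_used,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BetaBinomParams":
        return cls(
            t_stage=d["t_stage"],
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
            alpha_ci=tuple(d["alpha_ci"]) if d.get("alpha_ci") else None,
            beta_ci=tuple(d["beta_ci"]) if d.get("beta_ci") else None,
            loglik=d.get("loglik"),
            n_used=d.get("n_used"),
        )


def params_to_json(params: Sequence[BetaBinomParams], path: str | Path) -> None:
    Path(path).write_text(json.dumps([p.to_dict() for p in params], indent=2))


def params_from_json(path: str | Path) -> dict[str, BetaBinomParams]:
    data = json.loads(Path(path).read_text())
    out = {}
    for d in data:
        p = BetaBinomParams.from_dict(d)
        out[p.t_stage] = p
    return out


def _ab(params: BetaBinomParams | tuple[float, float]) -> tuple[float, float]:
    if isinstance(params, BetaBinomParams):
        return params.alpha, params.beta
    return float(params[0]), float(params[1])


def betabinom_logpmf(k, n, params) -> np.ndarray | float:
    """Log probability of ``k`` positive among ``n`` examined nodes."""
    a, b = _ab(params)
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("k must satisfy 0 <= k <= n")
    return stats.betabinom.logpmf(k, n, a, b)


def betabinom_pmf(k, n, params) -> np.ndarray | float:
    """Probability of ``k`` positive among ``n`` examined, C(n,k)·B(a+k, b+n−k)/B(a,b)."""
    return np.exp(betabinom_logpmf(k, n, params))


def fn_probability(params, nodes_examined) -> np.ndarray | float:
    """Probability that a diseased patient shows zero positive nodes.

    ``B(alpha, beta+n) / B(alpha, beta)``, evaluated as a log-gamma
    difference for numerical stability.  Equals 1 at ``n = 0`` (nothing
    examined, disease surely missed) and decreases strictly in ``n``.
    """
    a, b = _ab(params)
    n = np.asarray(nodes_examined, dtype=float)
    if np.any(n < 0):
        raise ValueError("nodes_examined must be >= 0")
    out = np.exp(special.betaln(a, b + n) - special.betaln(a, b))
    return float(out) if out.ndim == 0 else out


def fn_probability_product(params, nodes_examined: int) -> float:
    """Same quantity via the finite product — an independent cross-check path."""
    a, b = _ab(params)
    n = int(nodes_examined)
    if n < 0:
        raise ValueError("nodes_examined must be >= 0")
    k = np.arange(n, dtype=float)
    return float(np.prod((b + k) / (a + b + k)))


def truncated_loglik(params, n_examined, k_positive) -> float:
    """Zero-truncated log-likelihood over node-positive observations.

    ``sum_i log[ pmf(k_i; n_i) / (1 - pmf(0; n_i)) ]``.  The conditioning
    reflects how the fitting sample is ascertained: only patients with at
    least one positive node enter.
    """
    n = np.asarray(n_examined)
    k = np.asarray(k_positive)
    if np.any(k < 1):
        raise ValueError("truncated support requires k >= 1 for every observation")
    lp = betabinom_logpmf(k, n, params)
    a, b = _ab(params)
    log_p0 = special.betaln(a, b + n) - special.betaln(a, b)
    # log(1 - p0), stable when p0 is near 1
    log_norm = np.log1p(-np.exp(log_p0))
    return float(np.sum(lp - log_norm))


def untruncated_loglik(params, n_examined, k_positive) -> float:
    """Plain beta-binomial log-likelihood (sensitivity-analysis option)."""
    return float(np.sum(betabinom_logpmf(k_positive, n_examined, params)))


def _moment_start(n: np.ndarray, k: np.ndarray) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) from observed positive fractions."""
    p = k / n
    m = float(np.mean(p))
    v = float(np.var(p))
    m = min(max(m, 1e-3), 1 - 1e-3)
    if v <= 1e-8:
        return 1.0, max((1 - m) / m, 1e-2)
    s = m * (1 - m) / v - 1
    if s <= 0:
        s = 0.5
    a, b = m * s, (1 - m) * s
    return min(max(a, 1e-3), 1e3), min(max(b, 1e-3), 1e3)


@dataclass
class _FitProblem:
    n: np.ndarray
    k: np.ndarray
    truncated: bool

    def negloglik(self, log_ab: np.ndarray) -> float:
        a, b = np.exp(log_ab)
        if not np.isfinite(a) or not np.isfinite(b) or a <= 0 or b <= 0:
            return np.inf
        try:
            if self.truncated:
                return -truncated_loglik((a, b), self.n, self.k)
            return -untruncated_loglik((a, b), self.n, self.k)
        except FloatingPointError:
            return np.inf


def fit_beta_binomial(
    n_examined,
    k_positive,
    t_stage: str = "",
    truncated: bool = True,
    n_restarts: int = 4,
    seed: int = 0,
    xtol: float = 1e-8,
) -> BetaBinomParams:
    """Maximum-likelihood ``(alpha, beta)`` from node-positive observations.

    Optimizes the (by default zero-truncated) likelihood over
    ``(log alpha, log beta)`` with Nelder–Mead, starting from a
    method-of-moments estimate plus ``n_restarts`` jittered restarts drawn
    from a fixed-seed stream; the best optimum wins and is guaranteed to be
    at least as good as the starting point.

    A fit whose parameters drift beyond ``[1e-8, 1e6]`` is flagged
    ``degenerate`` (e.g. when every patient has all examined nodes
    positive, the likelihood pushes ``alpha`` to infinity) and a
    :class:`DegenerateFitWarning` is emitted.
    """
    n = np.asarray(n_examined, dtype=float)
    k = np.asarray(k_positive, dtype=float)
    if n.size < 2:
        raise ValueError("need at least 2 observations to fit")
    if truncated and np.any(k < 1):
        raise ValueError("truncated fit requires k >= 1 for every observation")

    prob = _FitProblem(n=n, k=k, truncated=truncated)
    a0, b0 = _moment_start(n, k)
    rng = np.random.default_rng(seed)
    starts = [np.log([a0, b0])]
    for _ in range(n_restarts):
        starts.append(starts[0] + rng.normal(scale=0.7, size=2))

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            prob.negloglik,
            x0,
            method="Nelder-Mead",
            options={"xatol": xtol, "fatol": 1e-10, "maxiter": 4000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    a_hat, b_hat = np.exp(best.x)
    degenerate = not (PARAM_LOWER < a_hat < PARAM_UPPER and PARAM_LOWER < b_hat < PARAM_UPPER)
    if degenerate:
        warnings.warn(
            f"degenerate fit for stage {t_stage or '?'}: "
            f"alpha={a_hat:.3g}, beta={b_hat:.3g} at parameter-range boundary",
            DegenerateFitWarning,
        )
        a_hat = min(max(a_hat, PARAM_LOWER), PARAM_UPPER)
        b_hat = min(max(b_hat, PARAM_LOWER), PARAM_UPPER)
    if not any_converged and not degenerate:
        raise RuntimeError(
            f"beta-binomial fit failed to converge (best loglik {-best.fun:.6g}, "
            f"alpha={a_hat:.6g}, beta={b_hat:.6g})"
        )
    return BetaBinomParams(
        t_stage=t_stage,
        alpha=float(a_hat),
        beta=float(b_hat),
        loglik=float(-best.fun),
        converged=any_converged,
        n_used=int(n.size),
        degenerate=degenerate,
    )
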