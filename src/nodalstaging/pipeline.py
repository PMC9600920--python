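"""End-to-end orchestration: validate → stratify → fit → adjust → score → survive.

``run_pipeline`` executes every stage of the analysis on a cohort and
writes a bundle of text artifacts (parameter JSON, prevalence CSV, NSS
curve CSV, minimal-node CSV, assignment CSV, survival exports) plus a run
manifest with SHA-256 digests of every file, so a rerun with the same
inputs and seed is verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .betabinom import BetaBinomParams, fit_beta_binomial, params_to_json
from .bootstrap import UnstableBootstrapError, bootstrap_params
from .cohort import CohortTable, read_cohort, stratify_counts, validate_cohort
from .nss import (
    assign_quantile_groups,
    assignments_to_dataframe,
    min_nodes_for_score,
    nss_curve,
    score_patients,
)
from .prevalence import prevalence_by_stage
from .survival import survival_by_nss_group

DEFAULT_CONFIG = {
    "prevalence_source": "adjusted",  # adjusted | apparent
    "truncated": True,
    "quantile_mode": "empirical",  # empirical | fixed
    "n_max": 90,
    "target_score": 0.8,
    "n_boot": 1000,
    "seed": 0,
}


@dataclass
class RunManifest:
    seed: int
    config: dict
    input_digest: str
    artifacts: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    stage_log: list[str] = field(default_factory=list)

    def to_json(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "config": self.config,
                    "input_digest": self.input_digest,
                    "artifacts": self.artifacts,
                    "warnings": self.warnings,
                    "stage_log": self.stage_log,
                },
                indent=2,
            )
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    cohort: CohortTable
    params: dict[str, BetaBinomParams]
    prevalence: dict
    curves: dict
    min_nodes: dict
    assignments: list
    survival: dict
    manifest: RunManifest


def run_pipeline(
    cohort: CohortTable | str | Path,
    config: dict | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full staging analysis; optionally write the artifact bundle.

    Stages that cannot be fitted (no node-positive patients, or all
    saturated) are skipped with a warning and the remaining stages
    complete.  With ``outdir`` set, all exports plus ``manifest.json`` are
    written there.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    if isinstance(cohort, (str, Path)):
        cohort = read_cohort(cohort)

    manifest = RunManifest(
        seed=int(cfg["seed"]),
        config=cfg,
        input_digest=hashlib.sha256(
            cohort.to_dataframe().to_csv(index=False).encode()
        ).hexdigest(),
    )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        cohort = validate_cohort(cohort)
        manifest.stage_log.append(
            f"validate: {len(cohort)} retained, {len(cohort.exclusion_log)} excluded"
        )

        strata = stratify_counts(cohort)
        stages = sorted({s.t_stage for s in strata})

        params: dict[str, BetaBinomParams] = {}
        for stage in stages:
            recs = [r for r in cohort.records if r.t_stage == stage]
            pos = [(r.nodes_examined, r.nodes_positive) for r in recs if r.nodes_positive >= 1]
            if len(pos) < 2 or all(k == n for n, k in pos):
                warnings.warn(f"stage {stage}: not fittable; skipped")
                continue
            n, k = zip(*pos)
            fit = fit_beta_binomial(
                n, k, t_stage=stage, truncated=cfg["truncated"], seed=cfg["seed"]
            )
            if cfg["n_boot"] > 0:
                try:
                    a_res, b_res = bootstrap_params(
                        cohort,
                        stage,
                        n_boot=int(cfg["n_boot"]),
                        seed=int(cfg["seed"]),
                        truncated=cfg["truncated"],
                    )
                except UnstableBootstrapError as exc:
                    warnings.warn(f"stage {stage}: {exc}; CIs omitted")
                else:
                    fit.alpha_ci = a_res.ci
                    fit.beta_ci = b_res.ci
            params[stage] = fit
            manifest.stage_log.append(
                f"fit {stage}: n={fit.n_used}, alpha={fit.alpha:.7g}, beta={fit.beta:.7g}"
            )

        prevalence = prevalence_by_stage(strata, params)
        prev_for_score = {
            st: (est.adjusted if cfg["prevalence_source"] == "adjusted" else est.apparent)
            for st, est in prevalence.items()
        }

        curves = {}
        min_nodes = {}
        for stage, fit in params.items():
            c = nss_curve(fit, prev_for_score[stage], n_max=int(cfg["n_max"]))
            curves[stage] = c
            min_nodes[stage] = min_nodes_for_score(c, float(cfg["target_score"]))

        scores = score_patients(cohort, params, prev_for_score)
        assignments = (
            assign_quantile_groups(scores, mode=cfg["quantile_mode"]) if len(scores) else []
        )
        surv = survival_by_nss_group(cohort, assignments) if assignments else {}
        manifest.warnings = [str(w.message) for w in caught]

    result = PipelineResult(
        cohort=cohort,
        params=params,
        prevalence=prevalence,
        curves=curves,
        min_nodes=min_nodes,
        assignments=assignments,
        survival=surv,
        manifest=manifest,
    )
    if outdir is not None:
        export_tables(result, Path(outdir))
    return result


def export_tables(result: PipelineResult, outdir: Path) -> None:
    """Write the artifact bundle and the digest manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    params_path = outdir / "params.json"
    params_to_json(list(result.params.values()), params_path)

    prev_rows = [
        {
            "t_stage": st,
            "apparent": round(e.apparent, 3),
            "adjusted": round(e.adjusted, 3),
            "fn_imputed": e.fn_total,
            "n_patients": e.n_patients,
        }
        for st, e in sorted(result.prevalence.items())
    ]
    prev_path = outdir / "prevalence.csv"
    pd.DataFrame(prev_rows).to_csv(prev_path, index=False)

    curve_path = outdir / "nss_curves.csv"
    if result.curves:
        pd.concat([c.to_dataframe() for c in result.curves.values()]).to_csv(
            curve_path, index=False
        )
    else:
        curve_path.write_text("t_stage,nodes_examined,nss\n")

    mn_path = outdir / "min_nodes.csv"
    pd.DataFrame(
        [
            {
                "t_stage": st,
                "target": result.manifest.config["target_score"],
                "min_nodes": "unreached" if m is None else m,
            }
            for st, m in sorted(result.min_nodes.items())
        ]
    ).to_csv(mn_path, index=False)

    assign_path = outdir / "assignments.csv"
    if result.assignments:
        assignments_to_dataframe(result.assignments).to_csv(assign_path, index=False)
    else:
        assign_path.write_text("patient_id,t_stage,nodes_examined,score,quantile_group\n")

    surv_path = outdir / "survival_curves.csv"
    frames = []
    tests = {}
    for stage, res in result.survival.items():
        for g, curve in res["curves"].items():
            frames.append(curve.to_dataframe())
        if res["logrank"] is not None:
            tests[stage] = {
                "statistic": res["logrank"].statistic,
                "df": res["logrank"].df,
                "p_value": res["logrank"].p_value,
            }
    if frames:
        pd.concat(frames).to_csv(surv_path, index=False)
    else:
        surv_path.write_text("group,time,at_risk,events,censored,survival\n")
    logrank_path = outdir / "logrank.json"
    logrank_path.write_text(json.dumps(tests, indent=2))

    for p in (params_path, prev_path, curve_path, mn_path, assign_path, surv_path, logrank_path):
        result.manifest.artifacts[p.name] = _digest(p)
    result.manifest.to_json(outdir / "manifest.json")


def format_params_table(params: dict[str, BetaBinomParams]) -> pd.DataFrame:
    """Parameter table with 7-significant-digit formatting and CI columns."""

    def fmt(x):
        return f"{x:.7g}"

    rows = []
    for st, p in sorted(params.items()):
        a_ci = f" ({fmt(p.alpha_ci[0])}-{fmt(p.alpha_ci[1])})" if p.alpha_ci else ""
        b_ci = f" ({fmt(p.beta_ci[0])}-{fmt(p.beta_ci[1])})" if p.beta_ci else ""
        rows.append(
            {
                "t_stage": st,
                "alpha (95% CI)": fmt(p.alpha) + a_ci,
                "beta (95% CI)": fmt(p.beta) + b_ci,
            }
        )
    return pd.DataFrame(rows)
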