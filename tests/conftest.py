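import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nodalstaging as ns
from nodalstaging.reference import NODAL_CROSSTAB, STAGE_PARAMS, positive_fraction

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stage_params():
    """Published stage-specific (alpha, beta) parameter sets."""
    return STAGE_PARAMS


@pytest.fixture(scope="session")
def stage_prevalence():
    """Node-positive fractions per stage from the published counts."""
    return {st: positive_fraction(st) for st in NODAL_CROSSTAB}


@pytest.fixture(scope="session")
def small_cohort():
    """Defect-free 561-patient synthetic cohort at the study's scale."""
    cohort, truth = ns.simulate_cohort(ns.SimulationConfig(cohort_size=561, seed=17))
    return cohort, truth


def make_cohort_csv(tmp_path, rows, name="cohort.csv"):
    """Write a cohort CSV from (pid, stage, n_ex, n_pos, months, event) tuples."""
    path = tmp_path / name
    lines = ["patient_id,t_stage,nodes_examined,nodes_positive,survival_months,event"]
    for r in rows:
        lines.append(",".join(str(x) for x in r))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def cohort_csv_factory(tmp_path):
    return lambda rows, name="cohort.csv": make_cohort_csv(tmp_path, rows, name)
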