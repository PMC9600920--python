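"""Patient-level cohort ingestion, validation, stratification and summary.

The canonical interchange format is a one-row-per-patient CSV with a
header.  Malformed rows are never silently dropped: every exclusion is
logged as a ``(patient_id, rule)`` pair so the screening cascade stays
auditable, in the spirit of a consort diagram.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VALID_T_STAGES = ("T1", "T2", "T3", "T4")

MANDATORY_COLUMNS = (
    "patient_id",
    "t_stage",
    "nodes_examined",
    "nodes_positive",
    "survival_months",
    "event",
)


class SchemaError(ValueError):
    """A mandatory column is missing from the input table."""


class EmptyCohortError(ValueError):
    """Validation removed every record; nothing left to analyze."""


@dataclass
class PatientRecord:
    """One patient: T stage, examined/positive node counts, survival outcome.

    ``event`` is 1 for death, 0 for censoring.  ``extras`` carries optional
    demographic labels (sex, age band, tumor size band, site code) as
    opaque strings.
    """

    patient_id: str
    t_stage: str
    nodes_examined: int
    nodes_positive: int
    survival_months: float
    event: int
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class CohortTable:
    """An ordered collection of patients plus the exclusion audit trail."""

    records: list[PatientRecord]
    provenance: str = ""
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, t_stage: str) -> "CohortTable":
        recs = [r for r in self.records if r.t_stage == t_stage]
        return CohortTable(records=recs, provenance=self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "patient_id": r.patient_id,
                "t_stage": r.t_stage,
                "nodes_examined": r.nodes_examined,
                "nodes_positive": r.nodes_positive,
                "survival_months": r.survival_months,
                "event": r.event,
            }
            row.update(r.extras)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class NodeCountStratum:
    """Tallies for one (T stage, examined-node count) cell.

    ``n_node_positive`` counts patients with at least one metastatic node
    (detected disease); ``n_node_negative`` counts patients with zero
    positive nodes — the pool that mixes true negatives with potential
    false negatives.
    """

    t_stage: str
    nodes_examined: int
    n_node_positive: int
    n_node_negative: int

    @property
    def n_total(self) -> int:
        return self.n_node_positive + self.n_node_negative


def _parse_stage(raw) -> str | None:
    s = str(raw).strip().upper()
    if s in VALID_T_STAGES:
        return s
    if s in {"1", "2", "3", "4"}:
        return "T" + s
    return None


def _parse_event(raw) -> int | None:
    s = str(raw).strip().lower()
    if s in {"1", "1.0", "death", "dead", "deceased"}:
        return 1
    if s in {"0", "0.0", "censored", "alive", "censor"}:
        return 0
    return None


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> CohortTable:
    """Read a patient-level CSV into a :class:`CohortTable`.

    Parameters
    ----------
    path
        CSV file with one row per patient and a header line.
    schema
        Optional mapping from canonical column names
        (``patient_id``, ``t_stage``, ``nodes_examined``, ``nodes_positive``,
        ``survival_months``, ``event``) to the file's column names.  Columns
        not covered by the mapping keep their own names and are carried as
        opaque demographic labels.

    Raises
    ------
    SchemaError
        If a mandatory column is absent (the error names it).

    Notes
    -----
    Row-level problems (unparseable stage code, positive count exceeding
    examined count, negative or missing counts) exclude the row and append
    a ``(patient_id, rule)`` entry to ``exclusion_log``.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, dtype=str)
    colmap = {canon: schema.get(canon, canon) for canon in MANDATORY_COLUMNS}
    for canon, col in colmap.items():
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} (for {canon!r}) not found")
    extra_cols = [c for c in df.columns if c not in colmap.values()]

    records: list[PatientRecord] = []
    exclusions: list[tuple[str, str]] = []
    for idx, row in df.iterrows():
        pid = str(row[colmap["patient_id"]]).strip()
        if not pid or pid.lower() == "nan":
            pid = f"row-{idx}"
        stage = _parse_stage(row[colmap["t_stage"]])
        if stage is None:
            exclusions.append((pid, "unstageable"))
            continue
        try:
            n_ex = int(float(row[colmap["nodes_examined"]]))
            n_pos = int(float(row[colmap["nodes_positive"]]))
        except (TypeError, ValueError):
            exclusions.append((pid, "unparseable node counts"))
            continue
        if n_ex < 0 or n_pos < 0:
            exclusions.append((pid, "negative node count"))
            continue
        if n_pos > n_ex:
            exclusions.append((pid, "positive>examined"))
            continue
        try:
            months = float(row[colmap["survival_months"]])
        except (TypeError, ValueError):
            months = float("nan")
        event = _parse_event(row[colmap["event"]])
        extras = {
            c: str(row[c]) for c in extra_cols if not pd.isna(row[c])
        }
        records.append(
            PatientRecord(
                patient_id=pid,
                t_stage=stage,
                nodes_examined=n_ex,
                nodes_positive=n_pos,
                survival_months=months,
                event=-1 if event is None else event,
                extras=extras,
            )
        )
    return CohortTable(
        records=records,
        provenance=provenance or str(path),
        exclusion_log=exclusions,
    )


def validate_cohort(cohort: CohortTable) -> CohortTable:
    """Keep only records usable by the staging model.

    A record is retained when its T stage is known, at least one lymph node
    was examined (a patient with zero examined nodes carries no information
    about nodal status and breaks the false-negative imputation), and the
    survival outcome is complete.

    Raises
    ------
    EmptyCohortError
        If no analyzable records remain.
    """
    kept: list[PatientRecord] = []
    log = list(cohort.exclusion_log)
    for r in cohort.records:
        if r.t_stage not in VALID_T_STAGES:
            log.append((r.patient_id, "unstageable"))
        elif r.nodes_examined < 1:
            log.append((r.patient_id, "no nodes examined"))
        elif not np.isfinite(r.survival_months) or r.survival_months < 0 or r.event not in (0, 1):
            log.append((r.patient_id, "missing survival outcome"))
        else:
            kept.append(r)
    if not kept:
        raise EmptyCohortError("no analyzable records after validation")
    return CohortTable(records=kept, provenance=cohort.provenance, exclusion_log=log)


def stratify_counts(cohort: CohortTable) -> list[NodeCountStratum]:
    """Tally node-positive / node-negative patients per (stage, examined count).

    Node-positive means ``nodes_positive >= 1``.  The strata partition the
    cohort: summed tallies equal the cohort size.
    """
    tally: dict[tuple[str, int], list[int]] = {}
    for r in cohort.records:
        key = (r.t_stage, r.nodes_examined)
        cell = tally.setdefault(key, [0, 0])
        if r.nodes_positive >= 1:
            cell[0] += 1
        else:
            cell[1] += 1
    return [
        NodeCountStratum(t_stage=st, nodes_examined=n, n_node_positive=p, n_node_negative=q)
        for (st, n), (p, q) in sorted(tally.items())
    ]


def _round_half_up(x: float, digits: int = 1) -> float:
    q = decimal.Decimal(10) ** -digits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def summarize_cohort(
    cohort: CohortTable,
    extra_keys: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cross-tabulate the cohort by nodal status, with column percentages.

    Returns a tidy frame with one row per (variable, level): counts and
    within-column percentages for the node-negative and node-positive
    groups, plus formatted ``"count (pct)"`` cells.  Percentages are
    rounded half-up to one decimal.
    """
    neg = [r for r in cohort.records if r.nodes_positive == 0]
    pos = [r for r in cohort.records if r.nodes_positive >= 1]
    n_neg, n_pos = len(neg), len(pos)

    if extra_keys is None:
        keys: list[str] = []
        for r in cohort.records:
            for k in r.extras:
                if k not in keys:
                    keys.append(k)
        extra_keys = keys

    def levels_of(getter) -> list[str]:
        seen: list[str] = []
        for r in cohort.records:
            v = getter(r)
            if v is not None and v not in seen:
                seen.append(v)
        return seen

    variables: list[tuple[str, object]] = [("t_stage", lambda r: r.t_stage)]
    # N-stage proxy from the positive-node count (AJCC 8th ed. cuts)
    def n_stage(r):
        k = r.nodes_positive
        if k == 0:
            return "N0"
        if k <= 2:
            return "N1"
        if k <= 6:
            return "N2"
        return "N3"

    variables.append(("n_stage", n_stage))
    for key in extra_keys:
        variables.append((key, lambda r, key=key: r.extras.get(key)))

    rows = []
    for var, getter in variables:
        for level in sorted(levels_of(getter)):
            c_neg = sum(1 for r in neg if getter(r) == level)
            c_pos = sum(1 for r in pos if getter(r) == level)
            p_neg = _round_half_up(100.0 * c_neg / n_neg) if n_neg else float("nan")
            p_pos = _round_half_up(100.0 * c_pos / n_pos) if n_pos else float("nan")
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "ln_negative_n": c_neg,
                    "ln_negative_pct": p_neg,
                    "ln_negative_cell": f"{c_neg} ({p_neg:.1f})",
                    "ln_positive_n": c_pos,
                    "ln_positive_pct": p_pos,
                    "ln_positive_cell": f"{c_pos} ({p_pos:.1f})",
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_ln_negative"] = n_neg
    out.attrs["n_ln_positive"] = n_pos
    out.attrs["n_total"] = n_neg + n_pos
    return out
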