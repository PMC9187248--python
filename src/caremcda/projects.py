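"""Project records, evidence validation and file I/O.

A :class:`ProjectRecord` bundles everything known about one project: light
metadata (remoteness category, claimed integration levels), one evidence
record per criterion, the cost components, and optionally the named outcome
measures backing each criterion. Named measures must be attached to exactly
one criterion per project — the guard against double-counting an outcome
(e.g. a length-of-stay reduction feeding both capacity and patient
outcomes).

Records round-trip through JSON (nested, the native form) and CSV (one flat
row per project, documented column prefixes). Missing evidence for a
criterion is legal and scores zero under every rubric, with a log message.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .rubric import (
    CRITERIA,
    CapacityEvidence,
    DomainAssessment,
    IntegrationEvidence,
    PatientOutcomeEvidence,
    RiskEvidence,
    RiskMatrix,
    ScoreVector,
    WorkforceEvidence,
    score_capacity,
    score_integration,
    score_patient_outcomes,
    score_risk_evidence,
    score_workforce,
)
from .league import CostRecord, Rounding

logger = logging.getLogger(__name__)

#: geographic remoteness categories used to describe project settings
LOCATIONS = (
    "major_city",
    "major_city_to_inner_regional",
    "inner_regional",
    "outer_regional",
    "remote_to_very_remote",
    "very_remote",
)

INTEGRATION_DOMAINS = ("clinical", "professional", "organisational")


class ProjectRecord(BaseModel):
    """All inputs for one project: metadata, evidence, costs."""

    model_config = ConfigDict(frozen=True)

    project_id: str
    location: Optional[Literal[LOCATIONS]] = None
    key_components: tuple[str, ...] = ()
    claimed_integration_levels: tuple[Literal[INTEGRATION_DOMAINS], ...] = ()
    capacity: Optional[CapacityEvidence] = None
    outcomes: Optional[PatientOutcomeEvidence] = None
    integration: Optional[IntegrationEvidence] = None
    workforce: Optional[WorkforceEvidence] = None
    risk: Optional[RiskEvidence] = None
    cost: CostRecord = CostRecord(budget_spend=0.0)
    outcome_measures: dict[str, tuple[str, ...]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _measures_unique_across_criteria(self) -> "ProjectRecord":
        unknown = set(self.outcome_measures) - set(CRITERIA)
        if unknown:
            raise ValueError(
                f"project {self.project_id!r}: outcome measures attached to "
                f"unknown criteria {sorted(unknown)}"
            )
        seen: dict[str, str] = {}
        for criterion, measures in self.outcome_measures.items():
            for m in measures:
                if m in seen:
                    raise ValueError(
                        f"project {self.project_id!r}: outcome measure {m!r} is "
                        f"attached to both {seen[m]!r} and {criterion!r}; each "
                        "measure may inform exactly one criterion"
                    )
                seen[m] = criterion
        return self


def score_project(
    record: ProjectRecord,
    risk_matrix: RiskMatrix | None = None,
    environment_rule: Literal["ratio", "share"] = "ratio",
) -> ScoreVector:
    """Apply the five rubrics to one project's evidence.

    Criteria with no evidence score zero (the rubrics award points only for
    demonstrated effects, and absence of data is indistinguishable from no
    demonstrated effect in this framework)."""
    from .rubric import DEFAULT_RISK_MATRIX

    matrix = risk_matrix if risk_matrix is not None else DEFAULT_RISK_MATRIX
    missing = [c for c in CRITERIA if getattr(record, c) is None]
    if missing:
        logger.info(
            "project %s: no evidence for %s; scoring 0 there",
            record.project_id, ", ".join(missing),
        )
    return ScoreVector(
        project_id=record.project_id,
        capacity=score_capacity(record.capacity) if record.capacity else 0,
        outcomes=score_patient_outcomes(record.outcomes) if record.outcomes else 0.0,
        integration=score_integration(record.integration) if record.integration else 0.0,
        workforce=score_workforce(record.workforce) if record.workforce else 0,
        risk=(
            score_risk_evidence(record.risk, matrix, environment_rule)
            if record.risk
            else 0.0
        ),
    )


def score_projects(
    records: Sequence[ProjectRecord],
    risk_matrix: RiskMatrix | None = None,
    environment_rule: Literal["ratio", "share"] = "ratio",
) -> list[ScoreVector]:
    return [score_project(r, risk_matrix, environment_rule) for r in records]


def scores_to_frame(scores: Sequence[ScoreVector]) -> pd.DataFrame:
    """One row per project, columns ``project_id`` plus the five criteria."""
    return pd.DataFrame(
        [{"project_id": s.project_id, **s.as_dict()} for s in scores],
        columns=["project_id", *CRITERIA],
    )


# ---------------------------------------------------------------------------
# JSON / CSV serialisation
# ---------------------------------------------------------------------------

_LIST_SEP = ";"


def _flatten(record: ProjectRecord) -> dict:
    row: dict = {
        "project_id": record.project_id,
        "location": record.location or "",
        "key_components": _LIST_SEP.join(record.key_components),
        "claimed_integration_levels": _LIST_SEP.join(record.claimed_integration_levels),
    }
    ev = record.capacity
    row["capacity_effect_direction"] = ev.effect_direction if ev else ""
    row["capacity_significant"] = ev.significant if ev else ""
    row["capacity_p_value"] = ev.p_value if ev and ev.p_value is not None else ""
    ev = record.outcomes
    row["outcomes_satisfaction"] = ev.satisfaction if ev else ""
    row["outcomes_quality_of_life"] = ev.quality_of_life if ev else ""
    row["outcomes_access_improved"] = ev.access_improved if ev else ""
    ev = record.integration
    for d in INTEGRATION_DOMAINS:
        a = getattr(ev, d) if ev else None
        row[f"integration_{d}_evaluator_1"] = a.evaluator_1 if a else ""
        row[f"integration_{d}_evaluator_2"] = a.evaluator_2 if a else ""
    ev = record.workforce
    row["workforce_upskilled"] = ev.upskilled if ev else ""
    row["workforce_satisfaction_improved"] = ev.satisfaction_improved if ev else ""
    row["workforce_worsened"] = ev.workload_or_satisfaction_worsened if ev else ""
    ev = record.risk
    row["risk_n_facilitators"] = ev.n_facilitators if ev else ""
    row["risk_n_barriers"] = ev.n_barriers if ev else ""
    row["risk_objectives_achieved"] = ev.objectives_achieved if ev else ""
    row["risk_objectives_total"] = ev.objectives_total if ev else ""
    c = record.cost
    row["cost_budget_spend"] = c.budget_spend
    row["cost_retained_funds"] = c.retained_funds
    row["cost_in_kind_value"] = c.in_kind_value
    row["cost_non_capacity_savings"] = c.non_capacity_savings
    row["outcome_measures"] = json.dumps(
        {k: list(v) for k, v in record.outcome_measures.items()}
    ) if record.outcome_measures else ""
    return row


def _is_blank(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == ""


def _as_bool(v) -> bool:
    return str(v).strip().lower() in ("true", "1", "yes")


def _unflatten(row: dict) -> ProjectRecord:
    def get(key):
        return row.get(key)

    capacity = None
    if not _is_blank(get("capacity_effect_direction")):
        capacity = CapacityEvidence(
            effect_direction=str(get("capacity_effect_direction")),
            significant=str(get("capacity_significant") or "unknown"),
            p_value=(
                None if _is_blank(get("capacity_p_value"))
                else float(get("capacity_p_value"))
            ),
        )
    outcomes = None
    if not all(
        _is_blank(get(k))
        for k in ("outcomes_satisfaction", "outcomes_quality_of_life",
                  "outcomes_access_improved")
    ):
        outcomes = PatientOutcomeEvidence(
            satisfaction=str(get("outcomes_satisfaction") or "none"),
            quality_of_life=str(get("outcomes_quality_of_life") or "none"),
            access_improved=_as_bool(get("outcomes_access_improved")),
        )
    integration = None
    if not all(
        _is_blank(get(f"integration_{d}_evaluator_{e}"))
        for d in INTEGRATION_DOMAINS for e in (1, 2)
    ):
        integration = IntegrationEvidence(
            **{
                d: DomainAssessment(
                    evaluator_1=str(get(f"integration_{d}_evaluator_1") or "none"),
                    evaluator_2=str(get(f"integration_{d}_evaluator_2") or "none"),
                )
                for d in INTEGRATION_DOMAINS
            }
        )
    workforce = None
    if not all(
        _is_blank(get(k))
        for k in ("workforce_upskilled", "workforce_satisfaction_improved",
                  "workforce_worsened")
    ):
        workforce = WorkforceEvidence(
            upskilled=_as_bool(get("workforce_upskilled")),
            satisfaction_improved=_as_bool(get("workforce_satisfaction_improved")),
            workload_or_satisfaction_worsened=_as_bool(get("workforce_worsened")),
        )
    risk = None
    if not _is_blank(get("risk_n_facilitators")):
        risk = RiskEvidence(
            n_facilitators=int(float(get("risk_n_facilitators"))),
            n_barriers=int(float(get("risk_n_barriers"))),
            objectives_achieved=int(float(get("risk_objectives_achieved"))),
            objectives_total=int(float(get("risk_objectives_total"))),
        )
    cost = CostRecord(
        budget_spend=float(get("cost_budget_spend") or 0),
        retained_funds=float(get("cost_retained_funds") or 0),
        in_kind_value=float(get("cost_in_kind_value") or 0),
        non_capacity_savings=float(get("cost_non_capacity_savings") or 0),
    )
    measures = {}
    if not _is_blank(get("outcome_measures")):
        measures = {
            k: tuple(v) for k, v in json.loads(str(get("outcome_measures"))).items()
        }
    return ProjectRecord(
        project_id=str(get("project_id")),
        location=None if _is_blank(get("location")) else str(get("location")),
        key_components=tuple(
            s for s in str(get("key_components") or "").split(_LIST_SEP) if s
        ),
        claimed_integration_levels=tuple(
            s for s in str(get("claimed_integration_levels") or "").split(_LIST_SEP) if s
        ),
        capacity=capacity,
        outcomes=outcomes,
        integration=integration,
        workforce=workforce,
        risk=risk,
        cost=cost,
        outcome_measures=measures,
    )


def load_projects(path: str | Path) -> list[ProjectRecord]:
    """Load project records from a JSON file (nested records, possibly under
    a top-level ``projects`` key) or a flat CSV file.

    Validation failures raise with the project id and offending field;
    duplicate project ids are rejected; an empty file yields an empty list
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        text = path.read_text(encoding="utf-8").strip()
        if not text:
            logger.warning("%s is empty; no projects loaded", path)
            return []
        payload = json.loads(text)
        if isinstance(payload, dict):
            payload = payload.get("projects", [])
        records = [ProjectRecord.model_validate(item) for item in payload]
    elif path.suffix.lower() == ".csv":
        try:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            logger.warning("%s is empty; no projects loaded", path)
            return []
        records = [_unflatten(row) for row in df.to_dict("records")]
    else:
        raise ValueError(f"unsupported project file format: {path.suffix!r}")
    if not records:
        logger.warning("%s contains no project records", path)
    ids = [r.project_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate project ids: {sorted(dupes)}")
    return records


def write_projects(records: Sequence[ProjectRecord], path: str | Path) -> Path:
    """Write project records to JSON or CSV (chosen by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {"projects": [r.model_dump(mode="json") for r in records]}
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    elif path.suffix.lower() == ".csv":
        pd.DataFrame([_flatten(r) for r in records]).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported project file format: {path.suffix!r}")
    return path


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


class RunConfig(BaseModel):
    """Validated knobs for a pipeline run.

    ``risk_matrix`` is given as nested mapping environment -> success ->
    score and must respect the anchored corners; ``schemes`` entries use the
    weight-scheme config form (see :func:`caremcda.weighting.scheme_from_config`).
    """

    rounding: Rounding = "exact"
    environment_rule: Literal["ratio", "share"] = "ratio"
    risk_matrix: Optional[dict[str, dict[str, float]]] = None
    schemes: list[dict] = Field(default_factory=lambda: [{"method": "equal"}])
    output_dir: Path = Path(".")
    seed: int = 0

    @model_validator(mode="after")
    def _validate_matrix_and_schemes(self) -> "RunConfig":
        self.build_risk_matrix()
        if not self.schemes:
            raise ValueError("at least one weight scheme is required")
        for cfg in self.schemes:
            from .weighting import scheme_from_config

            scheme_from_config(cfg)
        return self

    def build_risk_matrix(self) -> RiskMatrix:
        if self.risk_matrix is None:
            return RiskMatrix()
        cells = {
            (env, suc): float(v)
            for env, row in self.risk_matrix.items()
            for suc, v in row.items()
        }
        return RiskMatrix(cells)

    def build_schemes(self):
        from .weighting import scheme_from_config

        return [scheme_from_config(cfg) for cfg in self.schemes]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)
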