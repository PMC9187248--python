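"""Evidence-to-score rubrics for the five evaluation criteria.

Each integrated-care project is scored on five criteria — health-service
capacity, patient outcomes, integration of care, workforce development and
organisational (implementation) risk — on a common 0–2 scale so that the
criteria can be weighted and summed into a single benefit score.

The rubrics are deliberately coarse: they transform structured evidence
(effect directions, significance flags, evaluator judgements, facilitator and
barrier tallies) into discrete scores, trading sensitivity to effect size for
comparability across very heterogeneous projects.

Score supports
--------------
capacity, workforce   {0, 1, 2}
patient outcomes      {0, 0.4, 0.8, 1.2, 1.6, 2.0}   (raw 0–5 points x 2/5)
integration           {k/3 : k = 0..6}               (0–6 domain points / 3)
risk                  {0, 0.5, 1.0, 1.5, 2.0}        (3x3 risk matrix)
"""

from __future__ import annotations

import logging
import warnings
from enum import Enum
from fractions import Fraction
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger(__name__)

CRITERIA = ("capacity", "outcomes", "integration", "workforce", "risk")

SIGNIFICANCE_ALPHA = 0.05

#: levels used by the three-point ordinal scales
EffectDirection = Literal["reduction", "none", "mixed"]
Significance = Literal["yes", "no", "unknown"]
OutcomeLevel = Literal["none", "observed", "significant"]
DomainJudgement = Literal["none", "partial", "full"]

_OUTCOME_POINTS = {"none": 0, "observed": 1, "significant": 2}


class Environment(str, Enum):
    """Implementation environment from the facilitator/barrier balance."""

    SUPPORTIVE = "supportive"
    BALANCED = "balanced"
    HOSTILE = "hostile"


class Success(str, Enum):
    """Implementation success from the fraction of objectives achieved."""

    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"


class EvaluatorDisagreement(UserWarning):
    """Two evaluators returned full vs none for the same integration domain."""


# ---------------------------------------------------------------------------
# evidence records
# ---------------------------------------------------------------------------


class CapacityEvidence(BaseModel):
    """Service-use change evidence for the health-service-capacity criterion.

    ``effect_direction`` records whether acute/emergency utilisation fell
    (``reduction``), was unchanged (``none``), or fell in one setting while
    rising in another without proof of net benefit (``mixed``).
    ``significant`` is the p < 0.05 verdict of the underlying test; ``unknown``
    covers evaluations that did not report enough to judge.
    """

    model_config = ConfigDict(frozen=True)

    effect_direction: EffectDirection
    significant: Significance = "unknown"
    p_value: Optional[float] = Field(default=None, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _p_value_consistent(self) -> "CapacityEvidence":
        if self.p_value is None:
            return self
        if self.significant == "unknown":
            raise ValueError("a p-value was supplied but significance is 'unknown'")
        if self.significant == "yes" and not self.p_value < SIGNIFICANCE_ALPHA:
            raise ValueError(
                f"significant='yes' requires p < {SIGNIFICANCE_ALPHA}, got {self.p_value}"
            )
        if self.significant == "no" and self.p_value < SIGNIFICANCE_ALPHA:
            raise ValueError(
                f"significant='no' requires p >= {SIGNIFICANCE_ALPHA}, got {self.p_value}"
            )
        return self


class PatientOutcomeEvidence(BaseModel):
    """Patient satisfaction, health-related quality of life and access.

    Satisfaction and quality of life are scored none/observed/significant
    (0/1/2 raw points); access is binary (1 point for a perceived
    improvement). Raw points (0–5) are rescaled by 2/5 to the common scale.
    """

    model_config = ConfigDict(frozen=True)

    satisfaction: OutcomeLevel = "none"
    quality_of_life: OutcomeLevel = "none"
    access_improved: bool = False

    @property
    def raw_points(self) -> int:
        return (
            _OUTCOME_POINTS[self.satisfaction]
            + _OUTCOME_POINTS[self.quality_of_life]
            + int(self.access_improved)
        )


class DomainAssessment(BaseModel):
    """Two independent evaluators' judgements for one integration domain."""

    model_config = ConfigDict(frozen=True)

    evaluator_1: DomainJudgement = "none"
    evaluator_2: DomainJudgement = "none"


class IntegrationEvidence(BaseModel):
    """Evaluator judgements across the clinical, professional and
    organisational domains of integrated care."""

    model_config = ConfigDict(frozen=True)

    clinical: DomainAssessment = DomainAssessment()
    professional: DomainAssessment = DomainAssessment()
    organisational: DomainAssessment = DomainAssessment()

    def domains(self) -> dict[str, DomainAssessment]:
        return {
            "clinical": self.clinical,
            "professional": self.professional,
            "organisational": self.organisational,
        }


class WorkforceEvidence(BaseModel):
    """Provider upskilling and satisfaction evidence.

    ``workload_or_satisfaction_worsened`` dominates: a project that upskilled
    providers at the expense of higher workload or lower self-satisfaction
    scores zero regardless of the other flags.
    """

    model_config = ConfigDict(frozen=True)

    upskilled: bool = False
    satisfaction_improved: bool = False
    workload_or_satisfaction_worsened: bool = False


class RiskEvidence(BaseModel):
    """Tally-level inputs to the organisational-risk matrix.

    Facilitators and barriers are counts of coded implementation determinants
    (CFIR-style); objectives are the project's stated implementation
    objectives and how many were achieved.
    """

    model_config = ConfigDict(frozen=True)

    n_facilitators: int = Field(ge=0)
    n_barriers: int = Field(ge=0)
    objectives_achieved: int = Field(ge=0)
    objectives_total: int = Field(ge=1)

    @model_validator(mode="after")
    def _achieved_le_total(self) -> "RiskEvidence":
        if self.objectives_achieved > self.objectives_total:
            raise ValueError("objectives_achieved exceeds objectives_total")
        return self


# ---------------------------------------------------------------------------
# risk matrix
# ---------------------------------------------------------------------------

_ENV_LEVEL = {Environment.HOSTILE: 0, Environment.BALANCED: 1, Environment.SUPPORTIVE: 2}
_SUCCESS_LEVEL = {Success.LOW: 0, Success.MODERATE: 1, Success.HIGH: 2}
_RISK_VALUES = {0.0, 0.5, 1.0, 1.5, 2.0}


class RiskMatrix:
    """3x3 map from (environment, success) to a risk score in 0.5 steps.

    The two anchored corners are fixed by construction of the scale:
    (supportive, high) -> 2 and (hostile, low) -> 0. The default matrix is
    additive, score = (environment level + success level) / 2, which keeps
    every off-corner cell in {0.5, 1.0, 1.5}. Alternative matrices may be
    supplied but must respect the corners and the 0–2 / 0.5-step range.
    """

    def __init__(self, cells: dict[tuple[Environment, Success], float] | None = None):
        if cells is None:
            cells = {
                (env, suc): (_ENV_LEVEL[env] + _SUCCESS_LEVEL[suc]) / 2
                for env in Environment
                for suc in Success
            }
        else:
            cells = {
                (Environment(env), Success(suc)): float(v)
                for (env, suc), v in cells.items()
            }
        missing = {
            (env, suc) for env in Environment for suc in Success
        } - set(cells)
        if missing:
            raise ValueError(f"risk matrix missing cells: {sorted(missing)}")
        bad = {k: v for k, v in cells.items() if v not in _RISK_VALUES}
        if bad:
            raise ValueError(f"risk matrix cells outside {{0,0.5,1,1.5,2}}: {bad}")
        if cells[(Environment.SUPPORTIVE, Success.HIGH)] != 2.0:
            raise ValueError("risk matrix must map (supportive, high) to 2")
        if cells[(Environment.HOSTILE, Success.LOW)] != 0.0:
            raise ValueError("risk matrix must map (hostile, low) to 0")
        self._cells = cells

    def __getitem__(self, key: tuple[Environment | str, Success | str]) -> float:
        env, suc = key
        return self._cells[(Environment(env), Success(suc))]

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {(e.value, s.value): v for (e, s), v in self._cells.items()}


DEFAULT_RISK_MATRIX = RiskMatrix()


# ---------------------------------------------------------------------------
# scoring operations
# ---------------------------------------------------------------------------


def score_capacity(ev: CapacityEvidence) -> int:
    """Score the health-service-capacity criterion.

    2 — statistically significant reduction in acute service use;
    1 — reduction observed but not significant (or significance unknown);
    0 — no savings, or a mixed shift between settings.
    """
    if ev.effect_direction != "reduction":
        return 0
    return 2 if ev.significant == "yes" else 1


def score_patient_outcomes(ev: PatientOutcomeEvidence) -> float:
    """Score patient outcomes: (satisfaction + QoL + access points) x 2/5."""
    return ev.raw_points * 2.0 / 5.0


def _domain_points(name: str, a: DomainAssessment) -> int:
    j1, j2 = a.evaluator_1, a.evaluator_2
    if "none" in (j1, j2):
        if {j1, j2} == {"none", "full"}:
            # full-vs-none disagreement resolves conservatively to zero
            warnings.warn(
                f"evaluators disagree (full vs none) on {name} integration; "
                "scoring 0",
                EvaluatorDisagreement,
                stacklevel=3,
            )
        return 0
    if j1 == j2 == "full":
        return 2
    return 1  # agreed partial, or mixed full/partial


def score_integration(ev: IntegrationEvidence) -> float:
    """Score integration of care: domain points (0/1/2 each) summed over the
    clinical, professional and organisational domains, divided by three.

    Both evaluators must judge a domain fully integrated for 2 points; agreed
    partial (or one full / one partial) earns 1; any ``none`` judgement earns
    0, with a warning when the disagreement is full-vs-none.
    """
    return sum(_domain_points(n, a) for n, a in ev.domains().items()) / 3.0


def integration_points_exact(ev: IntegrationEvidence) -> Fraction:
    """Integration score as an exact fraction (thirds), for rounding studies."""
    return Fraction(sum(_domain_points(n, a) for n, a in ev.domains().items()), 3)


def score_workforce(ev: WorkforceEvidence) -> int:
    """Score workforce development.

    0 if workload or self-satisfaction worsened; otherwise 2 when providers
    were both upskilled and more satisfied, 1 when exactly one of the two
    held, 0 when neither did.
    """
    if ev.workload_or_satisfaction_worsened:
        return 0
    return int(ev.upskilled) + int(ev.satisfaction_improved)


def classify_environment(
    n_facilitators: int,
    n_barriers: int,
    rule: Literal["ratio", "share"] = "ratio",
) -> Environment:
    """Classify the implementation environment from determinant tallies.

    A project is ``supportive`` when facilitators outweigh barriers by more
    than 25 % and ``hostile`` in the mirror case; anything else (including no
    coded determinants at all) is ``balanced``.

    Two readings of "outweigh by more than 25 %" are provided: the default
    ``ratio`` rule F > 1.25 B, and the ``share`` rule
    (F - B) / (F + B) > 0.25.
    """
    f, b = n_facilitators, n_barriers
    if f < 0 or b < 0:
        raise ValueError("facilitator/barrier counts must be non-negative")
    if rule == "ratio":
        if f > 1.25 * b:
            return Environment.SUPPORTIVE
        if b > 1.25 * f:
            return Environment.HOSTILE
        return Environment.BALANCED
    if rule == "share":
        if f + b == 0:
            return Environment.BALANCED
        share = (f - b) / (f + b)
        if share > 0.25:
            return Environment.SUPPORTIVE
        if share < -0.25:
            return Environment.HOSTILE
        return Environment.BALANCED
    raise ValueError(f"unknown environment rule: {rule!r}")


def classify_success(objectives_achieved: int, objectives_total: int) -> Success:
    """Classify implementation success from the objective-achievement fraction.

    ``high`` for strictly more than 2/3 achieved, ``low`` for strictly less
    than 1/3; the boundaries themselves fall to ``moderate``.
    """
    if objectives_total < 1:
        raise ValueError("objectives_total must be at least 1")
    if objectives_achieved > objectives_total or objectives_achieved < 0:
        raise ValueError("objectives_achieved must lie in [0, objectives_total]")
    frac = Fraction(objectives_achieved, objectives_total)
    if frac > Fraction(2, 3):
        return Success.HIGH
    if frac < Fraction(1, 3):
        return Success.LOW
    return Success.MODERATE


def score_risk(
    env: Environment | str,
    success: Success | str,
    matrix: RiskMatrix = DEFAULT_RISK_MATRIX,
) -> float:
    """Look up the organisational-risk score for an (environment, success)
    cell of the risk matrix. Higher scores mean lower implementation risk."""
    return matrix[(env, success)]


def score_risk_evidence(
    ev: RiskEvidence,
    matrix: RiskMatrix = DEFAULT_RISK_MATRIX,
    environment_rule: Literal["ratio", "share"] = "ratio",
) -> float:
    """Classify tallies and objectives, then apply the risk matrix."""
    env = classify_environment(ev.n_facilitators, ev.n_barriers, rule=environment_rule)
    suc = classify_success(ev.objectives_achieved, ev.objectives_total)
    return score_risk(env, suc, matrix)


# ---------------------------------------------------------------------------
# score vector
# ---------------------------------------------------------------------------

_OUTCOME_SUPPORT = {round(k * 0.4, 1) for k in range(6)}
_RISK_SUPPORT = _RISK_VALUES
_TOL = 1e-9


class ScoreVector(BaseModel):
    """The five criterion scores for one project, each on the 0–2 scale."""

    model_config = ConfigDict(frozen=True)

    project_id: str
    capacity: float = Field(ge=0, le=2)
    outcomes: float = Field(ge=0, le=2)
    integration: float = Field(ge=0, le=2)
    workforce: float = Field(ge=0, le=2)
    risk: float = Field(ge=0, le=2)

    @model_validator(mode="after")
    def _supports(self) -> "ScoreVector":
        if self.capacity not in (0, 1, 2):
            raise ValueError(f"capacity score {self.capacity} not in {{0,1,2}}")
        if self.workforce not in (0, 1, 2):
            raise ValueError(f"workforce score {self.workforce} not in {{0,1,2}}")
        if min(abs(self.outcomes - v) for v in _OUTCOME_SUPPORT) > _TOL:
            raise ValueError(f"outcomes score {self.outcomes} not a multiple of 0.4")
        if min(abs(self.integration - k / 3) for k in range(7)) > _TOL:
            raise ValueError(f"integration score {self.integration} not a multiple of 1/3")
        if self.risk not in _RISK_SUPPORT:
            raise ValueError(f"risk score {self.risk} not a multiple of 0.5 in [0,2]")
        return self

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in CRITERIA}
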