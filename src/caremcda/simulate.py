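"""Seeded generation of rubric-valid synthetic project portfolios.

The generator draws one evidence record per criterion per project,
independently across criteria, so that any portfolio it emits is legal
input for the scoring pipeline. Defaults emulate a small state-funded
integrated-care portfolio: roughly a third of projects achieve a
statistically significant capacity improvement, roughly two thirds show
some workforce development, implementation determinants arrive as Poisson
tallies with facilitators slightly outnumbering barriers, and net costs are
log-normal in the hundreds of thousands to low millions of AUD.

All randomness flows through ``GeneratorConfig.seed``; equal configs give
byte-identical portfolios.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .league import CostRecord
from .projects import INTEGRATION_DOMAINS, LOCATIONS, ProjectRecord
from .rubric import (
    CapacityEvidence,
    DomainAssessment,
    IntegrationEvidence,
    PatientOutcomeEvidence,
    RiskEvidence,
    WorkforceEvidence,
)


def _probability_vector(v: Sequence[float], k: int, name: str) -> tuple[float, ...]:
    v = tuple(float(x) for x in v)
    if len(v) != k:
        raise ValueError(f"{name} must have {k} entries")
    if any(x < 0 for x in v) or sum(v) > 1 + 1e-12:
        raise ValueError(f"{name} entries must be non-negative and sum to at most 1")
    return v


class GeneratorConfig(BaseModel):
    """Branch probabilities and cost distribution for the generator.

    Ordinal probability vectors give P(observed), P(significant) etc.; the
    remaining mass goes to the weakest branch, so setting every probability
    to zero produces evidence with no demonstrated effects anywhere.
    """

    model_config = ConfigDict(frozen=True)

    n_projects: int = Field(default=17, ge=1)
    seed: int = 0

    # capacity: P(reduction), P(mixed); remainder = no change
    p_capacity_reduction: float = Field(default=0.55, ge=0, le=1)
    p_capacity_mixed: float = Field(default=0.15, ge=0, le=1)
    # significance given a reduction: P(yes), P(unknown); remainder = no
    p_capacity_significant: float = Field(default=0.6, ge=0, le=1)
    p_capacity_sig_unknown: float = Field(default=0.1, ge=0, le=1)

    # patient outcomes: (P(observed), P(significant)) per instrument
    p_satisfaction: tuple[float, float] = (0.15, 0.05)
    p_quality_of_life: tuple[float, float] = (0.25, 0.3)
    p_access: float = Field(default=0.6, ge=0, le=1)

    # integration per domain: (P(partial), P(full)); remainder = none
    p_domain: tuple[float, float] = (0.15, 0.5)

    # workforce
    p_upskilled: float = Field(default=0.6, ge=0, le=1)
    p_satisfaction_improved: float = Field(default=0.3, ge=0, le=1)
    p_worsened: float = Field(default=0.05, ge=0, le=1)

    # risk: Poisson tally means, objective count range, achievement prob
    facilitator_rate: float = Field(default=8.0, ge=0)
    barrier_rate: float = Field(default=6.0, ge=0)
    objectives_range: tuple[int, int] = (6, 12)
    p_objective_achieved: float = Field(default=0.6, ge=0, le=1)

    # net cost ~ LogNormal(log_mean, log_sigma), AUD
    cost_log_mean: float = 13.5
    cost_log_sigma: float = Field(default=0.8, ge=0)

    @model_validator(mode="after")
    def _vectors_valid(self) -> "GeneratorConfig":
        _probability_vector(
            (self.p_capacity_reduction, self.p_capacity_mixed), 2, "capacity direction"
        )
        _probability_vector(
            (self.p_capacity_significant, self.p_capacity_sig_unknown),
            2, "capacity significance",
        )
        _probability_vector(self.p_satisfaction, 2, "p_satisfaction")
        _probability_vector(self.p_quality_of_life, 2, "p_quality_of_life")
        _probability_vector(self.p_domain, 2, "p_domain")
        lo, hi = self.objectives_range
        if lo < 1 or hi < lo:
            raise ValueError("objectives_range must satisfy 1 <= low <= high")
        return self


def _ordinal(rng: np.random.Generator, p_mid: float, p_top: float) -> str:
    u = rng.random()
    if u < p_top:
        return "significant"
    if u < p_top + p_mid:
        return "observed"
    return "none"


def _judgement(rng: np.random.Generator, p_partial: float, p_full: float) -> str:
    u = rng.random()
    if u < p_full:
        return "full"
    if u < p_full + p_partial:
        return "partial"
    return "none"


def simulate_projects(cfg: GeneratorConfig) -> list[ProjectRecord]:
    """Draw a reproducible portfolio of ``cfg.n_projects`` synthetic projects."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    for i in range(1, cfg.n_projects + 1):
        u = rng.random()
        if u < cfg.p_capacity_reduction:
            direction = "reduction"
        elif u < cfg.p_capacity_reduction + cfg.p_capacity_mixed:
            direction = "mixed"
        else:
            direction = "none"
        if direction == "reduction":
            v = rng.random()
            if v < cfg.p_capacity_significant:
                significant = "yes"
            elif v < cfg.p_capacity_significant + cfg.p_capacity_sig_unknown:
                significant = "unknown"
            else:
                significant = "no"
        else:
            significant = "unknown"
        capacity = CapacityEvidence(effect_direction=direction, significant=significant)

        outcomes = PatientOutcomeEvidence(
            satisfaction=_ordinal(rng, *cfg.p_satisfaction),
            quality_of_life=_ordinal(rng, *cfg.p_quality_of_life),
            access_improved=bool(rng.random() < cfg.p_access),
        )

        integration = IntegrationEvidence(
            **{
                d: DomainAssessment(
                    evaluator_1=(level := _judgement(rng, *cfg.p_domain)),
                    evaluator_2=level,
                )
                for d in INTEGRATION_DOMAINS
            }
        )

        workforce = WorkforceEvidence(
            upskilled=bool(rng.random() < cfg.p_upskilled),
            satisfaction_improved=bool(rng.random() < cfg.p_satisfaction_improved),
            workload_or_satisfaction_worsened=bool(rng.random() < cfg.p_worsened),
        )

        lo, hi = cfg.objectives_range
        total = int(rng.integers(lo, hi + 1))
        risk = RiskEvidence(
            n_facilitators=int(rng.poisson(cfg.facilitator_rate)),
            n_barriers=int(rng.poisson(cfg.barrier_rate)),
            objectives_achieved=int(rng.binomial(total, cfg.p_objective_achieved)),
            objectives_total=total,
        )

        cost = CostRecord(
            budget_spend=round(
                float(rng.lognormal(cfg.cost_log_mean, cfg.cost_log_sigma)), 2
            )
        )

        records.append(
            ProjectRecord(
                project_id=str(i),
                location=LOCATIONS[int(rng.integers(len(LOCATIONS)))],
                capacity=capacity,
                outcomes=outcomes,
                integration=integration,
                workforce=workforce,
                risk=risk,
                cost=cost,
            )
        )
    return records
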