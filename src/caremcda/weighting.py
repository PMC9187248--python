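"""Criteria weight schemes: equal, direct, and rank-based surrogate weights.

Stakeholders often find it easier to rank criteria than to state numeric
weights. The surrogate-weight transforms here convert an ordinal ranking
(ties allowed) into positive weights:

rank sum              w_c ∝ n + 1 - r_c
rank reciprocal       w_c ∝ 1 / r_c
rank-order centroid   w_c ∝ (1/n) Σ_{j=r_c..n} 1/j

Tied ranks are averaged (fractional ranks) before the transform; the
rank-order-centroid formula is extended to fractional ranks by linear
interpolation between the integer-rank centroid weights, which for a tie of
adjacent ranks equals averaging the tied positions' weights.

Weights are normalised so that they sum to the number of criteria (mean
weight 1). The equal scheme therefore assigns weight 1 to every criterion
and reproduces plain unweighted score sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .rubric import CRITERIA

RankMethod = Literal["rank_sum", "rank_reciprocal", "rank_order_centroid"]
WeightSource = Literal["equal", "direct", "rank_sum", "rank_reciprocal", "rank_order_centroid"]

DEFAULT_RANK_METHOD: RankMethod = "rank_order_centroid"


@dataclass(frozen=True)
class WeightScheme:
    """A labelled, positive weight per criterion, normalised to mean 1."""

    label: str
    weights: dict[str, float]
    source: WeightSource = "direct"

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("weight scheme needs at least one criterion")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all weights must be strictly positive")
        total = sum(self.weights.values())
        n = len(self.weights)
        if abs(total - n) > 1e-9 * n:
            object.__setattr__(
                self, "weights", {c: w * n / total for c, w in self.weights.items()}
            )

    @property
    def criteria(self) -> tuple[str, ...]:
        return tuple(self.weights)

    def __getitem__(self, criterion: str) -> float:
        return self.weights[criterion]


def equal_weights(criteria: Sequence[str] = CRITERIA, label: str = "equal") -> WeightScheme:
    """The equal-importance scheme: weight 1 for every criterion."""
    if len(criteria) == 0:
        raise ValueError("criteria list must be non-empty")
    return WeightScheme(label=label, weights={c: 1.0 for c in criteria}, source="equal")


def average_tied_ranks(ranks: Mapping[str, float]) -> dict[str, float]:
    """Convert a ranking with ties into fractional average ranks.

    Input ranks only need to encode the ordering (e.g. two criteria both
    given rank 1); output ranks are the standard tie-averaged positions
    (the two joint-first criteria get 1.5 each).
    """
    names = list(ranks)
    averaged = rankdata([ranks[c] for c in names], method="average")
    return {c: float(r) for c, r in zip(names, averaged)}


def _centroid_weight(r: float, n: int) -> float:
    """Rank-order-centroid raw weight at (possibly fractional) rank r."""
    grid = np.array([sum(1.0 / j for j in range(k, n + 1)) / n for k in range(1, n + 1)])
    return float(np.interp(r, np.arange(1, n + 1), grid))


def weights_from_ranks(
    ranks: Mapping[str, float],
    method: RankMethod = DEFAULT_RANK_METHOD,
    label: str | None = None,
) -> WeightScheme:
    """Derive a surrogate-weight scheme from an ordinal criteria ranking.

    Ties are averaged before the transform; raw weights are rescaled to sum
    to the number of criteria. Each transform is rank-order preserving, and
    an all-tied ranking maps to equal weights under every method.
    """
    if not ranks:
        raise ValueError("ranking must cover at least one criterion")
    if any(r <= 0 for r in ranks.values()):
        raise ValueError("ranks must be positive")
    avg = average_tied_ranks(ranks)
    n = len(avg)
    if method == "rank_sum":
        raw = {c: n + 1 - r for c, r in avg.items()}
    elif method == "rank_reciprocal":
        raw = {c: 1.0 / r for c, r in avg.items()}
    elif method == "rank_order_centroid":
        raw = {c: _centroid_weight(r, n) for c, r in avg.items()}
    else:
        raise ValueError(f"unknown rank-to-weight method: {method!r}")
    return WeightScheme(
        label=label or method, weights=raw, source=method
    )


def standard_lenses(
    method: RankMethod = DEFAULT_RANK_METHOD,
    criteria: Sequence[str] = CRITERIA,
) -> list[WeightScheme]:
    """The four bundled weighting lenses used for sensitivity analysis.

    * ``equal`` — all criteria weighted 1 (the base case);
    * ``quantitative`` — criteria ranked by the strength of quantitative
      evidence behind them: capacity, outcomes, workforce, integration, risk
      as ranks 1–5;
    * ``qualitative`` — the reverse ordering;
    * ``stakeholder_perception`` — capacity and patient outcomes joint first
      (averaged rank 1.5), then risk, workforce, integration.
    """
    quant = {"capacity": 1, "outcomes": 2, "workforce": 3, "integration": 4, "risk": 5}
    qual = {c: 6 - r for c, r in quant.items()}
    percep = {"capacity": 1, "outcomes": 1, "risk": 3, "workforce": 4, "integration": 5}
    return [
        equal_weights(criteria),
        weights_from_ranks(quant, method=method, label="quantitative"),
        weights_from_ranks(qual, method=method, label="qualitative"),
        weights_from_ranks(percep, method=method, label="stakeholder_perception"),
    ]


def scheme_from_config(cfg: Mapping) -> WeightScheme:
    """Build a scheme from a config mapping.

    Accepted forms::

        {label: ..., weights: {criterion: w, ...}}
        {label: ..., method: rank_sum|rank_reciprocal|rank_order_centroid,
         ranks: {criterion: r, ...}}
        {label: ..., method: equal, criteria: [...]}   # criteria optional
    """
    label = cfg.get("label")
    if "weights" in cfg:
        return WeightScheme(label=label or "direct", weights=dict(cfg["weights"]))
    method = cfg.get("method", DEFAULT_RANK_METHOD)
    if method == "equal":
        return equal_weights(cfg.get("criteria", CRITERIA), label=label or "equal")
    if "ranks" not in cfg:
        raise ValueError("scheme config needs 'weights', 'ranks', or method 'equal'")
    return weights_from_ranks(dict(cfg["ranks"]), method=method, label=label)


def scheme_to_config(scheme: WeightScheme) -> dict:
    """Serialise a scheme to the config mapping form (weights always given)."""
    return {
        "label": scheme.label,
        "source": scheme.source,
        "weights": dict(scheme.weights),
    }
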