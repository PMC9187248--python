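"""Cost-per-point league tables, dominance frontier and weight sensitivity.

A project's benefit is the weighted sum of its five criterion scores,
T = Σ_c w_c s_c; its value for money is the net implementation cost divided
by that total, V = C / T (AUD per point, lower is better). Projects are
ranked by ascending V, and the non-dominated set on the (T, C) plane — no
other project scores at least as high for no more cost — forms the
cost-effectiveness frontier.

Two totalling modes are provided. ``exact`` keeps full precision (the
library default). ``1dp`` first rounds each criterion score to one decimal
place, matching how published league tables print component scores, so that
totals and cost-per-point agree with a table whose fractions were rounded
before summation.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy.stats import rankdata

from .rubric import CRITERIA, ScoreVector
from .weighting import WeightScheme

logger = logging.getLogger(__name__)

Rounding = Literal["exact", "1dp"]

_CENTS = 100


class CostRecord(BaseModel):
    """Implementation cost components for one project, in AUD.

    net cost = budget spend - funds retained by the health service
               + market-rate value of in-kind contributions
               - cost savings not attributable to capacity improvements

    Components are non-negative; amounts are held internally as integer
    cents so that league-table arithmetic is free of float drift.
    """

    model_config = ConfigDict(frozen=True)

    budget_spend: float = Field(ge=0)
    retained_funds: float = Field(default=0.0, ge=0)
    in_kind_value: float = Field(default=0.0, ge=0)
    non_capacity_savings: float = Field(default=0.0, ge=0)

    def _cents(self, amount: float) -> int:
        return round(amount * _CENTS)

    @property
    def net_cost(self) -> float:
        """Net cost in AUD; may be negative for a cost-saving project."""
        cents = (
            self._cents(self.budget_spend)
            - self._cents(self.retained_funds)
            + self._cents(self.in_kind_value)
            - self._cents(self.non_capacity_savings)
        )
        return cents / _CENTS


def compute_net_cost(cost: CostRecord) -> float:
    """Net cost in AUD. Negative results (cost-saving projects, which would
    plot below the x-axis of the cost-effectiveness plane) are permitted but
    logged."""
    net = cost.net_cost
    if net < 0:
        logger.warning("net cost is negative (cost-saving project): %s", net)
    return net


def _round_scores(s: ScoreVector, rounding: Rounding) -> dict[str, float]:
    if rounding == "exact":
        return s.as_dict()
    if rounding == "1dp":
        return {c: round(v, 1) for c, v in s.as_dict().items()}
    raise ValueError(f"unknown rounding mode: {rounding!r}")


def total_score(
    s: ScoreVector, scheme: WeightScheme, rounding: Rounding = "exact"
) -> float:
    """Weighted total T = Σ_c w_c s_c for one project.

    In ``1dp`` mode each criterion score is rounded to one decimal place
    before weighting, which reproduces totals computed from printed scores.
    """
    if set(scheme.criteria) != set(CRITERIA):
        raise ValueError(
            f"weight scheme criteria {sorted(scheme.criteria)} do not match "
            f"score criteria {sorted(CRITERIA)}"
        )
    scores = _round_scores(s, rounding)
    return sum(scheme[c] * scores[c] for c in CRITERIA)


def cost_per_point(net_cost: float, total: float) -> float:
    """Value-for-money ratio V = net cost / total score (AUD per point).

    Undefined for a zero total (the project earned no points and cannot be
    placed in the league table).
    """
    if total == 0:
        raise ZeroDivisionError("total score is zero; cost per point undefined")
    return net_cost / total


def competition_ranks(values: Sequence[float]) -> np.ndarray:
    """Ascending competition ranking ("1224"): ties share the smallest rank
    of their group and the following rank is skipped."""
    return rankdata(values, method="min").astype(int)


def dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """True when (total_a, cost_a) weakly dominates (total_b, cost_b):
    at least the score for at most the cost, strictly better in one."""
    ta, ca = a
    tb, cb = b
    return ta >= tb and ca <= cb and (ta > tb or ca < cb)


def non_dominated_mask(totals: Sequence[float], costs: Sequence[float]) -> np.ndarray:
    """Boolean mask of frontier membership under weak pairwise dominance.

    Sort-and-sweep over totals in descending order: within a group of equal
    totals only the cheapest points survive, and the whole group is dominated
    by any strictly-higher-scoring point that is at most as expensive.
    Duplicate (total, cost) pairs do not dominate each other and are all kept
    when non-dominated.
    """
    t = np.asarray(totals, dtype=float)
    c = np.asarray(costs, dtype=float)
    if t.shape != c.shape:
        raise ValueError("totals and costs must have equal length")
    mask = np.ones(t.size, dtype=bool)
    order = np.lexsort((c, -t))  # descending total, then ascending cost
    best = np.inf  # min cost among strictly-higher-total points
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and t[order[j]] == t[order[i]]:
            j += 1
        group = order[i:j]
        group_min = c[group[0]]
        for k in group:
            if c[k] >= best or c[k] > group_min:
                mask[k] = False
        best = min(best, group_min)
        i = j
    return mask


def non_dominated_frontier(
    entries: Iterable[tuple[str, float, float]]
) -> list[tuple[str, float, float]]:
    """Frontier subset of (project_id, total, net_cost) triples, sorted by
    ascending total score."""
    entries = list(entries)
    if not entries:
        return []
    ids, totals, costs = zip(*entries)
    mask = non_dominated_mask(totals, costs)
    kept = [e for e, m in zip(entries, mask) if m]
    return sorted(kept, key=lambda e: (e[1], e[2], e[0]))


def build_league_table(
    scores: Sequence[ScoreVector],
    costs: Mapping[str, CostRecord | float],
    scheme: WeightScheme,
    rounding: Rounding = "exact",
) -> pd.DataFrame:
    """Assemble the full league table for one weight scheme.

    Returns a DataFrame indexed by rank order with columns ``project_id``,
    ``total``, ``net_cost``, ``cost_per_point``, ``rank``, ``on_frontier``
    and ``cost_saving``. Projects with a zero total have no defined
    cost-per-point and are excluded, with a warning naming them.
    """
    rows = []
    for s in scores:
        if s.project_id not in costs:
            raise KeyError(f"no cost record for project {s.project_id!r}")
        c = costs[s.project_id]
        net = compute_net_cost(c) if isinstance(c, CostRecord) else float(c)
        t = total_score(s, scheme, rounding)
        if t == 0:
            logger.warning(
                "project %s scored zero points; cost per point undefined, "
                "excluded from league table",
                s.project_id,
            )
            continue
        rows.append(
            {
                "project_id": s.project_id,
                "total": t,
                "net_cost": net,
                "cost_per_point": cost_per_point(net, t),
                "cost_saving": net < 0,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "project_id", "total", "net_cost", "cost_per_point",
                "rank", "on_frontier", "cost_saving",
            ]
        )
    df = pd.DataFrame(rows)
    df["rank"] = competition_ranks(df["cost_per_point"].to_numpy())
    df["on_frontier"] = non_dominated_mask(
        df["total"].to_numpy(), df["net_cost"].to_numpy()
    )
    df = df.sort_values(["rank", "project_id"], kind="stable").reset_index(drop=True)
    return df[
        ["project_id", "total", "net_cost", "cost_per_point", "rank",
         "on_frontier", "cost_saving"]
    ]


def rank_by_value(table: pd.DataFrame) -> pd.Series:
    """Project -> rank mapping (ascending cost-per-point) from a league table."""
    return table.set_index("project_id")["rank"]


def ce_plane_table(table: pd.DataFrame) -> pd.DataFrame:
    """Cost-effectiveness-plane coordinates: x = total score (benefit),
    y = net cost, with frontier membership. The origin represents usual
    care; a point below the x-axis would be cost saving."""
    if table.empty:
        return pd.DataFrame(columns=["project_id", "x", "y", "on_frontier"])
    out = table[["project_id", "total", "net_cost", "on_frontier"]].copy()
    return out.rename(columns={"total": "x", "net_cost": "y"})


def sensitivity_ranks(
    scores: Sequence[ScoreVector],
    costs: Mapping[str, CostRecord | float],
    schemes: Sequence[WeightScheme],
    rounding: Rounding = "exact",
) -> pd.DataFrame:
    """Re-rank the portfolio under each weight scheme and report rank ranges.

    Returns a DataFrame indexed by project with one column per scheme label
    plus ``rank_min`` / ``rank_max`` over the schemes.
    """
    if not schemes:
        raise ValueError("at least one weight scheme is required")
    labels = [s.label for s in schemes]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate scheme labels: {labels}")
    cols = {}
    for scheme in schemes:
        table = build_league_table(scores, costs, scheme, rounding)
        cols[scheme.label] = rank_by_value(table)
    df = pd.DataFrame(cols)
    df.index.name = "project_id"
    return append_rank_ranges(df)


def append_rank_ranges(rank_table: pd.DataFrame) -> pd.DataFrame:
    """Add ``rank_min`` / ``rank_max`` columns to a per-scheme rank table.

    The table may come from :func:`sensitivity_ranks` or be supplied
    directly (e.g. externally published rank vectors)."""
    out = rank_table.copy()
    scheme_cols = [c for c in out.columns if c not in ("rank_min", "rank_max")]
    out["rank_min"] = out[scheme_cols].min(axis=1).astype(int)
    out["rank_max"] = out[scheme_cols].max(axis=1).astype(int)
    return out


def plot_ce_plane(table: pd.DataFrame, ax=None):
    """Scatter the league table on the cost-effectiveness plane.

    Frontier projects are highlighted and connected; requires matplotlib.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    coords = ce_plane_table(table)
    off = coords[~coords["on_frontier"]]
    on = coords[coords["on_frontier"]].sort_values("x")
    ax.scatter(off["x"], off["y"], color="grey", label="dominated")
    ax.scatter(on["x"], on["y"], color="crimson", zorder=3, label="frontier")
    ax.plot(on["x"], on["y"], color="crimson", alpha=0.5, zorder=2)
    for _, row in coords.iterrows():
        ax.annotate(row["project_id"], (row["x"], row["y"]),
                    textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("total score (points)")
    ax.set_ylabel("net cost (AUD)")
    ax.legend(frameon=False)
    return ax
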