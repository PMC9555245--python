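"""Decision-analytic summaries: CE-plane classification and per-size rollups.

A rational, risk-neutral decision maker adopts a programme that improves
health and saves money (the dominant quadrant of the cost-effectiveness
plane), rejects one that worsens health and adds cost (dominated), and in
the two mixed quadrants compares the incremental cost-effectiveness ratio
against a willingness-to-pay threshold λ ($ per QALY).  This module
classifies per-replicate outcomes, aggregates them per grid size alongside
statistical-significance proportions, and computes Tukey boxplot statistics
for p-value-by-size displays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DecisionRule",
    "DecisionSummary",
    "BoxplotStats",
    "ThresholdRequiredError",
    "classify",
    "ADOPT_CLASSES",
    "summarise_grid",
    "boxplot_stats",
]

ADOPT_CLASSES = frozenset({"adopt_dominant", "adopt_cost_effective"})
ALL_CLASSES = ("adopt_dominant", "adopt_cost_effective",
               "reject_dominated", "reject_not_cost_effective")


class ThresholdRequiredError(ValueError):
    """Raised when classification needs a willingness-to-pay threshold."""


@dataclass(frozen=True)
class DecisionRule:
    """Adoption rule for CE-plane points.

    ``wtp_threshold`` is λ in $ per QALY; ``None`` disables it, which is
    sufficient whenever all points fall in the dominant/dominated quadrants
    (as in the calibrated and null scenarios here).  Points on the ICER
    boundary (ΔCost/ΔQALY = λ) are adopted (weak preference).
    """

    wtp_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.wtp_threshold is not None and self.wtp_threshold <= 0:
            raise ValueError("wtp_threshold must be positive or None")


@dataclass(frozen=True)
class BoxplotStats:
    """Tukey five-number summary plus individually plotted outliers.

    Quartiles use linear interpolation (type-7); whiskers extend to the
    most extreme data point within 1.5 IQR of the nearer quartile; points
    beyond the whiskers are outliers.
    """

    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = ()


@dataclass(frozen=True)
class DecisionSummary:
    """Per-size rollup of the grid experiment.

    ``per_size`` has one row per grid size with the significance and
    adoption proportions, CE-plane quadrant shares and p-value quartiles.
    ``smallest_majority_significant`` is the smallest size at which more
    than half of the (non-degenerate) replicates were significant;
    ``smallest_decisive_adopt`` the smallest size at which the adoption
    proportion reached the decisiveness level.  Either is None when no
    size qualifies.
    """

    per_size: pd.DataFrame
    smallest_majority_significant: int | None
    smallest_decisive_adopt: int | None
    alpha: float
    decisiveness: float


def classify(delta_cost: float, delta_qaly: float,
             rule: DecisionRule) -> str:
    """Place one (ΔCost, ΔQALY) point into an adopt/reject class.

    Dominant (ΔQALY > 0, ΔCost < 0) points are adopted and dominated ones
    (ΔQALY < 0, ΔCost > 0) rejected outright.  North-east points (costlier,
    healthier) are adopted iff their ICER ΔCost/ΔQALY ≤ λ; south-west
    points (cheaper, less healthy) iff the saving per QALY forgone is at
    least λ.  Exact zeros preserve the status quo: a change is adopted
    only if it strictly improves at least one dimension and worsens
    neither.
    """
    if not (math.isfinite(delta_cost) and math.isfinite(delta_qaly)):
        raise ValueError("classification requires finite inputs")
    if delta_qaly == 0.0:
        return "adopt_dominant" if delta_cost < 0.0 \
            else "reject_not_cost_effective" if delta_cost == 0.0 \
            else "reject_dominated"
    if delta_cost == 0.0:
        return "adopt_dominant" if delta_qaly > 0.0 else "reject_dominated"
    if delta_qaly > 0.0 and delta_cost < 0.0:
        return "adopt_dominant"
    if delta_qaly < 0.0 and delta_cost > 0.0:
        return "reject_dominated"
    if rule.wtp_threshold is None:
        raise ThresholdRequiredError(
            "point lies in a mixed CE-plane quadrant: a willingness-to-pay "
            "threshold is required"
        )
    lam = rule.wtp_threshold
    if delta_qaly > 0.0:  # north-east: pay more, gain health
        return "adopt_cost_effective" if delta_cost / delta_qaly <= lam \
            else "reject_not_cost_effective"
    # south-west: save money, forgo health
    return "adopt_cost_effective" if (-delta_cost) / (-delta_qaly) >= lam \
        else "reject_not_cost_effective"


def boxplot_stats(values) -> BoxplotStats:
    """Tukey boxplot statistics of a collection of finite values."""
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("boxplot_stats requires at least one finite value")
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75])  # type-7 interpolation
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return BoxplotStats(
        median=float(med), q25=float(q25), q75=float(q75),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=tuple(sorted(float(v) for v in x[(x < lo_fence) | (x > hi_fence)])),
    )


def summarise_grid(results: pd.DataFrame, rule: DecisionRule | None = None,
                   alpha: float = 0.05,
                   decisiveness: float = 0.9) -> DecisionSummary:
    """Aggregate a grid results table into per-size decision statistics.

    Significance is ``p < alpha`` among non-degenerate replicates;
    adoption is membership of an adopt class of :func:`classify` among
    replicates with finite economic outcomes.  When the rule's threshold
    is disabled, mixed-quadrant points are counted as
    ``reject_not_cost_effective``: without a stated willingness to pay a
    decision maker keeps the status quo rather than adopt a costlier
    programme.  Size buckets in which every replicate is degenerate are
    reported with NaN proportions.
    """
    if rule is None:
        rule = DecisionRule()
    if len(results) == 0:
        raise ValueError("empty results table")

    rows = []
    for size, bucket in results.groupby("size", sort=True):
        ok = bucket[~bucket["degenerate"]]
        row: dict = {
            "size": int(size),
            "n_rows": len(bucket),
            "n_degenerate": int(bucket["degenerate"].sum()),
        }
        if len(ok) == 0:
            row.update({k: math.nan for k in (
                "proportion_significant", "proportion_adopt",
                "p_median", "p_q25", "p_q75",
                *(f"share_{c}" for c in ALL_CLASSES))})
            rows.append(row)
            continue
        pvals = ok["p_value"].to_numpy()
        row["proportion_significant"] = float((pvals < alpha).mean())
        classes = []
        for c, q in zip(ok["delta_cost"], ok["delta_qaly"]):
            try:
                classes.append(classify(c, q, rule))
            except ThresholdRequiredError:
                classes.append("reject_not_cost_effective")
        counts = pd.Series(classes).value_counts()
        for c in ALL_CLASSES:
            row[f"share_{c}"] = counts.get(c, 0) / len(ok)
        row["proportion_adopt"] = float(
            sum(counts.get(c, 0) for c in ADOPT_CLASSES) / len(ok)
        )
        q25, med, q75 = np.quantile(pvals, [0.25, 0.5, 0.75])
        row.update(p_median=float(med), p_q25=float(q25), p_q75=float(q75))
        rows.append(row)

    per_size = pd.DataFrame(rows).sort_values("size").reset_index(drop=True)

    def _smallest(mask: pd.Series) -> int | None:
        hits = per_size.loc[mask.fillna(False), "size"]
        return int(hits.iloc[0]) if len(hits) else None

    return DecisionSummary(
        per_size=per_size,
        smallest_majority_significant=_smallest(
            per_size["proportion_significant"] > 0.5),
        smallest_decisive_adopt=_smallest(
            per_size["proportion_adopt"] >= decisiveness),
        alpha=alpha,
        decisiveness=decisiveness,
    )
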