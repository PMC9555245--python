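"""The bootstrap sample-size-grid experiment.

One fixed individual-patient dataset is resampled with replacement at each
size on a grid (by default 100, 200, ..., 700 patients, 500 replicates per
size, unstratified by arm).  Every subsample is pushed through both analysis
arms: the hypothesis test of the LDL difference, and the cohort
cost-effectiveness model run on the subsample's own effect estimates.  Each
(size, replicate) yields one result row carrying the p-value and the
incremental cohort cost and QALYs side by side.

Randomness is organised as one independent substream per (size, replicate),
keyed on (seed, size, replicate), so results are reproducible and invariant
to execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .econ import EconParams, TreatmentEffects, null_params, run_cohort_model
from .inference import DesignSpec, mean_difference_test
from .trial import TrialDataset

__all__ = [
    "GridSpec",
    "RESULT_COLUMNS",
    "bootstrap_subsample",
    "run_grid",
]

DEFAULT_SIZES = (100, 200, 300, 400, 500, 600, 700)

RESULT_COLUMNS = [
    "size", "replicate", "p_value", "estimate_ldl", "estimate_sbp",
    "delta_smoking_prev", "delta_cost", "delta_qaly", "degenerate",
]


@dataclass(frozen=True)
class GridSpec:
    """Grid of reduced sample sizes and the replication plan."""

    sizes: tuple[int, ...] = DEFAULT_SIZES
    replicates: int = 500
    seed: int = 0
    scenario: str = "calibrated"  # or "null"

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if len(sizes) == 0:
            raise ValueError("sizes must be non-empty")
        if any(s <= 0 for s in sizes):
            raise ValueError("sizes must be positive")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("sizes must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.scenario not in ("calibrated", "null"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


def _substream(seed: int, size: int, replicate: int) -> np.random.Generator:
    # counter-based keying: each (size, replicate) cell owns its stream,
    # so the grid can be evaluated in any order
    return np.random.default_rng(
        np.random.SeedSequence([seed, size, replicate])
    )


def bootstrap_subsample(dataset: TrialDataset, n: int,
                        rng: np.random.Generator,
                        max_n: int | None = None) -> TrialDataset:
    """Draw ``n`` records with replacement, unstratified by arm.

    Arm sizes in the subsample are therefore random and may be unequal or
    even zero at small ``n``.  Duplicated records get fresh unique ids.
    """
    if n < 1:
        raise ValueError("subsample size must be >= 1")
    if max_n is not None and n > max_n:
        raise ValueError(f"subsample size {n} exceeds allowed maximum {max_n}")
    idx = rng.integers(0, len(dataset), n)
    df = dataset.data.iloc[idx].reset_index(drop=True)
    df["id"] = np.arange(1, n + 1)
    return TrialDataset(df, provenance=f"{dataset.provenance}|bootstrap-n{n}")


def _replicate_row(dataset: TrialDataset, size: int, replicate: int,
                   seed: int, econ: EconParams) -> dict:
    rng = _substream(seed, size, replicate)
    sub = bootstrap_subsample(dataset, size, rng)

    row = {
        "size": size, "replicate": replicate, "p_value": math.nan,
        "estimate_ldl": math.nan, "estimate_sbp": math.nan,
        "delta_smoking_prev": math.nan, "delta_cost": math.nan,
        "delta_qaly": math.nan, "degenerate": False,
    }

    ldl = mean_difference_test(sub, "ldl")
    row["p_value"] = ldl.p_value
    row["estimate_ldl"] = ldl.estimate
    row["degenerate"] = ldl.degenerate

    arm_int = sub.arm("intervention")
    arm_ctl = sub.arm("control")
    if len(arm_int) == 0 or len(arm_ctl) == 0:
        row["degenerate"] = True
        return row

    sbp_diff = arm_int["sbp"].mean() - arm_ctl["sbp"].mean()
    prev_int = arm_int["smoker"].mean()
    prev_ctl = arm_ctl["smoker"].mean()
    row["estimate_sbp"] = sbp_diff
    row["delta_smoking_prev"] = prev_int - prev_ctl

    effects = TreatmentEffects(
        ldl_change=(ldl.estimate if math.isfinite(ldl.estimate) else 0.0),
        sbp_change=sbp_diff,
        smoking_prev_change=prev_int - prev_ctl,
    )
    try:
        outcome = run_cohort_model(effects, econ)
    except ValueError:
        row["degenerate"] = True
        return row
    row["delta_cost"] = outcome.delta_cost
    row["delta_qaly"] = outcome.delta_qaly
    return row


def run_grid(dataset: TrialDataset, grid: GridSpec,
             design: DesignSpec | None = None,
             econ: EconParams | None = None) -> pd.DataFrame:
    """Run the full (size x replicate) experiment on one dataset.

    Returns one row per (size, replicate) — ``len(sizes) * replicates``
    rows, always — with the p-value of the LDL Welch test, the effect
    estimates fed to the economic model, and the incremental cohort cost
    and QALYs.  Replicates whose subsample defeats a stage (an arm with
    too few patients, an undefined prevalence ratio) are flagged
    ``degenerate`` with missing values rather than aborting the grid.

    Under ``grid.scenario == "null"`` the economic model's
    zero-risk-reduction switch is forced on, as the null counter-example
    requires; the caller supplies the arm-permuted dataset.
    """
    if econ is None:
        econ = EconParams()
    if grid.scenario == "null":
        econ = null_params(econ)
    if max(grid.sizes) > len(dataset):
        raise ValueError(
            f"grid size {max(grid.sizes)} exceeds dataset size {len(dataset)}"
        )
    rows = [
        _replicate_row(dataset, size, rep, grid.seed, econ)
        for size in grid.sizes
        for rep in range(grid.replicates)
    ]
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out["degenerate"] = out["degenerate"].astype(bool)
    return out
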