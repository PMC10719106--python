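"""Randomization inference: design-based p-values under the sharp null.

Outcomes are held fixed while the entire two-stage assignment is re-drawn
under the design's own law -- quadruplet membership stays fixed, the four
arms are re-permuted within each quadruplet and the embedded-placebo
positions are re-drawn (see :meth:`AssignmentPlan.rerandomize`, the same code
path the original plan used).  The two-sided Monte-Carlo p-value carries the
standard +1 finite-sample correction:

    p = (1 + #{ |T_b| >= |T_obs| }) / (B + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .design import AssignmentPlan
from .estimators import diff_in_means_clustered

__all__ = ["RIResult", "ri_pvalue", "diff_statistic"]


@dataclass
class RIResult:
    """A randomization-inference test: observed statistic, null draws, p."""

    observed_stat: float
    null_draws: np.ndarray
    p_value: float
    n_replicates: int
    n_failed: int = 0
    seed: int | None = None

    def __str__(self) -> str:
        return (
            f"RI p = {self.p_value:.4g}  (observed {self.observed_stat:.3f}, "
            f"B = {self.n_replicates}, failed draws = {self.n_failed})"
        )


def diff_statistic(
    outcome: str, arm_a: str, arm_b: str
) -> Callable[[pd.DataFrame], float]:
    """Statistic factory: the cluster-weighted arm_a - arm_b rate difference."""

    def stat(df: pd.DataFrame) -> float:
        return diff_in_means_clustered(df, outcome, arm_a, arm_b, by="arm").diff

    return stat


def _reassign(records: pd.DataFrame, plan: AssignmentPlan) -> pd.DataFrame:
    """Relabel arm/video columns of a fixed-outcome table under a new plan."""
    df = records.copy()
    df["arm"] = df["village_id"].map(plan.village_arm)
    untreated = df.get("untreated_spillover")
    mask = (
        untreated.astype(bool)
        if untreated is not None
        else pd.Series(False, index=df.index)
    )
    df.loc[~mask, "video"] = df.loc[~mask, "individual_id"].map(plan.individual_video)
    return df


def ri_pvalue(
    records: pd.DataFrame,
    plan: AssignmentPlan,
    stat_fn: Callable[[pd.DataFrame], float],
    B: int = 2000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> RIResult:
    """Two-sided randomization p-value for ``stat_fn`` under the sharp null.

    ``records`` must carry individual_id, village_id, arm, video and the
    fixed outcomes; ``plan`` is the realized assignment the records came
    from.  Draws where the statistic fails (e.g. an empty stratum) are
    dropped and counted.
    """
    if B < 1:
        raise ValueError("need B >= 1 replicates")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = float(stat_fn(records))
    draws = []
    failed = 0
    for _ in range(B):
        new_plan = plan.rerandomize(rng)
        try:
            draws.append(float(stat_fn(_reassign(records, new_plan))))
        except Exception as err:
            failed += 1
            warnings.warn(f"statistic failed on a re-draw: {err}")
    draws_arr = np.asarray(draws)
    b_eff = len(draws_arr)
    if b_eff == 0:
        raise RuntimeError("statistic failed on every re-draw")
    p = (1.0 + np.sum(np.abs(draws_arr) >= abs(observed))) / (b_eff + 1.0)
    return RIResult(
        observed_stat=observed,
        null_draws=draws_arr,
        p_value=float(p),
        n_replicates=b_eff,
        n_failed=failed,
        seed=seed,
    )
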