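"""Simulation-based and closed-form power for the four-arm cluster design.

Each replicate builds a four-arm trial under the blocked design (arms
permuted within quadruplets of villages), simulates a clustered binary
outcome whose marginal rates are ``baseline_rate`` (placebo, health) and
``baseline_rate + effect`` (the cash arms) at a village-intercept scale
calibrated to the requested ANOVA-scale ICC, and tests cash vs placebo with
the cluster-robust difference-in-means t-test.  Power is the rejection
fraction at ``alpha``.

"Effect size" is an absolute risk difference (0.06 means 6 percentage
points), matching how the trial's contrasts are reported.  The closed-form
cross-check deflates per-arm sample sizes by the design effect
1 + (m - 1) * ICC and applies the usual two-proportion normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import ARMS
from .estimators import diff_from_cluster_means
from .population import _baseline_for_marginal, calibrate_glmm

__all__ = ["PowerResult", "simulate_power", "analytic_power", "design_effect"]


@dataclass(frozen=True)
class PowerResult:
    """Simulated power with its Monte-Carlo standard error."""

    power: float
    n_villages: int
    per_village: int
    effect: float
    icc_assumed: float
    alpha: float
    reps: int

    @property
    def mc_se(self) -> float:
        return math.sqrt(self.power * (1.0 - self.power) / self.reps)

    def __str__(self) -> str:
        return (
            f"power {self.power:.3f} (MC SE {self.mc_se:.3f}) at effect "
            f"{self.effect:+.2f}, {self.n_villages} villages x {self.per_village}, "
            f"ICC {self.icc_assumed}, alpha {self.alpha}"
        )


def design_effect(m: float, icc: float) -> float:
    """Variance inflation of a cluster sample of size m: 1 + (m - 1) ICC."""
    return 1.0 + (m - 1.0) * icc


def simulate_power(
    n_villages: int = 310,
    per_village: int = 21,
    baseline_rate: float = 0.36,
    effect: float = 0.06,
    icc: float = 0.02,
    alpha: float = 0.05,
    reps: int = 500,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    contrast: str = "cash",
) -> PowerResult:
    """Monte-Carlo power of the cash-vs-placebo cluster-robust t-test.

    ``contrast='cash'`` pools the two cash arms against placebo (the primary
    pre-registered comparison); ``'low_cash'`` uses the single-arm contrast.
    Analysis is by assigned village arm, so per-village counts stay fixed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not (0.0 < baseline_rate < 1.0 and 0.0 < baseline_rate + effect < 1.0):
        raise ValueError("baseline_rate and baseline_rate + effect must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_quads = n_villages // 4
    if n_quads < 2:
        raise ValueError("need at least 8 villages")
    b0, sigma = calibrate_glmm(baseline_rate, icc)
    b1 = _baseline_for_marginal(baseline_rate + effect, sigma) if effect else b0
    cash_arms = {"low_cash", "high_cash"} if contrast == "cash" else {contrast}
    n_vill_used = 4 * n_quads
    rejections = 0
    arm_idx = {a: i for i, a in enumerate(ARMS)}
    cash_codes = np.array([arm_idx[a] for a in cash_arms])
    for _ in range(reps):
        # blocked arm assignment: one permutation of the four arms per quadruplet
        arms = np.empty(n_vill_used, dtype=int)
        for q in range(n_quads):
            arms[4 * q : 4 * q + 4] = rng.permutation(4)
        is_cash = np.isin(arms, cash_codes)
        is_placebo = arms == arm_idx["placebo"]
        u = rng.normal(0.0, sigma, size=n_vill_used)
        eta = np.where(is_cash, b1, b0) + u
        p = 1.0 / (1.0 + np.exp(-eta))
        means = rng.binomial(per_village, p) / per_village
        sizes = np.full(n_vill_used, float(per_village))
        est = diff_from_cluster_means(
            means[is_cash], sizes[is_cash], means[is_placebo], sizes[is_placebo]
        )
        if est.p < alpha:
            rejections += 1
    return PowerResult(
        power=rejections / reps,
        n_villages=n_vill_used,
        per_village=per_village,
        effect=effect,
        icc_assumed=icc,
        alpha=alpha,
        reps=reps,
    )


def analytic_power(
    n_eff_per_arm: float,
    baseline_rate: float,
    effect: float,
    alpha: float = 0.05,
    n_eff_other: float | None = None,
) -> float:
    """Closed-form two-proportion power after design-effect deflation.

    ``n_eff_per_arm`` is the treated arm's effective size (n / design effect);
    ``n_eff_other`` the comparison arm's (defaults to the same).  Two-sided
    normal approximation with unpooled variance.
    """
    if not (0.0 < baseline_rate < 1.0 and 0.0 < baseline_rate + effect < 1.0):
        raise ValueError("proportions must lie in (0, 1)")
    n1 = n_eff_per_arm
    n2 = n_eff_other if n_eff_other is not None else n_eff_per_arm
    p1 = baseline_rate + effect
    p2 = baseline_rate
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    d = abs(effect) / se if se > 0 else np.inf
    return float(stats.norm.cdf(d - z) + stats.norm.cdf(-d - z))
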