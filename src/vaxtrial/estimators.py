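"""Descriptive estimators for clustered binary outcomes.

Arm rates, size-weighted pooled rates, cluster-robust two-arm contrasts with
t-based confidence intervals, the one-way ANOVA intracluster correlation, and
standardized-mean-difference balance tables.

The two-arm contrast works on size-weighted cluster means, which reproduces a
two-sided t-test for the difference of arm proportions without any
individual-level likelihood assumption: with clusters g = 1..G in an arm,
cluster means ybar_g and sizes n_g, the arm proportion is the ratio estimator
p = sum n_g ybar_g / sum n_g and its variance is the between-cluster variance
of the weighted means,

    Var(p) = G/(G-1) * sum_g (n_g / N)^2 (ybar_g - p)^2 .
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiffEstimate",
    "ICCEstimate",
    "arm_rate",
    "pooled_rate",
    "cluster_summaries",
    "diff_from_cluster_means",
    "diff_in_means_clustered",
    "icc_anova",
    "smd_balance",
]


@dataclass(frozen=True)
class DiffEstimate:
    """A two-arm contrast in percentage points with cluster-robust inference."""

    diff: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    df: int
    n_a: int
    n_b: int
    g_a: int
    g_b: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.diff <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")

    def __str__(self) -> str:
        return (
            f"{self.label or 'contrast'}: {self.diff:.1f} pp "
            f"(95% CI {self.ci_low:.1f}, {self.ci_high:.1f}; p={self.p:.3g}; "
            f"df={self.df}; clusters {self.g_a}/{self.g_b})"
        )


@dataclass(frozen=True)
class ICCEstimate:
    """One-way ANOVA intracluster correlation with a large-sample CI."""

    icc: float
    ci_low: float
    ci_high: float
    n_clusters: int
    mean_cluster_size: float

    def __str__(self) -> str:
        return f"ICC {self.icc:.3f} (95% CI {self.ci_low:.3f}, {self.ci_high:.3f})"


def arm_rate(
    records: pd.DataFrame, outcome: str, arm: str, by: str = "arm"
) -> tuple[float, int, int]:
    """Percentage of successes in one arm: (rate %, numerator, denominator).

    Only records with the outcome observed count toward the denominator.
    """
    sub = records.loc[(records[by] == arm) & records[outcome].notna(), outcome]
    if len(sub) == 0:
        raise ValueError(f"no observed {outcome!r} records in arm {arm!r}")
    num = int(sub.sum())
    return 100.0 * num / len(sub), num, len(sub)


def pooled_rate(rates: list[tuple[float, int]]) -> float:
    """Sample-size-weighted average of (rate, n) pairs, in the rate's units."""
    if any(n <= 0 for _, n in rates):
        raise ValueError("all sample sizes must be positive")
    total = sum(n for _, n in rates)
    return sum(r * n for r, n in rates) / total


def cluster_summaries(
    records: pd.DataFrame,
    outcome: str,
    arm: str,
    cluster: str = "village_id",
    by: str = "arm",
    weights: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(cluster means, cluster sizes) for observed outcomes in one arm.

    With ``weights`` the cluster mean is the weighted mean and the size is the
    cluster's total weight (used for inverse-probability reweighting).
    """
    sub = records.loc[(records[by] == arm) & records[outcome].notna()]
    if len(sub) == 0:
        raise ValueError(f"no observed {outcome!r} records in arm {arm!r}")
    if weights is None:
        grp = sub.groupby(cluster)[outcome].agg(["mean", "size"])
        return grp["mean"].to_numpy(float), grp["size"].to_numpy(float)
    w = sub[weights]
    num = (sub[outcome] * w).groupby(sub[cluster]).sum()
    den = w.groupby(sub[cluster]).sum()
    return (num / den).to_numpy(float), den.to_numpy(float)


def diff_from_cluster_means(
    means_a: np.ndarray,
    sizes_a: np.ndarray,
    means_b: np.ndarray,
    sizes_b: np.ndarray,
    n_a: int | None = None,
    n_b: int | None = None,
    label: str = "",
) -> DiffEstimate:
    """Cluster-level core of the two-arm contrast (percentage points)."""

    def part(means: np.ndarray, sizes: np.ndarray) -> tuple[float, float, int]:
        g = len(means)
        if g < 2:
            raise ValueError("need >= 2 clusters per arm for a between-cluster variance")
        w = sizes / sizes.sum()
        p = float(np.sum(w * means))
        var = g / (g - 1) * float(np.sum(w**2 * (means - p) ** 2))
        return p, var, g

    p_a, var_a, g_a = part(np.asarray(means_a, float), np.asarray(sizes_a, float))
    p_b, var_b, g_b = part(np.asarray(means_b, float), np.asarray(sizes_b, float))
    diff = 100.0 * (p_a - p_b)
    se = 100.0 * math.sqrt(var_a + var_b)
    df = g_a + g_b - 2
    if se == 0.0:
        t, p_val = 0.0, 1.0
    else:
        t = diff / se
        p_val = 2.0 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * se
    return DiffEstimate(
        diff=diff,
        se=se,
        ci_low=diff - half,
        ci_high=diff + half,
        p=float(p_val),
        df=df,
        n_a=int(n_a if n_a is not None else np.sum(sizes_a)),
        n_b=int(n_b if n_b is not None else np.sum(sizes_b)),
        g_a=g_a,
        g_b=g_b,
        label=label,
    )


def diff_in_means_clustered(
    records: pd.DataFrame,
    outcome: str,
    arm_a: str,
    arm_b: str,
    cluster: str = "village_id",
    by: str = "arm",
    weights: str | None = None,
) -> DiffEstimate:
    """Two-sided cluster-robust t-test for the arm_a - arm_b rate difference.

    Point estimate in percentage points; SE from the between-cluster variance
    of size-weighted cluster means; df = G_a + G_b - 2.
    """
    ma, sa = cluster_summaries(records, outcome, arm_a, cluster, by, weights)
    mb, sb = cluster_summaries(records, outcome, arm_b, cluster, by, weights)
    n_a = int(((records[by] == arm_a) & records[outcome].notna()).sum())
    n_b = int(((records[by] == arm_b) & records[outcome].notna()).sum())
    return diff_from_cluster_means(
        ma, sa, mb, sb, n_a=n_a, n_b=n_b, label=f"{outcome}: {arm_a} - {arm_b}"
    )


def icc_anova(
    records: pd.DataFrame,
    outcome: str,
    cluster: str = "village_id",
    ci_method: str = "smith",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> ICCEstimate:
    """One-way ANOVA intracluster correlation of a (binary) outcome.

    rho = (MSB - MSW) / (MSB + (m0 - 1) MSW) with the ANOVA mean cluster size
    m0 = (N - sum n_g^2 / N) / (G - 1).  The default CI is the Smith/Swiger
    large-sample normal interval; ``ci_method='bootstrap'`` resamples clusters.
    """
    sub = records.loc[records[outcome].notna(), [cluster, outcome]]
    y = sub[outcome].to_numpy(float)
    if np.all(y == y[0]):
        raise ValueError(f"outcome {outcome!r} is constant; ICC undefined")
    groups = sub.groupby(cluster)[outcome]
    means = groups.mean().to_numpy(float)
    sizes = groups.size().to_numpy(float)
    g = len(means)
    n = float(sizes.sum())
    if g < 2:
        raise ValueError("need >= 2 clusters")
    grand = float(np.sum(sizes * means) / n)
    msb = float(np.sum(sizes * (means - grand) ** 2) / (g - 1))
    ssw = float(np.sum(y**2) - np.sum(sizes * means**2))
    msw = ssw / (n - g)
    m0 = (n - np.sum(sizes**2) / n) / (g - 1)
    icc = (msb - msw) / (msb + (m0 - 1) * msw)

    if ci_method == "smith":
        var = (
            2.0 * (n - 1) * (1 - icc) ** 2 * (1 + (m0 - 1) * icc) ** 2
            / (m0**2 * (n - g) * (g - 1))
        )
        half = 1.959963984540054 * math.sqrt(max(var, 0.0))
        lo, hi = icc - half, icc + half
    elif ci_method == "bootstrap":
        rng = rng or np.random.default_rng(0)
        stats_ = []
        ids = groups.size().index.to_numpy()
        frames = {k: v for k, v in sub.groupby(cluster)}
        for _ in range(n_boot):
            take = rng.choice(len(ids), size=len(ids), replace=True)
            boot = pd.concat(
                [frames[ids[t]].assign(**{cluster: f"b{j}"}) for j, t in enumerate(take)]
            )
            try:
                stats_.append(icc_anova(boot, outcome, cluster, ci_method="smith").icc)
            except ValueError:
                continue
        lo, hi = np.percentile(stats_, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo = max(lo, -1.0 / (m0 - 1.0))
    hi = min(hi, 1.0)
    return ICCEstimate(
        icc=float(icc),
        ci_low=float(lo),
        ci_high=float(hi),
        n_clusters=g,
        mean_cluster_size=float(m0),
    )


def _is_binary(x: pd.Series) -> bool:
    vals = set(pd.unique(x.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def smd_balance(
    records: pd.DataFrame,
    covariates: list[str],
    arm_pairs: list[tuple[str, str]],
    by: str = "arm",
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Covariate balance across arm pairs.

    Standardized mean difference (mean_a - mean_b) / pooled SD for continuous
    covariates; the raw difference in proportions for binary covariates.
    Rows with |SMD| > threshold are flagged.  Categorical covariates are
    expanded to one binary row per level.
    """
    rows = []
    df = records.copy()
    expanded: list[str] = []
    for cov in covariates:
        if df[cov].dtype == object or isinstance(df[cov].dtype, pd.CategoricalDtype):
            for level in sorted(df[cov].dropna().unique()):
                name = f"{cov}={level}"
                df[name] = (df[cov] == level).astype(float)
                expanded.append(name)
        else:
            expanded.append(cov)
    for cov in expanded:
        for a, b in arm_pairs:
            xa = df.loc[df[by] == a, cov].dropna().astype(float)
            xb = df.loc[df[by] == b, cov].dropna().astype(float)
            if len(xa) == 0 or len(xb) == 0:
                raise ValueError(f"covariate {cov!r} missing in arm pair ({a}, {b})")
            if _is_binary(df[cov]):
                smd = xa.mean() - xb.mean()
            else:
                pooled = math.sqrt((xa.var(ddof=1) + xb.var(ddof=1)) / 2.0)
                if pooled == 0.0:
                    warnings.warn(f"zero pooled SD for {cov!r}; SMD undefined")
                    smd = np.nan
                else:
                    smd = (xa.mean() - xb.mean()) / pooled
            rows.append(
                {
                    "covariate": cov,
                    "arm_a": a,
                    "arm_b": b,
                    "smd": smd,
                    # boundary counts as imbalanced: |SMD| >= tolerance
                    "flag": bool(abs(smd) >= threshold - 1e-12) if np.isfinite(smd) else True,
                }
            )
    return pd.DataFrame(rows)
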