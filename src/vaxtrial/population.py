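"""Synthetic trial population generator.

Generates villages, participants, covariates, three clustered binary
vaccination outcomes (intention, self-reported, register-verified) and
attrition with the statistical structure the estimation suite assumes, so
that every downstream stage is testable without the original field data.

The outcome model is a logistic random-intercept GLMM: for individual *i* in
village *c* (district *d*),

    logit P(Y_ic = 1) = b + beta[video_ic] + gamma[arm_c] * 1{spillover}
                        + omega' X_ic + u_c (+ u_d)

with u_c ~ N(0, sigma_village^2) and an optional district intercept
u_d ~ N(0, sigma_district^2) (the verified outcome shows extreme district
heterogeneity, which an ordinary village intercept cannot reproduce).

Because the village intercept acts on the latent logit scale, the intraclass
correlation of the *binary* outcome (what an ANOVA estimator sees) is smaller
than the latent ICC sigma^2/(sigma^2 + pi^2/3).  :func:`calibrate_glmm` inverts
the exact Gauss-Hermite expression so generator defaults can be stated on the
observed (ANOVA) scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .design import (
    ARMS,
    TREATED_ARMS,
    AssignmentPlan,
    Village,
    randomize_trial,
)

__all__ = [
    "OutcomeParams",
    "AttritionParams",
    "GeneratorConfig",
    "TrialData",
    "observed_icc",
    "latent_icc",
    "calibrate_glmm",
    "sigma_for_observed_icc",
    "generate_villages",
    "draw_covariates",
    "generate_individuals",
    "simulate_outcomes",
    "simulate_attrition",
    "generate_trial",
]

_LOGIT = special.logit
_EXPIT = special.expit

# ---------------------------------------------------------------------------
# latent-scale <-> observed-scale ICC
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)


def _gh_mean(f) -> float:
    """E[f(Z)] for Z ~ N(0,1) by 80-node Gauss-Hermite quadrature."""
    z = math.sqrt(2.0) * _GH_NODES
    return float(np.sum(_GH_WEIGHTS * f(z)) / math.sqrt(math.pi))


def marginal_probability(baseline_logit: float, sigma: float) -> float:
    """Marginal success probability of expit(b + sigma Z), Z ~ N(0,1)."""
    if sigma == 0.0:
        return float(_EXPIT(baseline_logit))
    return _gh_mean(lambda z: _EXPIT(baseline_logit + sigma * z))


def observed_icc(baseline_logit: float, sigma: float) -> float:
    """ANOVA-scale (Pearson) ICC of the binary outcome of a logit-normal GLMM.

    ICC_obs = Var(p(U)) / (pbar (1 - pbar)) with p(u) = expit(b + u).
    """
    if sigma == 0.0:
        return 0.0
    m1 = _gh_mean(lambda z: _EXPIT(baseline_logit + sigma * z))
    m2 = _gh_mean(lambda z: _EXPIT(baseline_logit + sigma * z) ** 2)
    return float((m2 - m1 * m1) / (m1 * (1.0 - m1)))


def latent_icc(sigma: float) -> float:
    """Latent-logit-scale ICC: sigma^2 / (sigma^2 + pi^2/3)."""
    return sigma**2 / (sigma**2 + math.pi**2 / 3.0)


def _baseline_for_marginal(p: float, sigma: float) -> float:
    """Conditional intercept b with E[expit(b + sigma Z)] = p."""
    if not 0.0 < p < 1.0:
        raise ValueError("marginal probability must be in (0, 1)")
    if sigma == 0.0:
        return float(_LOGIT(p))
    return float(
        optimize.brentq(lambda b: marginal_probability(b, sigma) - p, -30.0, 30.0)
    )


def calibrate_glmm(p_marginal: float, icc_obs: float) -> tuple[float, float]:
    """Solve for (baseline_logit, sigma_village) hitting a marginal rate and
    an observed-scale ICC simultaneously.

    Returns the conditional intercept and random-effect SD such that the
    marginal success probability equals ``p_marginal`` and the binary-scale
    ICC equals ``icc_obs``.
    """
    if not 0.0 <= icc_obs < 1.0:
        raise ValueError("icc_obs must be in [0, 1)")
    if icc_obs == 0.0:
        return float(_LOGIT(p_marginal)), 0.0

    def gap(sigma: float) -> float:
        b = _baseline_for_marginal(p_marginal, sigma)
        return observed_icc(b, sigma) - icc_obs

    sigma = float(optimize.brentq(gap, 1e-8, 40.0))
    return _baseline_for_marginal(p_marginal, sigma), sigma


def sigma_for_observed_icc(icc_obs: float, p_marginal: float = 0.5) -> float:
    """Village-intercept SD whose binary-scale ICC equals ``icc_obs``."""
    return calibrate_glmm(p_marginal, icc_obs)[1]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


def _zero_arms() -> dict[str, float]:
    return {a: 0.0 for a in ARMS}


@dataclass
class OutcomeParams:
    """Generator truth for one binary outcome.

    All effects live on the conditional log-odds scale.  ``arm_effects`` act
    on the video actually shown; ``gamma_embedded`` acts on placebo-video
    individuals in treated villages (within-village spillover onto embedded
    placebos); ``gamma_untreated`` acts on never-treated residents sampled
    from the spillover survey, keyed by their village's arm.
    """

    baseline_logit: float = 0.0
    arm_effects: dict[str, float] = field(default_factory=_zero_arms)
    gamma_embedded: dict[str, float] = field(default_factory=_zero_arms)
    gamma_untreated: dict[str, float] = field(default_factory=_zero_arms)
    untreated_shift: float = 0.0
    sigma_village: float = 0.0
    sigma_district: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma_village < 0 or self.sigma_district < 0:
            raise ValueError("random-intercept SDs must be >= 0")

    @classmethod
    def from_marginal_rates(
        cls,
        rates: Mapping[str, float],
        icc_obs: float = 0.0,
        sigma_district: float = 0.0,
        **kwargs,
    ) -> "OutcomeParams":
        """Build conditional-scale params from target marginal arm rates.

        ``rates`` maps arm -> marginal success probability; the placebo rate
        anchors the intercept and each arm effect is the difference of the
        conditional intercepts solving the respective marginal rates at the
        calibrated sigma, so simulated arm rates reproduce the targets.
        """
        b0, sigma = calibrate_glmm(rates["placebo"], icc_obs)
        effects = _zero_arms()
        for arm, rate in rates.items():
            if arm == "placebo":
                continue
            effects[arm] = _baseline_for_marginal(rate, sigma) - b0
        return cls(
            baseline_logit=b0,
            arm_effects=effects,
            sigma_village=sigma,
            sigma_district=sigma_district,
            **kwargs,
        )


@dataclass
class AttritionParams:
    """Logit models of phase II/III recontact and phase IV verification."""

    recontact_intercept: float = float(_LOGIT(0.695))  # 4,101 of 5,900 recontacted
    recontact_arm: dict[str, float] = field(default_factory=_zero_arms)
    recontact_covariates: dict[str, float] = field(default_factory=dict)
    # arm -> {covariate -> coef}: selective attrition that differs by arm,
    # the mechanism that actually biases naive contrasts under MAR
    recontact_arm_covariates: dict[str, dict[str, float]] = field(default_factory=dict)
    verified_intercept: float = float(_LOGIT(0.521))  # 3,075 of 5,900 verified
    verified_arm: dict[str, float] = field(default_factory=_zero_arms)
    verified_covariates: dict[str, float] = field(default_factory=dict)


def _default_outcomes() -> dict[str, OutcomeParams]:
    """Defaults calibrated to the trial's published arm rates and ICCs.

    Intention: placebo 71.0%, health 72.5%, low cash 81.7%, high cash 78.2%,
    observed ICC 0.15.  Reported: 36.3 / 38.5 / 41.9 / 38.1, ICC 0.06.
    Verified: 28.4 / 21.6 / 40.7 / 25.9, village ICC modest but with a strong
    district intercept (the register-verification success varied wildly by
    district, which is what drives the published verified ICC of 0.64).
    """
    intention = OutcomeParams.from_marginal_rates(
        {"placebo": 0.710, "health": 0.725, "low_cash": 0.817, "high_cash": 0.782},
        icc_obs=0.15,
        covariate_effects={"age": -0.0186, "female": 0.10},
    )
    reported = OutcomeParams.from_marginal_rates(
        {"placebo": 0.363, "health": 0.385, "low_cash": 0.419, "high_cash": 0.381},
        icc_obs=0.06,
        covariate_effects={"whatsapp": 0.15},
    )
    verified = OutcomeParams.from_marginal_rates(
        {"placebo": 0.284, "health": 0.216, "low_cash": 0.407, "high_cash": 0.259},
        icc_obs=0.06,
        sigma_district=1.8,
        covariate_effects={"age": 0.004},
    )
    # embedded-placebo spillover defaults: verified panel showed 38.3% for
    # placebo-video individuals in low-cash villages vs 26.8% in placebo
    # villages; other strata were null.
    verified.gamma_embedded = {
        "placebo": 0.0,
        "health": float(_LOGIT(0.228) - _LOGIT(0.268)),
        "low_cash": float(_LOGIT(0.383) - _LOGIT(0.268)),
        "high_cash": float(_LOGIT(0.263) - _LOGIT(0.268)),
    }
    # never-treated residents report much higher vaccination (53.9% in
    # placebo villages): they were not screened to be unvaccinated.
    reported.untreated_shift = float(_LOGIT(0.539) - _LOGIT(0.363))
    verified.untreated_shift = float(_LOGIT(0.298) - _LOGIT(0.284))
    return {"intention": intention, "reported": reported, "verified": verified}


@dataclass
class GeneratorConfig:
    """Everything the generator needs; reproducible from ``seed``.

    Village populations follow a log-normal truncated to [30, 5428] with
    median 1,040 (log-sd 0.7 puts the truncated mean near the reported 1,268).
    """

    n_districts: int = 6
    villages_per_district: int = 200
    quads_per_district: int = 13
    individuals_per_village: int = 21
    pop_median: float = 1040.0
    pop_log_sigma: float = 0.7
    pop_min: int = 30
    pop_max: int = 5428
    outcomes: dict[str, OutcomeParams] = field(default_factory=_default_outcomes)
    attrition: AttritionParams = field(default_factory=AttritionParams)
    # verified register status derived from reported status by directional
    # misreporting flips (over-reporting dominates), unless the verified
    # outcome is simulated from its own GLMM.
    verified_mode: str = "misreport"  # or "independent"
    misreport_1_to_0: float = 0.29
    misreport_0_to_1: float = 0.03
    spillover_per_village: float = 3.7  # Poisson mean; ~1,100 over 300 villages
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_log_sigma <= 0:
            raise ValueError("pop_log_sigma must be > 0")
        if self.verified_mode not in ("misreport", "independent"):
            raise ValueError("verified_mode must be 'misreport' or 'independent'")


@dataclass
class TrialData:
    """A generated trial: tables plus the plan and the generating truth."""

    individuals: pd.DataFrame
    villages: pd.DataFrame
    plan: AssignmentPlan
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# villages
# ---------------------------------------------------------------------------


def generate_villages(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[Village]:
    """Draw villages with truncated log-normal populations for each district."""
    rng = rng or np.random.default_rng(config.seed)
    mu = math.log(config.pop_median)
    lo = (math.log(config.pop_min) - mu) / config.pop_log_sigma
    hi = (math.log(config.pop_max) - mu) / config.pop_log_sigma
    villages: list[Village] = []
    for d in range(1, config.n_districts + 1):
        z = stats.truncnorm.rvs(
            lo, hi, size=config.villages_per_district, random_state=rng
        )
        pops = np.exp(mu + config.pop_log_sigma * z).round().astype(int)
        pops = np.clip(pops, config.pop_min, config.pop_max)
        for j, p in enumerate(pops):
            villages.append(
                Village(
                    village_id=f"d{d}-v{j + 1:03d}",
                    district_id=f"d{d}",
                    population=int(p),
                )
            )
    return villages


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _truncnorm_underlying(mean: float, sd: float, lower: float, upper: float):
    """Parameters (mu0, sigma0) of the untruncated normal whose truncation to
    [lower, upper] has the requested mean and SD."""

    def gap(x):
        mu0, log_s0 = x
        s0 = math.exp(log_s0)
        a, b = (lower - mu0) / s0, (upper - mu0) / s0
        m, v = stats.truncnorm.stats(a, b, loc=mu0, scale=s0, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.root(gap, x0=[mean, math.log(sd)], tol=1e-10)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"truncated-normal calibration failed: {sol.message}")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _trunc_draw(
    rng: np.random.Generator, n: int, mean: float, sd: float, lower: float, upper: float
) -> np.ndarray:
    mu0, s0 = _truncnorm_underlying(mean, sd, lower, upper)
    a, b = (lower - mu0) / s0, (upper - mu0) / s0
    return stats.truncnorm.rvs(a, b, loc=mu0, scale=s0, size=n, random_state=rng)


def draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` participants' covariates with the trial's marginal moments.

    Marginals only -- covariates are drawn independently since only means and
    SDs per arm are published.  Age is truncated at the 18-year eligibility
    floor with underlying parameters solved so the *truncated* mean/SD equal
    the published 37.4 (16.4).
    """
    emp = rng.choice(
        ["full", "part", "unemployed", "other"], size=n, p=[0.590, 0.137, 0.126, 0.147]
    )
    edu = rng.choice(
        ["none", "low", "medium", "high"], size=n, p=[0.181, 0.196, 0.553, 0.070]
    )
    return pd.DataFrame(
        {
            "female": (rng.random(n) < 0.571).astype(int),
            "age": _trunc_draw(rng, n, 37.4, 16.4, 18.0, 100.0),
            "household_size": np.maximum(
                1, np.rint(rng.normal(5.0, 2.7, size=n))
            ).astype(int),
            "children_u18": np.maximum(
                0, np.rint(rng.normal(1.8, 2.2, size=n))
            ).astype(int),
            "employment": emp,
            "weekly_food_spend": _trunc_draw(rng, n, 161.6, 99.7, 0.0, 2000.0),
            "weekly_nonfood_spend": np.maximum(
                0.0, rng.normal(37.1, 52.1, size=n)
            ),
            "finances_score": rng.choice(
                [1, 2, 3, 4, 5], size=n, p=[0.25, 0.35, 0.25, 0.10, 0.05]
            ),
            "education": edu,
            "whatsapp": (rng.random(n) < 0.284).astype(int),
            "dist_clinic_km": _trunc_draw(rng, n, 5.6, 4.4, 0.05, 60.0),
        }
    )


def generate_individuals(
    village: Village, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Covariate table for one village's sampled participants."""
    df = draw_covariates(config.individuals_per_village, rng)
    df.insert(0, "individual_id", [f"{village.village_id}-i{j + 1}" for j in range(len(df))])
    df.insert(1, "village_id", village.village_id)
    df.insert(2, "district_id", village.district_id)
    return df


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def _linear_predictor(
    df: pd.DataFrame, params: OutcomeParams, u_village: Mapping[str, float],
    u_district: Mapping[str, float],
) -> np.ndarray:
    eta = np.full(len(df), params.baseline_logit)
    video = df["video"].to_numpy()
    arm = df["arm"].to_numpy()
    untreated = df["untreated_spillover"].to_numpy().astype(bool)
    for a in ARMS:
        eff = params.arm_effects.get(a, 0.0)
        if eff:
            eta += eff * ((video == a) & ~untreated)
    # spillover onto embedded placebos: placebo video inside a treated village
    embedded = (video == "placebo") & (arm != "placebo") & ~untreated
    for a in TREATED_ARMS:
        g = params.gamma_embedded.get(a, 0.0)
        if g:
            eta += g * (embedded & (arm == a))
    if untreated.any():
        eta += params.untreated_shift * untreated
        for a in ARMS:
            g = params.gamma_untreated.get(a, 0.0)
            if g:
                eta += g * (untreated & (arm == a))
    for col, w in params.covariate_effects.items():
        x = df[col].to_numpy(dtype=float)
        eta += w * (x - x.mean())  # centred so the intercept keeps its meaning
    eta += df["village_id"].map(u_village).to_numpy(dtype=float)
    if params.sigma_district > 0:
        eta += df["district_id"].map(u_district).to_numpy(dtype=float)
    return eta


def simulate_outcomes(
    records: pd.DataFrame,
    plan: AssignmentPlan,
    outcomes: Mapping[str, OutcomeParams],
    rng: np.random.Generator,
    verified_mode: str = "misreport",
    misreport_1_to_0: float = 0.29,
    misreport_0_to_1: float = 0.03,
) -> pd.DataFrame:
    """Attach binary outcomes to a covariate table.

    ``records`` must carry village_id, district_id, video, arm and an
    ``untreated_spillover`` flag (created here if absent, all zero).  Each
    outcome draws its own village (and optional district) intercepts.  In
    ``misreport`` mode the verified register status is the reported status
    flipped with direction-specific misreport probabilities; in
    ``independent`` mode it is simulated from its own GLMM.
    """
    df = records.copy()
    if "untreated_spillover" not in df:
        df["untreated_spillover"] = 0
    if "arm" not in df:
        df["arm"] = df["village_id"].map(plan.village_arm)
    unknown = df["arm"].isna()
    if unknown.any():
        bad = df.loc[unknown, "village_id"].unique()[:5]
        raise ValueError(f"villages not in assignment plan: {list(bad)}")

    village_ids = df["village_id"].unique()
    district_ids = df["district_id"].unique()

    def draw(name: str, params: OutcomeParams) -> np.ndarray:
        u_v = dict(zip(village_ids, rng.normal(0.0, params.sigma_village, len(village_ids))))
        u_d = dict(zip(district_ids, rng.normal(0.0, params.sigma_district, len(district_ids))))
        p = _EXPIT(_linear_predictor(df, params, u_v, u_d))
        return (rng.random(len(df)) < p).astype(int)

    if "intention" in outcomes:
        df["intention"] = draw("intention", outcomes["intention"])
        # never-treated residents were not asked the intention item
        df.loc[df["untreated_spillover"] == 1, "intention"] = np.nan
    if "reported" in outcomes:
        df["reported_vax"] = draw("reported", outcomes["reported"])
    if verified_mode == "misreport":
        rep = df["reported_vax"].to_numpy()
        flip_down = rng.random(len(df)) < misreport_1_to_0
        flip_up = rng.random(len(df)) < misreport_0_to_1
        df["verified_vax"] = np.where(rep == 1, (~flip_down).astype(int), flip_up.astype(int))
    elif "verified" in outcomes:
        df["verified_vax"] = draw("verified", outcomes["verified"])
    return df


def simulate_attrition(
    records: pd.DataFrame, params: AttritionParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw recontact / verification indicators and mask unobserved outcomes.

    Recontact (phase II/III) and register verification (phase IV) are
    independent logit draws on arm and covariates; defaults give ~30% and
    ~48% attrition.  Reported status is missing unless recontacted; verified
    status is missing unless found in the register.  The never-treated
    spillover sample is surveyed by construction (recontacted = 1).
    """
    df = records.copy()

    def logits(intercept: float, arm_coefs: Mapping[str, float],
               cov_coefs: Mapping[str, float]) -> np.ndarray:
        eta = np.full(len(df), intercept)
        arm = df["arm"].to_numpy()
        for a, c in arm_coefs.items():
            if c:
                eta += c * (arm == a)
        for col, c in cov_coefs.items():
            x = df[col].to_numpy(dtype=float)
            eta += c * (x - x.mean())
        return eta

    eta_re = logits(params.recontact_intercept, params.recontact_arm,
                    params.recontact_covariates)
    arm_col = df["arm"].to_numpy()
    for a, covs in params.recontact_arm_covariates.items():
        in_arm = arm_col == a
        for col, c in covs.items():
            x = df[col].to_numpy(dtype=float)
            eta_re += c * (x - x.mean()) * in_arm
    p_re = _EXPIT(eta_re)
    p_ve = _EXPIT(logits(params.verified_intercept, params.verified_arm,
                         params.verified_covariates))
    df["p_recontact"] = p_re
    df["recontacted"] = (rng.random(len(df)) < p_re).astype(int)
    df["verified_status_found"] = (rng.random(len(df)) < p_ve).astype(int)
    untreated = df["untreated_spillover"] == 1
    df.loc[untreated, "recontacted"] = 1
    df.loc[untreated, "p_recontact"] = 1.0
    if "reported_vax" in df:
        df.loc[df["recontacted"] == 0, "reported_vax"] = np.nan
    if "verified_vax" in df:
        df.loc[df["verified_status_found"] == 0, "verified_vax"] = np.nan
    return df


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def generate_trial(config: GeneratorConfig | None = None, seed: int | None = None) -> TrialData:
    """Generate a complete synthetic trial.

    Villages -> two-stage randomization -> participant covariates ->
    clustered outcomes -> never-treated spillover sample -> attrition.
    """
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    master = np.random.SeedSequence(config.seed)
    s_vill, s_design, s_cov, s_out, s_attr, s_spill = master.spawn(6)

    villages = generate_villages(config, np.random.default_rng(s_vill))
    plan = randomize_trial(
        villages,
        quads_per_district=config.quads_per_district,
        individuals_per_village=config.individuals_per_village,
        seed=int(s_design.generate_state(1)[0] % (2**31)),
    )
    by_id = {v.village_id: v for v in villages}
    selected = [by_id[vid] for quad in plan.quadruplets for vid in quad.members]

    rng_cov = np.random.default_rng(s_cov)
    n_main = len(selected) * config.individuals_per_village
    cov = draw_covariates(n_main, rng_cov)
    cov.insert(0, "individual_id", list(plan.individual_video))
    cov.insert(1, "village_id", [plan.individual_village[i] for i in plan.individual_video])
    cov.insert(2, "district_id", [by_id[v].district_id for v in cov["village_id"]])
    cov["video"] = [plan.individual_video[i] for i in cov["individual_id"]]
    cov["arm"] = cov["village_id"].map(plan.village_arm)
    cov["untreated_spillover"] = 0

    # never-treated residents sampled in the phase III spillover survey
    rng_spill = np.random.default_rng(s_spill)
    spill_rows = []
    for v in selected:
        m = rng_spill.poisson(config.spillover_per_village)
        if m == 0:
            continue
        extra = draw_covariates(m, rng_spill)
        extra.insert(0, "individual_id", [f"{v.village_id}-s{j + 1}" for j in range(m)])
        extra.insert(1, "village_id", v.village_id)
        extra.insert(2, "district_id", v.district_id)
        extra["video"] = "none"
        extra["arm"] = plan.village_arm[v.village_id]
        extra["untreated_spillover"] = 1
        spill_rows.append(extra)
    if spill_rows:
        cov = pd.concat([cov, *spill_rows], ignore_index=True)

    rng_out = np.random.default_rng(s_out)
    cov = simulate_outcomes(
        cov,
        plan,
        config.outcomes,
        rng_out,
        verified_mode=config.verified_mode,
        misreport_1_to_0=config.misreport_1_to_0,
        misreport_0_to_1=config.misreport_0_to_1,
    )
    cov = simulate_attrition(cov, config.attrition, np.random.default_rng(s_attr))

    vill_df = pd.DataFrame(
        {
            "village_id": [v.village_id for v in selected],
            "district_id": [v.district_id for v in selected],
            "population": [v.population for v in selected],
            "arm": [plan.village_arm[v.village_id] for v in selected],
        }
    )
    return TrialData(individuals=cov, villages=vill_df, plan=plan, config=config)
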