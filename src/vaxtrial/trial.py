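"""Trial-level analysis: one model object over the individual table.

:class:`TrialModel` is built from the individual-level table (synthetic or
user-supplied) and its :meth:`~TrialModel.fit` returns a
:class:`TrialResults` carrying arm rates, cluster-robust contrasts, ICCs and
the logistic regressions of the pre-registered analysis:

* direct effects: outcome ~ Health + Cash (or LowCash + HighCash) + covariates
* embedded-placebo spillover: adds HealthPlacebo / CashPlacebo dummies, or the
  same contrasts restricted to placebo-video recipients
* never-treated spillover: village-arm contrasts in the untreated sample

plus attrition logits, inverse-probability reweighting and a
leave-one-district-out sensitivity loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .design import ARMS, TREATED_ARMS
from .estimators import (
    DiffEstimate,
    ICCEstimate,
    arm_rate,
    diff_in_means_clustered,
    icc_anova,
    smd_balance,
)
from .logit import ClusterLogit, ClusterLogitResults

__all__ = [
    "OUTCOME_COLUMNS",
    "COVARIATE_TERMS",
    "add_design_indicators",
    "fit_logistic_clustered",
    "direct_effect_formula",
    "spillover_contrasts",
    "attrition_logit",
    "ipw_reestimate",
    "district_sensitivity",
    "TrialModel",
    "TrialResults",
]

#: outcome column per phase
OUTCOME_COLUMNS = {"intention": "intention", "reported": "reported_vax", "verified": "verified_vax"}

#: covariate adjustment set of the multivariable models (scalings follow the
#: published convention: age per 10 years, weekly food spend per 50 cedis)
COVARIATE_TERMS = [
    "dist_clinic_km",
    "age10",
    "male",
    "edu_low",
    "edu_medium",
    "edu_high",
    "employed",
    "food50",
    "whatsapp",
]


def add_design_indicators(df: pd.DataFrame) -> pd.DataFrame:
    """Attach the dummy variables used by the regression specifications.

    Treatment dummies follow the video actually shown (embedded placebos carry
    video == 'placebo'); the ``*_placebo`` dummies mark embedded placebos by
    their village's arm; the ``vcash_*`` dummies mark never-treated residents
    by their village's arm; ``arm_*`` dummies follow the village assignment.
    """
    out = df.copy()
    if "untreated_spillover" not in out:
        out["untreated_spillover"] = 0
    untreated = out["untreated_spillover"].astype(bool)
    video = out["video"].where(~untreated, "none")
    for a in TREATED_ARMS:
        out[a] = ((video == a) & ~untreated).astype(int)
        out[f"{a}_placebo"] = ((video == "placebo") & (out["arm"] == a) & ~untreated).astype(int)
        out[f"vcash_{a}"] = (untreated & (out["arm"] == a)).astype(int)
        out[f"arm_{a}"] = (out["arm"] == a).astype(int)
    out["cash"] = out["low_cash"] | out["high_cash"]
    out["cash_placebo"] = out["low_cash_placebo"] | out["high_cash_placebo"]
    if "female" in out:
        out["male"] = 1 - out["female"]
    if "age" in out:
        out["age10"] = out["age"] / 10.0
    if "weekly_food_spend" in out:
        out["food50"] = out["weekly_food_spend"] / 50.0
    if "education" in out:
        for level in ("low", "medium", "high"):
            out[f"edu_{level}"] = (out["education"] == level).astype(int)
    if "employment" in out:
        out["employed"] = out["employment"].isin(["full", "part"]).astype(int)
    return out


def direct_effect_formula(
    outcome: str,
    treatment: str = "cash",
    covariates: bool = True,
    districts: bool = True,
    spillover: str | None = None,
) -> str:
    """Formula for the pre-registered logistic specifications.

    treatment='cash' pools the two cash arms; 'lowhigh' separates them.
    spillover='embedded' adds the embedded-placebo dummies; 'embedded_only'
    is for the placebo-video subsample; 'untreated' is for the never-treated
    sample (village-arm dummies).
    """
    if treatment == "cash":
        terms = ["health", "cash"]
    elif treatment == "lowhigh":
        terms = ["health", "low_cash", "high_cash"]
    else:
        raise ValueError("treatment must be 'cash' or 'lowhigh'")
    if spillover == "embedded":
        terms = ["health", "health_placebo", "cash", "cash_placebo"]
    elif spillover == "embedded_only":
        terms = ["health_placebo", "cash_placebo"]
    elif spillover == "untreated":
        terms = ["arm_health", "arm_low_cash", "arm_high_cash"]
    elif spillover is not None:
        raise ValueError(f"unknown spillover spec {spillover!r}")
    if covariates:
        terms += COVARIATE_TERMS
    if districts:
        terms.append("C(district_id)")
    return f"{outcome} ~ " + " + ".join(terms)


def fit_logistic_clustered(
    records: pd.DataFrame, model_spec: str, cluster: str = "village_id", weights=None
) -> ClusterLogitResults:
    """Fit ``outcome ~ terms`` with cluster-robust errors.

    ``model_spec`` may carry the cluster inline as ``"y ~ x1 + x2 | village_id"``.
    """
    if "|" in model_spec:
        model_spec, cluster = (s.strip() for s in model_spec.rsplit("|", 1))
    data = add_design_indicators(records)
    return ClusterLogit.from_formula(model_spec, data, cluster=cluster, weights=weights).fit()


# ---------------------------------------------------------------------------
# spillover
# ---------------------------------------------------------------------------


def spillover_contrasts(records: pd.DataFrame, outcome: str = "verified_vax") -> dict:
    """Embedded-placebo and never-treated spillover estimates.

    Embedded contrasts compare placebo-video recipients in each treated
    village arm with participants in placebo villages; untreated contrasts
    compare never-treated residents across village arms.  Returns the
    cluster-robust differences plus the corresponding logistic fits.
    """
    df = add_design_indicators(records)
    treated_sample = df[df["untreated_spillover"] == 0]
    embedded: dict[str, DiffEstimate] = {}
    emb = treated_sample[treated_sample["video"] == "placebo"]
    for a in TREATED_ARMS:
        try:
            embedded[a] = diff_in_means_clustered(emb, outcome, a, "placebo", by="arm")
        except ValueError as err:
            warnings.warn(f"embedded contrast {a} skipped: {err}")
    untreated: dict[str, DiffEstimate] = {}
    unt = df[df["untreated_spillover"] == 1]
    if len(unt):
        for a in TREATED_ARMS:
            try:
                untreated[a] = diff_in_means_clustered(unt, outcome, a, "placebo", by="arm")
            except ValueError as err:
                warnings.warn(f"untreated contrast {a} skipped: {err}")
    fits: dict[str, ClusterLogitResults] = {}
    try:
        fits["embedded_full"] = fit_logistic_clustered(
            treated_sample, direct_effect_formula(outcome, spillover="embedded")
        )
        fits["embedded_placebo_only"] = fit_logistic_clustered(
            emb, direct_effect_formula(outcome, spillover="embedded_only")
        )
    except ValueError as err:  # e.g. a stratum entirely missing
        warnings.warn(f"embedded spillover fit skipped: {err}")
    if len(unt):
        try:
            fits["untreated"] = fit_logistic_clustered(
                unt, direct_effect_formula(outcome, spillover="untreated")
            )
        except ValueError as err:
            warnings.warn(f"untreated spillover fit skipped: {err}")
    return {"embedded": embedded, "untreated": untreated, "fits": fits}


# ---------------------------------------------------------------------------
# attrition and reweighting
# ---------------------------------------------------------------------------

_PHASE_COLUMN = {"recontact": "recontacted", "verified": "verified_status_found"}


def attrition_logit(
    records: pd.DataFrame,
    phase: str = "recontact",
    covariates: bool = False,
    village_fe: bool = False,
) -> ClusterLogitResults:
    """Differential-attrition logit: retention on treatment arm.

    Model 1: arm dummies only; model 2 adds covariates; model 3 adds village
    fixed effects (then treatment variation comes from the embedded-placebo
    videos, and single-observation villages are dropped).
    """
    col = _PHASE_COLUMN[phase]
    df = add_design_indicators(records)
    df = df[df["untreated_spillover"] == 0]
    if village_fe:
        sizes = df.groupby("village_id")["village_id"].transform("size")
        if (sizes < 2).any():
            warnings.warn("dropping single-observation villages for fixed effects")
            df = df[sizes >= 2]
        terms = ["health", "low_cash", "high_cash", "C(village_id)"]
    else:
        terms = ["arm_health", "arm_low_cash", "arm_high_cash"]
    if covariates:
        terms += COVARIATE_TERMS
    return fit_logistic_clustered(df, f"{col} ~ " + " + ".join(terms))


def ipw_reestimate(
    records: pd.DataFrame,
    phase: str = "recontact",
    outcome: str = "reported_vax",
    trim_quantile: float = 0.99,
    interactions: bool = False,
) -> dict:
    """Re-estimate treatment effects weighting by inverse retention probability.

    A retention logit on arm + covariates (with ``interactions`` also
    arm-by-covariate products, for selective attrition that differs by arm)
    yields fitted probabilities; each retained participant gets weight 1/p,
    trimmed at the given weight quantile (1.0 leaves weights untrimmed).
    Returns the weighted arm contrasts and weighted logistic fits.
    """
    col = _PHASE_COLUMN[phase]
    df = add_design_indicators(records)
    df = df[df["untreated_spillover"] == 0].copy()
    arm_terms = ["arm_health", "arm_low_cash", "arm_high_cash"]
    ret_terms = arm_terms + COVARIATE_TERMS
    if interactions:
        ret_terms += [f"{a}:{c}" for a in arm_terms for c in COVARIATE_TERMS]
    ret_fit = fit_logistic_clustered(df, f"{col} ~ " + " + ".join(ret_terms))
    p_hat = ret_fit.fittedvalues
    retained = df[col].to_numpy() == 1
    if np.any(p_hat[retained] <= 0.0):
        raise ValueError("retained record with zero predicted retention probability")
    df["ipw"] = 1.0 / p_hat
    kept = df[retained].copy()
    if trim_quantile < 1.0:
        cap = kept["ipw"].quantile(trim_quantile)
        kept["ipw"] = kept["ipw"].clip(upper=cap)
    contrasts = {}
    for a in TREATED_ARMS:
        try:
            contrasts[a] = diff_in_means_clustered(
                kept, outcome, a, "placebo", by="arm", weights="ipw"
            )
        except ValueError as err:
            warnings.warn(f"IPW contrast {a} skipped: {err}")
    fit = fit_logistic_clustered(
        kept, direct_effect_formula(outcome, treatment="lowhigh"), weights="ipw"
    )
    return {"weights": kept["ipw"], "contrasts": contrasts, "fit": fit, "retention_fit": ret_fit}


def district_sensitivity(
    records: pd.DataFrame,
    outcome: str = "verified_vax",
    treatment: str = "lowhigh",
    covariates: bool = True,
    districts: bool = True,
) -> dict[str, ClusterLogitResults | Exception]:
    """Leave-one-district-out refits of the multivariable model."""
    district_ids = sorted(records["district_id"].unique())
    if len(district_ids) < 2:
        raise ValueError("need >= 2 districts")
    if len(district_ids) == 2:
        districts = False  # a single remaining district leaves no indicator
    out: dict[str, ClusterLogitResults | Exception] = {}
    for d in district_ids:
        sub = records[records["district_id"] != d]
        try:
            out[d] = fit_logistic_clustered(
                sub,
                direct_effect_formula(
                    outcome, treatment=treatment, covariates=covariates,
                    districts=districts,
                ),
            )
        except Exception as err:  # record and continue with other folds
            out[d] = err
    return out


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------


class TrialModel:
    """The full estimation suite over one individual-level table.

    Parameters
    ----------
    individuals : DataFrame with village_id, district_id, arm, video, the
        covariates and outcome columns (as produced by the generator or read
        from a delimited file with the same schema).
    cluster : cluster identifier column (village).
    """

    def __init__(self, individuals: pd.DataFrame, cluster: str = "village_id"):
        self.data = add_design_indicators(individuals)
        self.cluster = cluster

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TrialModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(
        self,
        outcomes: tuple[str, ...] = ("intention", "reported_vax", "verified_vax"),
        covariates: bool = True,
    ) -> "TrialResults":
        df = self.data
        treated = df[df["untreated_spillover"] == 0]
        rates, contrasts, iccs, fits = {}, {}, {}, {}
        # groups follow the video actually shown, as in the published tables:
        # the placebo column pools placebo villages with the embedded placebos
        for outcome in outcomes:
            if outcome not in df or treated[outcome].notna().sum() == 0:
                continue
            rates[outcome] = {
                a: arm_rate(treated, outcome, a, by="video")
                for a in ARMS
                if ((treated["video"] == a) & treated[outcome].notna()).any()
            }
            contrasts[outcome] = {}
            for a in TREATED_ARMS:
                try:
                    contrasts[outcome][(a, "placebo")] = diff_in_means_clustered(
                        treated, outcome, a, "placebo", by="video", cluster=self.cluster
                    )
                except ValueError as err:
                    warnings.warn(f"contrast {a} vs placebo skipped for {outcome}: {err}")
            try:
                contrasts[outcome][("low_cash", "high_cash")] = diff_in_means_clustered(
                    treated, outcome, "low_cash", "high_cash", by="video", cluster=self.cluster
                )
            except ValueError as err:
                warnings.warn(f"low vs high contrast skipped for {outcome}: {err}")
            try:
                iccs[outcome] = icc_anova(treated, outcome, cluster=self.cluster)
            except ValueError as err:
                warnings.warn(f"ICC skipped for {outcome}: {err}")
            for spec in ("cash", "lowhigh"):
                try:
                    fits[(outcome, spec)] = fit_logistic_clustered(
                        treated,
                        direct_effect_formula(outcome, treatment=spec, covariates=covariates),
                        cluster=self.cluster,
                    )
                except ValueError as err:
                    warnings.warn(f"logistic fit ({outcome}, {spec}) skipped: {err}")
        return TrialResults(
            model=self, arm_rates=rates, contrasts=contrasts, iccs=iccs, fits=fits
        )

    # convenience pass-throughs so the analysis hangs off the model object
    def spillover(self, outcome: str = "verified_vax") -> dict:
        return spillover_contrasts(self.data, outcome)

    def attrition(self, phase: str = "recontact", **kwargs) -> ClusterLogitResults:
        return attrition_logit(self.data, phase, **kwargs)

    def ipw(self, **kwargs) -> dict:
        return ipw_reestimate(self.data, **kwargs)

    def district_sensitivity(self, **kwargs) -> dict:
        return district_sensitivity(self.data, **kwargs)

    def balance(self, covariates: list[str] | None = None) -> pd.DataFrame:
        covs = covariates or [
            "female", "age", "household_size", "children_u18", "employed",
            "weekly_food_spend", "weekly_nonfood_spend", "finances_score",
            "whatsapp", "dist_clinic_km",
        ]
        covs = [c for c in covs if c in self.data]
        pairs = list(combinations(ARMS, 2))
        treated = self.data[self.data["untreated_spillover"] == 0]
        return smd_balance(treated, covs, pairs, by="arm")


@dataclass
class TrialResults:
    """Everything :meth:`TrialModel.fit` estimates, with a printable summary."""

    model: TrialModel
    arm_rates: dict
    contrasts: dict[str, dict[tuple[str, str], DiffEstimate]]
    iccs: dict[str, ICCEstimate]
    fits: dict[tuple[str, str], ClusterLogitResults]

    def summary(self) -> str:
        lines = []
        for outcome, rates in self.arm_rates.items():
            lines.append(f"== {outcome} ==")
            for a, (rate, num, den) in rates.items():
                lines.append(f"  {a:>10}: {rate:5.1f}%  ({num} of {den})")
            if outcome in self.iccs:
                lines.append(f"  {self.iccs[outcome]}")
            for pair, est in self.contrasts.get(outcome, {}).items():
                lines.append(f"  {est}")
        for (outcome, spec), fit in self.fits.items():
            ors = fit.odds_ratios()
            keep = [t for t in ("health", "cash", "low_cash", "high_cash") if t in ors.index]
            pretty = ", ".join(
                f"{t} OR {ors.loc[t, 'OR']:.2f} ({ors.loc[t, 'ci_low']:.2f}, "
                f"{ors.loc[t, 'ci_high']:.2f})"
                for t in keep
            )
            lines.append(f"logit [{outcome}, {spec}]: {pretty}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "arm_rates": {
                o: {a: {"rate": r, "num": n, "den": d} for a, (r, n, d) in rates.items()}
                for o, rates in self.arm_rates.items()
            },
            "contrasts": {
                o: {f"{a}-{b}": vars(est) for (a, b), est in c.items()}
                for o, c in self.contrasts.items()
            },
            "iccs": {o: vars(icc) for o, icc in self.iccs.items()},
            "fits": {f"{o}:{s}": fit.to_dict() for (o, s), fit in self.fits.items()},
        }
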