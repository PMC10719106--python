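"""Trial-level analysis: spillover estimands, attrition, IPW, sensitivity."""

import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from vaxtrial.design import TREATED_ARMS
from vaxtrial.population import (
    AttritionParams,
    GeneratorConfig,
    OutcomeParams,
    generate_trial,
)
from vaxtrial.trial import (
    TrialModel,
    add_design_indicators,
    attrition_logit,
    direct_effect_formula,
    district_sensitivity,
    fit_logistic_clustered,
    ipw_reestimate,
    spillover_contrasts,
)


def null_config(**overrides):
    """Generator with no treatment or spillover effects anywhere."""
    outcomes = {
        "intention": OutcomeParams.from_marginal_rates(
            {"placebo": 0.7, "health": 0.7, "low_cash": 0.7, "high_cash": 0.7},
            icc_obs=0.05,
        ),
        "reported": OutcomeParams.from_marginal_rates(
            {"placebo": 0.4, "health": 0.4, "low_cash": 0.4, "high_cash": 0.4},
            icc_obs=0.05,
        ),
    }
    base = dict(
        outcomes=outcomes,
        verified_mode="misreport",
        attrition=AttritionParams(recontact_intercept=20.0, verified_intercept=20.0),
    )
    base.update(overrides)
    return small_config(**base)


class TestIndicators:
    def test_dummies_partition_sample(self, small_trial):
        df = add_design_indicators(small_trial.individuals)
        treated = df[df.untreated_spillover == 0]
        groups = (
            treated[["health", "low_cash", "high_cash"]].sum(axis=1)
            + (treated["video"] == "placebo")
        )
        assert (groups == 1).all()
        # embedded placebo dummies only inside matching village arms
        for a in TREATED_ARMS:
            flagged = treated[treated[f"{a}_placebo"] == 1]
            assert (flagged["arm"] == a).all()
            assert (flagged["video"] == "placebo").all()

    def test_scalings(self, small_trial):
        df = add_design_indicators(small_trial.individuals)
        assert np.allclose(df["age10"], df["age"] / 10)
        assert np.allclose(df["food50"], df["weekly_food_spend"] / 50)
        assert ((df["male"] == 1) == (df["female"] == 0)).all()


class TestModelFormulas:
    def test_spec_grammar_with_inline_cluster(self, small_trial):
        fit = fit_logistic_clustered(
            small_trial.individuals[small_trial.individuals.untreated_spillover == 0],
            "intention ~ health + cash | village_id",
        )
        assert set(fit.model.exog_names) == {"Intercept", "health", "cash"}

    def test_direct_effect_formula_variants(self):
        f = direct_effect_formula("verified_vax", treatment="lowhigh",
                                  covariates=False, districts=False)
        assert f == "verified_vax ~ health + low_cash + high_cash"
        with pytest.raises(ValueError):
            direct_effect_formula("y", treatment="bogus")


class TestSpillover:
    def test_null_generator_contrasts_center_on_zero(self):
        trial = generate_trial(null_config(), seed=5)
        res = spillover_contrasts(trial.individuals, outcome="reported_vax")
        for est in {**res["embedded"], **res["untreated"]}.values():
            # zero spillover truth: the 95% CI should almost always cover 0
            assert est.ci_low < 0 < est.ci_high or abs(est.diff) < 4 * est.se

    def test_restricted_fit_equals_full_fit_on_saturated_spec(self):
        # without covariates, the placebo-video-only regression coefficients
        # equal the matching coefficients of the full embedded-placebo model
        trial = generate_trial(null_config(), seed=6)
        df = add_design_indicators(trial.individuals)
        treated = df[df.untreated_spillover == 0]
        emb = treated[treated["video"] == "placebo"]
        full = fit_logistic_clustered(
            treated,
            "reported_vax ~ health + health_placebo + cash + cash_placebo",
        )
        restricted = fit_logistic_clustered(
            emb, "reported_vax ~ health_placebo + cash_placebo"
        )
        names_f = full.model.exog_names
        names_r = restricted.model.exog_names
        for term in ("Intercept", "health_placebo", "cash_placebo"):
            assert full.params[names_f.index(term)] == pytest.approx(
                restricted.params[names_r.index(term)], abs=1e-6
            )

    def test_positive_embedded_spillover_recovered(self):
        cfg = null_config()
        cfg.outcomes["reported"].gamma_embedded = {
            "placebo": 0.0, "health": 0.0, "low_cash": 1.0, "high_cash": 0.0
        }
        cfg.villages_per_district = 60
        cfg.quads_per_district = 12
        trial = generate_trial(cfg, seed=8)
        res = spillover_contrasts(trial.individuals, outcome="reported_vax")
        assert res["embedded"]["low_cash"].diff > 0
        assert res["embedded"]["low_cash"].p < 0.05


class TestAttrition:
    def test_null_arm_coefficients_covered(self):
        trial = generate_trial(small_config(), seed=9)
        fit = attrition_logit(trial.individuals, phase="recontact")
        ci = fit.conf_int()
        for term in ("arm_health", "arm_low_cash", "arm_high_cash"):
            j = fit.model.exog_names.index(term)
            assert ci[j, 0] < 0 < ci[j, 1]

    def test_mar_on_arm_sign_recovered(self):
        cfg = small_config(
            villages_per_district=60, quads_per_district=12,
            attrition=AttritionParams(
                recontact_arm={"placebo": 0.0, "health": 0.0,
                               "low_cash": -0.8, "high_cash": 0.0}
            ),
        )
        trial = generate_trial(cfg, seed=10)
        fit = attrition_logit(trial.individuals, phase="recontact")
        j = fit.model.exog_names.index("arm_low_cash")
        assert fit.params[j] < 0
        assert fit.pvalues[j] < 0.05

    def test_village_fixed_effects_drop_singletons(self, small_trial):
        df = small_trial.individuals.copy()
        lone = df.iloc[[0]].copy()
        lone["individual_id"] = "lone-1"
        lone["village_id"] = "lonely-village"
        df = pd.concat([df, lone], ignore_index=True)
        with pytest.warns(UserWarning, match="single-observation"):
            fit = attrition_logit(df, phase="recontact", village_fe=True)
        assert not any("lonely-village" in t for t in fit.model.exog_names)


class TestIPW:
    def test_no_attrition_identity(self):
        trial = generate_trial(null_config(), seed=12)
        res = ipw_reestimate(trial.individuals, phase="recontact",
                             outcome="reported_vax")
        assert np.allclose(res["weights"], 1.0, atol=1e-6)
        from vaxtrial.estimators import diff_in_means_clustered
        treated = trial.individuals[trial.individuals.untreated_spillover == 0]
        naive = diff_in_means_clustered(treated, "reported_vax",
                                        "low_cash", "placebo", by="arm")
        assert res["contrasts"]["low_cash"].diff == pytest.approx(naive.diff, abs=1e-9)

    def test_trim_passthrough(self):
        trial = generate_trial(small_config(), seed=13)
        res_t = ipw_reestimate(trial.individuals, trim_quantile=1.0)
        res_trim = ipw_reestimate(trial.individuals, trim_quantile=0.5)
        assert res_trim["weights"].max() <= res_t["weights"].max()
        assert res_t["weights"].min() >= 1.0 - 1e-9

    def test_ipw_reduces_selective_attrition_bias(self):
        # selective attrition in the low-cash arm only: heavier WhatsApp users
        # (who report vaccination more) drop out of that arm, biasing the
        # naive low-cash contrast; a correctly specified retention model
        # should pull the estimate back toward the truth more often than not
        reps, ipw_better = 30, 0
        for s in range(reps):
            cfg = null_config(
                villages_per_district=40, quads_per_district=8,
                individuals_per_village=20,
            )
            cfg.outcomes["reported"].covariate_effects = {"whatsapp": 2.5}
            cfg.attrition = AttritionParams(
                recontact_intercept=1.2,
                recontact_arm_covariates={"low_cash": {"whatsapp": -3.0}},
            )
            trial = generate_trial(cfg, seed=100 + s)
            from vaxtrial.estimators import diff_in_means_clustered
            treated = trial.individuals[trial.individuals.untreated_spillover == 0]
            naive = diff_in_means_clustered(
                treated, "reported_vax", "low_cash", "placebo", by="arm"
            ).diff
            res = ipw_reestimate(trial.individuals, phase="recontact",
                                 outcome="reported_vax", interactions=True)
            ipw = res["contrasts"]["low_cash"].diff
            if abs(ipw - 0.0) < abs(naive - 0.0):  # generator truth: no effect
                ipw_better += 1
        assert ipw_better / reps >= 0.7


class TestDistrictSensitivity:
    def test_fold_count(self, small_trial):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            folds = district_sensitivity(
                small_trial.individuals[small_trial.individuals.untreated_spillover == 0],
                outcome="intention",
            )
        assert len(folds) == small_trial.individuals["district_id"].nunique()

    def test_single_district_rejected(self):
        df = pd.DataFrame({"district_id": ["d1"] * 4})
        with pytest.raises(ValueError):
            district_sensitivity(df)

    def test_constructed_heterogeneity_moves_pooled_or(self, rng):
        # district B carries no effect; dropping it must raise the pooled OR
        rows = []
        for d, eff in (("dA", 1.2), ("dB", 0.0)):
            for v in range(40):
                arm = ["placebo", "health", "low_cash", "high_cash"][v % 4]
                logit = -0.5 + (eff if arm == "low_cash" else 0.0)
                p = 1 / (1 + np.exp(-logit))
                for i in range(20):
                    rows.append({
                        "individual_id": f"{d}v{v}i{i}", "village_id": f"{d}v{v}",
                        "district_id": d, "arm": arm, "video": arm,
                        "untreated_spillover": 0,
                        "verified_vax": float(rng.random() < p),
                    })
        df = pd.DataFrame(rows)
        full = fit_logistic_clustered(
            df, "verified_vax ~ health + low_cash + high_cash | village_id"
        )
        folds = district_sensitivity(df, outcome="verified_vax", covariates=False)
        drop_b = folds["dB"]
        j = full.model.exog_names.index("low_cash")
        jf = drop_b.model.exog_names.index("low_cash")
        assert drop_b.params[jf] > full.params[j]


class TestTrialModel:
    def test_fit_produces_summary(self, default_trial):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = TrialModel(default_trial.individuals).fit()
        text = res.summary()
        assert "intention" in text and "ICC" in text
        assert ("intention", "cash") in res.fits
        d = res.to_dict()
        assert "arm_rates" in d and "fits" in d

    def test_balance_table_mostly_within_tolerance(self, default_trial):
        table = TrialModel(default_trial.individuals).balance()
        # randomized covariates: the vast majority of |SMD| below 0.1
        assert (~table["flag"]).mean() > 0.8
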