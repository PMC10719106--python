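"""Rates, cluster-robust contrasts, ANOVA ICC, balance."""

import numpy as np
import pandas as pd
import pytest

from vaxtrial.estimators import (
    arm_rate,
    diff_from_cluster_means,
    diff_in_means_clustered,
    icc_anova,
    pooled_rate,
    smd_balance,
)


def make_counts_df(spec):
    """Individual table from {(arm): [(cluster_successes, cluster_size), ...]}."""
    rows = []
    for arm, clusters in spec.items():
        for c, (succ, size) in enumerate(clusters):
            for i in range(size):
                rows.append(
                    {"arm": arm, "village_id": f"{arm}-c{c}", "y": float(i < succ)}
                )
    return pd.DataFrame(rows)


class TestArmRate:
    def test_published_placebo_intention(self):
        df = make_counts_df({"placebo": [(1895, 2669)]})
        rate, num, den = arm_rate(df, "y", "placebo")
        assert round(rate, 1) == 71.0 and (num, den) == (1895, 2669)

    def test_published_placebo_reported(self):
        df = make_counts_df({"placebo": [(672, 1850)]})
        assert round(arm_rate(df, "y", "placebo")[0], 1) == 36.3

    def test_zero_successes(self):
        df = make_counts_df({"a": [(0, 50)]})
        assert arm_rate(df, "y", "a")[0] == 0.0

    def test_missing_excluded_from_denominator(self):
        df = make_counts_df({"a": [(3, 10)]})
        df.loc[0, "y"] = np.nan
        rate, num, den = arm_rate(df, "y", "a")
        assert den == 9

    def test_empty_arm_is_error(self):
        df = make_counts_df({"a": [(1, 2)]})
        with pytest.raises(ValueError):
            arm_rate(df, "y", "b")


class TestPooledRate:
    def test_cash_verified(self):
        assert round(pooled_rate([(40.7, 548), (25.9, 510)]), 1) == 33.6

    def test_all_arms_verified(self):
        rates = [(28.4, 1544), (21.6, 473), (40.7, 548), (25.9, 510)]
        assert round(pooled_rate(rates), 1) == 29.1

    def test_single_arm_identity(self):
        assert pooled_rate([(42.0, 100)]) == 42.0

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            pooled_rate([(10.0, 0)])


class TestDiffInMeans:
    def test_identical_outcomes_null(self):
        df = make_counts_df({"a": [(3, 10), (5, 10)], "b": [(3, 10), (5, 10)]})
        est = diff_in_means_clustered(df, "y", "a", "b")
        assert est.diff == 0.0 and est.p == pytest.approx(1.0)

    def test_published_verified_difference(self):
        # counts reproducing the printed 40.7% vs 28.4% arm rates
        low = [(45, 110)] * 4 + [(43, 108)]  # 223 of 548
        plc = [(44, 154)] * 9 + [(42, 158)]  # 438 of 1544
        df = make_counts_df({"low_cash": low, "placebo": plc})
        est = diff_in_means_clustered(df, "y", "low_cash", "placebo")
        assert round(est.diff, 1) == 12.3
        assert est.df == 5 + 10 - 2

    def test_six_cluster_closed_form_oracle(self, rng):
        # hand-computed ratio-estimator variance on a small fixture
        means_a, sizes_a = np.array([0.2, 0.5, 0.8]), np.array([10.0, 20.0, 30.0])
        means_b, sizes_b = np.array([0.1, 0.4, 0.3]), np.array([15.0, 15.0, 10.0])
        est = diff_from_cluster_means(means_a, sizes_a, means_b, sizes_b)

        def by_hand(m, s):
            w = s / s.sum()
            p = (w * m).sum()
            return p, len(m) / (len(m) - 1) * ((w**2) * (m - p) ** 2).sum()

        pa, va = by_hand(means_a, sizes_a)
        pb, vb = by_hand(means_b, sizes_b)
        assert est.diff == pytest.approx(100 * (pa - pb), abs=1e-12)
        assert est.se == pytest.approx(100 * np.sqrt(va + vb), abs=1e-12)

    def test_regression_on_cluster_means_agrees(self):
        # a size-weighted intercept+dummy regression on cluster means gives
        # the same point estimate as the ratio-estimator contrast
        rng = np.random.default_rng(3)
        means = rng.random(12)
        sizes = rng.integers(5, 40, 12).astype(float)
        arm = np.array([1] * 6 + [0] * 6)
        est = diff_from_cluster_means(means[:6], sizes[:6], means[6:], sizes[6:])
        X = np.column_stack([np.ones(12), arm])
        W = np.diag(sizes)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ means)
        assert est.diff == pytest.approx(100 * beta[1], abs=1e-10)

    def test_single_cluster_arm_is_error(self):
        df = make_counts_df({"a": [(3, 10)], "b": [(2, 10), (4, 10)]})
        with pytest.raises(ValueError, match="clusters"):
            diff_in_means_clustered(df, "y", "a", "b")

    def test_ci_brackets_estimate(self, default_trial):
        treated = default_trial.individuals.query("untreated_spillover == 0")
        est = diff_in_means_clustered(treated, "intention", "low_cash", "placebo",
                                      by="video")
        assert est.ci_low <= est.diff <= est.ci_high
        assert 0.0 <= est.p <= 1.0


class TestICC:
    def test_perfect_clustering_limit(self):
        df = pd.DataFrame(
            {"village_id": np.repeat(np.arange(20), 10),
             "y": np.repeat(np.arange(20) % 2, 10).astype(float)}
        )
        est = icc_anova(df, "y")
        assert est.icc == pytest.approx(1.0, abs=1e-9)

    def test_iid_null(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {"village_id": np.repeat(np.arange(310), 19),
             "y": (rng.random(310 * 19) < 0.4).astype(float)}
        )
        est = icc_anova(df, "y")
        assert abs(est.icc) < 0.02
        assert est.ci_low <= est.icc <= est.ci_high

    def test_constant_outcome_flagged(self):
        df = pd.DataFrame({"village_id": [1, 1, 2, 2], "y": [1.0] * 4})
        with pytest.raises(ValueError, match="constant"):
            icc_anova(df, "y")

    def test_bootstrap_ci_brackets(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {"village_id": np.repeat(np.arange(40), 15),
             "y": (rng.random(600) < 0.5).astype(float)}
        )
        est = icc_anova(df, "y", ci_method="bootstrap", n_boot=100, rng=rng)
        assert est.ci_low <= est.icc <= est.ci_high


class TestBalance:
    def _df(self, shift=0.0, n=400):
        rng = np.random.default_rng(4)

        def std(z):  # exact sample moments per arm
            return (z - z.mean()) / z.std(ddof=1)

        xa = std(rng.normal(0, 1, n // 2)) + shift
        xb = std(rng.normal(0, 1, n // 2))
        return pd.DataFrame(
            {"arm": ["a"] * (n // 2) + ["b"] * (n // 2),
             "x": np.concatenate([xa, xb])}
        )

    def test_identical_distributions_zero(self):
        df = self._df()
        df["x"] = 1.5  # identical constant -> raw diff 0 for binaries
        df["b"] = 0
        table = smd_balance(df, ["b"], [("a", "b")])
        assert (table["smd"] == 0).all()

    def test_published_age_row_arithmetic(self):
        # means 37.3 vs 38.4 with SDs 16.1 / 16.8: SMD ~ 0.067, within tolerance
        rng = np.random.default_rng(5)
        za = rng.normal(size=500)
        za = (za - za.mean()) / za.std(ddof=1)
        zb = rng.normal(size=500)
        zb = (zb - zb.mean()) / zb.std(ddof=1)
        df = pd.DataFrame(
            {"arm": ["a"] * 500 + ["b"] * 500,
             "age": np.concatenate([37.3 + 16.1 * za, 38.4 + 16.8 * zb])}
        )
        table = smd_balance(df, ["age"], [("a", "b")])
        pooled = np.sqrt((16.1**2 + 16.8**2) / 2)
        assert table.loc[0, "smd"] == pytest.approx((37.3 - 38.4) / pooled, abs=1e-9)
        assert abs(table.loc[0, "smd"]) == pytest.approx(0.067, abs=0.002)
        assert not table.loc[0, "flag"]

    def test_boundary_shift_flagged(self):
        df = self._df(shift=0.1)  # exactly 0.1 pooled SDs
        table = smd_balance(df, ["x"], [("a", "b")])
        assert table.loc[0, "smd"] == pytest.approx(0.1, abs=1e-9)
        assert bool(table.loc[0, "flag"])

    def test_antisymmetric_under_swap(self):
        df = self._df(shift=0.3)
        t1 = smd_balance(df, ["x"], [("a", "b")])
        t2 = smd_balance(df, ["x"], [("b", "a")])
        assert t1.loc[0, "smd"] == pytest.approx(-t2.loc[0, "smd"])

    def test_zero_pooled_sd_warns(self):
        df = pd.DataFrame({"arm": ["a", "a", "b", "b"], "x": [2.0, 2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="pooled SD"):
            table = smd_balance(df, ["x"], [("a", "b")])
        assert table.loc[0, "flag"]


def test_count_identity_across_video_groups(default_trial):
    """Arm numerators/denominators partition the observed sample."""
    treated = default_trial.individuals.query("untreated_spillover == 0")
    total_num = total_den = 0
    for arm in ("placebo", "health", "low_cash", "high_cash"):
        _, num, den = arm_rate(treated, "intention", arm, by="video")
        total_num += num
        total_den += den
    assert total_den == treated["intention"].notna().sum()
    assert total_num == treated["intention"].sum()
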