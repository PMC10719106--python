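"""Cluster-robust logistic regression (statsmodels-style model/results pair).

:class:`ClusterLogit` fits a binary logit by iteratively reweighted least
squares and reports the CR1 cluster-robust sandwich covariance

    V = A^{-1} B A^{-1},   A = X' W X,   B = G/(G-1) * sum_g s_g s_g',

where s_g is the summed score x_i (y_i - p_i) over cluster g and W the IRLS
weight matrix at the MLE.  Odds-ratio confidence intervals use normal
quantiles on the log-odds scale; coefficient p-values use a t reference with
G - 1 degrees of freedom (both conventional for village-clustered trials, and
switchable via ``use_t`` / ``small_sample``).

Supports frequency-style case weights (used by the inverse-probability
reweighting of the attrition analysis).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats, special

__all__ = ["ClusterLogit", "ClusterLogitResults", "SeparationWarning"]


class SeparationWarning(UserWarning):
    """Quasi-complete separation: some fitted probabilities are 0/1."""


class ClusterLogit:
    """Binary logistic regression with village-clustered sandwich errors.

    Parameters
    ----------
    endog : array-like of 0/1
    exog : 2-D array or DataFrame (design matrix including the intercept)
    clusters : array-like of cluster labels, one per row
    weights : optional positive case weights
    exog_names : column names when ``exog`` is a bare array
    """

    def __init__(self, endog, exog, clusters, weights=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            self.exog = exog.to_numpy(dtype=float)
        else:
            self.exog = np.asarray(exog, dtype=float)
            self.exog_names = list(
                exog_names or [f"x{j}" for j in range(self.exog.shape[1])]
            )
        self.clusters = np.asarray(clusters)
        self.weights = (
            np.ones(len(self.endog)) if weights is None else np.asarray(weights, float)
        )
        if np.any(self.weights <= 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be positive and finite")
        if not set(np.unique(self.endog)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if len({len(self.endog), len(self.exog), len(self.clusters)}) != 1:
            raise ValueError("endog, exog and clusters must have equal length")
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            # name the offending columns for the user
            _, r = np.linalg.qr(self.exog)
            dep = [
                self.exog_names[j]
                for j in range(self.exog.shape[1])
                if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))
            ]
            raise ValueError(f"design matrix is rank deficient; check columns {dep}")

    @classmethod
    def from_formula(cls, formula, data, cluster, weights=None):
        """Build from a patsy formula; ``cluster`` is a column name in data."""
        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        idx = X.index
        w = data.loc[idx, weights] if isinstance(weights, str) else weights
        return cls(
            y.to_numpy().ravel(),
            X,
            data.loc[idx, cluster].to_numpy(),
            weights=w,
        )

    def loglike(self, params: np.ndarray) -> float:
        eta = self.exog @ params
        # log(1+e^eta) computed stably
        return float(
            np.sum(self.weights * (self.endog * eta - np.logaddexp(0.0, eta)))
        )

    def fit(self, maxiter: int = 100, tol: float = 1e-12) -> "ClusterLogitResults":
        X, y, w = self.exog, self.endog, self.weights
        beta = np.zeros(X.shape[1])
        ll_old = -np.inf
        for _ in range(maxiter):
            eta = X @ beta
            p = special.expit(eta)
            wls = w * np.clip(p * (1.0 - p), 1e-10, None)
            z = eta + (y - p) / np.clip(p * (1.0 - p), 1e-10, None)
            sw = np.sqrt(wls)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
            ll = self.loglike(beta)
            if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
                break
            ll_old = ll
        eta = X @ beta
        p = special.expit(eta)
        if np.any(p < 1e-8) or np.any(p > 1 - 1e-8) or np.max(np.abs(eta)) > 25:
            warnings.warn(
                "fitted probabilities numerically 0 or 1: possible separation; "
                "coefficients and sandwich SEs may be unreliable",
                SeparationWarning,
            )
        return ClusterLogitResults(model=self, params=beta, fittedvalues=p)


@dataclass
class ClusterLogitResults:
    """Fitted coefficients with CR1 cluster-robust covariance."""

    model: ClusterLogit
    params: np.ndarray
    fittedvalues: np.ndarray
    small_sample: bool = True
    use_t: bool = True
    _vcov: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._vcov = self._sandwich()

    # -- covariance ---------------------------------------------------------

    def _sandwich(self) -> np.ndarray:
        X = self.model.exog
        y = self.model.endog
        w = self.model.weights
        p = self.fittedvalues
        A = X.T @ (X * (w * p * (1.0 - p))[:, None])
        scores = X * (w * (y - p))[:, None]
        labels = self.model.clusters
        order = np.argsort(labels, kind="stable")
        sorted_scores = scores[order]
        _, starts = np.unique(labels[order], return_index=True)
        s_g = np.add.reduceat(sorted_scores, starts, axis=0)
        B = s_g.T @ s_g
        G = len(starts)
        if self.small_sample:
            if G < 2:
                raise ValueError("need >= 2 clusters for the CR1 correction")
            B = B * (G / (G - 1.0))
        Ainv = np.linalg.inv(A)
        V = Ainv @ B @ Ainv
        return (V + V.T) / 2.0

    # -- accessors ----------------------------------------------------------

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.model.clusters))

    @property
    def df_resid(self) -> int:
        return self.n_clusters - 1

    @property
    def vcov(self) -> np.ndarray:
        return self._vcov

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self._vcov))

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        if self.use_t:
            return 2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid)
        return 2.0 * stats.norm.sf(np.abs(self.tvalues))

    @property
    def llf(self) -> float:
        return self.model.loglike(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * len(self.params) - 2.0 * self.llf

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Normal-quantile CI on the log-odds scale (odds-ratio convention)."""
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = np.exp(self.conf_int(alpha))
        return pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.pvalues,
            },
            index=self.model.exog_names,
        )

    def params_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            },
            index=self.model.exog_names,
        )

    def summary(self) -> str:
        head = (
            f"Cluster-robust logit  n={self.nobs}  clusters={self.n_clusters}  "
            f"llf={self.llf:.1f}  AIC={self.aic:.1f}\n"
        )
        table = self.params_table()
        table["OR"] = np.exp(self.params)
        return head + table.to_string(float_format=lambda v: f"{v: .4f}")

    def to_dict(self) -> dict:
        return {
            "terms": self.model.exog_names,
            "coefficients": self.params.tolist(),
            "robust_se": self.bse.tolist(),
            "odds_ratios": np.exp(self.params).tolist(),
            "p_values": self.pvalues.tolist(),
            "log_likelihood": self.llf,
            "n": self.nobs,
            "n_clusters": self.n_clusters,
        }
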