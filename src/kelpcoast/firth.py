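"""Firth-penalized logistic regression.

Small binary datasets with (near-)complete separation — e.g. a handful of
adjacent locality pairs where every long-beach pair is genetically disjunct —
give infinite maximum-likelihood estimates.  Firth's penalty adds half the
log determinant of the Fisher information (a Jeffreys prior) to the
log-likelihood:

    l*(beta) = l(beta) + 1/2 * log det I(beta),    I = X' W X,
    W = diag(p_i (1 - p_i)),

which keeps every estimate finite.  The score of l* has the closed form

    U*_r = sum_i (y_i - p_i + h_i (1/2 - p_i)) x_ir,

with h_i the hat-matrix diagonals of the weighted design.  Estimation is by
modified-score Newton iteration with step-halving whenever the penalized
log-likelihood would decrease.

P-values are penalized likelihood-ratio (profile) tests: each coefficient in
turn is fixed at zero and the remaining coefficients re-estimated under the
same full-design penalty; 2 * (l*_full - l*_profile) is referred to
chi-square with 1 df.  Wald standard errors from the inverse information are
reported alongside.

The interface follows the statsmodels convention: a model object holds the
data, ``fit()`` returns a results object with ``params``, ``bse``,
``pvalues`` and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError, RankError


def _penalized_loglik(y, X, beta):
    eta = X @ beta
    # log-likelihood via logaddexp for stability
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


class FirthLogit:
    """Logistic regression model with Firth's penalty.

    Parameters
    ----------
    endog : array-like of 0/1
        Binary response.
    exog : array-like, n x k
        Design matrix; include the intercept column explicitly (or use
        :meth:`from_dataframe`, which prepends one).
    exog_names : optional list of column names.
    """

    def __init__(self, endog, exog, exog_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ParameterError("endog and exog have different lengths")
        if not set(np.unique(self.endog)).issubset({0.0, 1.0}):
            raise ParameterError("endog must be binary 0/1")
        n, k = self.exog.shape
        if n < k:
            raise ParameterError("need at least as many observations as columns")
        if np.linalg.matrix_rank(self.exog) < k:
            raise RankError("design matrix is rank deficient (collinear columns)")
        if exog_names is None:
            exog_names = [f"x{i}" for i in range(k)]
        if len(exog_names) != k:
            raise ParameterError("exog_names length mismatch")
        self.exog_names = list(exog_names)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        predictors: list[str],
        add_intercept: bool = True,
    ) -> "FirthLogit":
        y = data[response].astype(float).to_numpy()
        X = data[list(predictors)].astype(float).to_numpy()
        names = list(predictors)
        if add_intercept:
            X = np.column_stack([np.ones(len(y)), X])
            names = ["intercept"] + names
        return cls(y, X, names)

    # -- core fitting ------------------------------------------------------

    def _newton(self, fixed_at_zero=(), tol=1e-8, max_iter=50):
        """Modified-score Newton iterations; ``fixed_at_zero`` columns are
        profiled out (held at 0 while the penalty uses the full design)."""
        y, X = self.endog, self.exog
        n, k = X.shape
        free = np.array([i not in fixed_at_zero for i in range(k)])
        beta = np.zeros(k)
        ll = _penalized_loglik(y, X, beta)
        if not free.any():  # everything constrained: nothing to estimate
            return beta, ll, True, 0
        converged = False
        iterations = 0
        for iterations in range(1, max_iter + 1):
            eta = X @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            Xw = X * w[:, None]
            info = X.T @ Xw
            try:
                info_inv = np.linalg.inv(info)
            except np.linalg.LinAlgError as exc:
                raise RankError(f"singular information matrix: {exc}") from exc
            h = np.einsum("ij,jk,ik->i", X, info_inv, Xw)
            score = X.T @ (y - p + h * (0.5 - p))
            if np.max(np.abs(score[free])) < tol:
                converged = True
                break
            sub_info = info[np.ix_(free, free)]
            step = np.zeros(k)
            step[free] = np.linalg.solve(sub_info, score[free])
            # step-halving on penalized-likelihood decrease
            factor = 1.0
            for _ in range(25):
                candidate = beta + factor * step
                ll_new = _penalized_loglik(y, X, candidate)
                if ll_new >= ll - 1e-12:
                    break
                factor /= 2.0
            beta = beta + factor * step
            ll = _penalized_loglik(y, X, beta)
        return beta, ll, converged, iterations

    def fit(
        self, tol: float = 1e-8, max_iter: int = 50, pl_pvalues: bool = True
    ) -> "FirthLogitResults":
        beta, ll, converged, iterations = self._newton(tol=tol, max_iter=max_iter)
        y, X = self.endog, self.exog
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.diag(cov))

        pvalues = np.full(len(beta), np.nan)
        lr_stats = np.full(len(beta), np.nan)
        if pl_pvalues:
            for r in range(len(beta)):
                _, ll0, conv0, _ = self._newton(
                    fixed_at_zero=(r,), tol=tol, max_iter=max_iter
                )
                stat = max(0.0, 2.0 * (ll - ll0))
                lr_stats[r] = stat
                pvalues[r] = float(stats.chi2.sf(stat, df=1))
                converged = converged and conv0
        return FirthLogitResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            pvalues=pd.Series(pvalues, index=self.exog_names),
            lr_stats=pd.Series(lr_stats, index=self.exog_names),
            loglik=ll,
            converged=converged,
            iterations=iterations,
            nobs=len(y),
        )


@dataclass
class FirthLogitResults:
    """Estimates, uncertainties and penalized-LR p-values for a FirthLogit fit."""

    model: FirthLogit
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    lr_stats: pd.Series
    loglik: float
    converged: bool
    iterations: int
    nobs: int

    def to_dict(self) -> dict:
        return {
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "standard_errors": {k: float(v) for k, v in self.bse.items()},
            "p_values": {k: float(v) for k, v in self.pvalues.items()},
            "penalized_loglik": float(self.loglik),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "n": int(self.nobs),
        }

    def summary(self) -> str:
        lines = [
            "Firth-penalized logistic regression",
            f"  n = {self.nobs}   penalized log-likelihood = {self.loglik:.4f}",
            f"  converged = {self.converged} (iterations: {self.iterations})",
            "",
            f"  {'term':<14}{'coef':>10}{'std err':>10}{'PLR p':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<14}{self.params[name]:>10.4f}"
                f"{self.bse[name]:>10.4f}{self.pvalues[name]:>10.4f}"
            )
        return "\n".join(lines)
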