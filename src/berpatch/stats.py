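"""Compositional statistics for repair-product proportions.

Replicate compositions live on the probability simplex, so group
comparisons use Dirichlet regression: the concentration parameters of
a Dirichlet response are log-linked to the covariates (the "common"
parametrization), alpha_id = exp(x_i . beta_d).  Global group effects
are tested by likelihood ratio against the intercept-only model, with
chi-square reference on D*(G-1) degrees of freedom.  Component-wise
follow-up uses beta regression (logit mean link, constant precision)
per class, with Benjamini-Hochberg control across classes.

The Dirichlet model is fit here by quasi-Newton (L-BFGS) with the
analytic digamma gradient from a moment-matching start; beta
regression and the BH step-up are delegated to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from statsmodels.othermod.betareg import BetaModel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "close",
    "DirichletRegression",
    "DirichletRegressionResults",
    "lrt_global",
    "beta_component_tests",
    "bh_adjust",
    "TestResult",
]


def close(table: pd.DataFrame, classes, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Closure with pseudocount: replace zeros, renormalize rows to 1.

    Only the ``classes`` columns are touched; other columns (group,
    replicate id) pass through.  A row whose class entries are all zero
    is an error.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out = table.copy()
    y = out[list(classes)].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("proportions must be nonnegative")
    if np.any(y.sum(axis=1) <= 0):
        raise ValueError("row with all-zero composition")
    y = np.where(y == 0, pseudocount, y)
    y = y / y.sum(axis=1, keepdims=True)
    out[list(classes)] = y
    return out


@dataclass
class TestResult:
    statistic: float
    df: int
    pvalue: float
    qvalue: float | None = None
    label: str | None = None
    status: str = "ok"


# ---------------------------------------------------------------------
# Dirichlet regression


class DirichletRegression:
    """Dirichlet regression with log-linked concentrations.

    Parameters
    ----------
    endog : (n, D) array of strictly interior compositions (rows sum to 1).
    exog : (n, p) design matrix (include the intercept column).
    class_names, exog_names : optional labels for reporting.

    The log-likelihood of one observation y with concentrations
    alpha = exp(X beta) is
    ``lnGamma(sum a) - sum lnGamma(a_d) + sum (a_d - 1) ln y_d``.
    """

    def __init__(self, endog, exog, class_names=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.endog.ndim != 2 or self.exog.ndim != 2:
            raise ValueError("endog and exog must be 2-D")
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("endog and exog row counts differ")
        if np.any(self.endog <= 0) or np.any(self.endog >= 1):
            raise ValueError("compositions must be strictly inside the simplex; close() first")
        if not np.allclose(self.endog.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("composition rows must sum to 1")
        self.n, self.D = self.endog.shape
        self.p = self.exog.shape[1]
        self.class_names = list(class_names) if class_names is not None else [
            f"y{d}" for d in range(self.D)
        ]
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(self.p)
        ]
        self._logy = np.log(self.endog)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, classes, group: str | None = None):
        """Build from a replicate table; ``group`` (a column name) adds
        treatment-coded indicator columns, else the model is
        intercept-only."""
        y = table[list(classes)].to_numpy(dtype=float)
        n = y.shape[0]
        cols = [np.ones(n)]
        names = ["intercept"]
        if group is not None:
            levels = sorted(pd.unique(table[group]).tolist(), key=str)
            if len(levels) < 2:
                raise ValueError("group factor needs >= 2 levels")
            counts = table[group].value_counts()
            if counts.min() < 2:
                raise ValueError("each group needs >= 2 samples")
            for lev in levels[1:]:
                cols.append((table[group] == lev).to_numpy(dtype=float))
                names.append(f"{group}[{lev}]")
        X = np.column_stack(cols)
        return cls(y, X, class_names=list(classes), exog_names=names)

    # -- likelihood ----------------------------------------------------
    def _alpha(self, beta: np.ndarray) -> np.ndarray:
        eta = self.exog @ beta.reshape(self.p, self.D)
        return np.exp(np.clip(eta, -30, 30))

    def loglike(self, beta: np.ndarray) -> float:
        a = self._alpha(beta)
        return float(
            np.sum(special.gammaln(a.sum(axis=1)))
            - np.sum(special.gammaln(a))
            + np.sum((a - 1) * self._logy)
        )

    def score(self, beta: np.ndarray) -> np.ndarray:
        a = self._alpha(beta)
        a0 = a.sum(axis=1, keepdims=True)
        # d ll / d eta_id = a_id * (psi(a0_i) - psi(a_id) + ln y_id)
        g_eta = a * (special.digamma(a0) - special.digamma(a) + self._logy)
        return (self.exog.T @ g_eta).ravel()

    def _start_params(self) -> np.ndarray:
        m = self.endog.mean(axis=0)
        v = self.endog.var(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = m * (1 - m) / v - 1
        s = s[np.isfinite(s) & (s > 0)]
        prec = float(np.median(s)) if s.size else float(self.D)
        prec = min(max(prec, 1.0), 1e4)
        beta = np.zeros((self.p, self.D))
        beta[0] = np.log(prec * m)
        return beta.ravel()

    def fit(self, maxiter: int = 500, gtol: float = 1e-8) -> "DirichletRegressionResults":
        x0 = self._start_params()
        ll0 = self.loglike(x0)
        res = optimize.minimize(
            lambda b: -self.loglike(b),
            x0,
            jac=lambda b: -self.score(b),
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol},
        )
        llf = -float(res.fun)
        converged = bool(res.success) and llf >= ll0 - 1e-8
        return DirichletRegressionResults(self, res.x.reshape(self.p, self.D),
                                          llf, converged, start_llf=ll0)


class DirichletRegressionResults:
    """Fit results: coefficient matrix, log-likelihood, fitted
    group-wise expected compositions, and a text summary."""

    def __init__(self, model: DirichletRegression, params, llf, converged, start_llf=None):
        self.model = model
        self.params = np.asarray(params)  # (p, D)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.start_llf = start_llf
        self.df_model = self.params.size

    def alpha(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else np.atleast_2d(np.asarray(exog, dtype=float))
        return np.exp(np.clip(X @ self.params, -30, 30))

    def expected_composition(self, exog=None) -> np.ndarray:
        a = self.alpha(exog)
        return a / a.sum(axis=1, keepdims=True)

    def group_compositions(self) -> pd.DataFrame:
        """Expected composition for each distinct design-matrix row."""
        X = np.unique(self.model.exog, axis=0)
        comp = self.expected_composition(X)
        idx = [" ".join(f"{v:g}" for v in row) for row in X]
        return pd.DataFrame(comp, columns=self.model.class_names, index=idx)

    def summary(self) -> str:
        lines = [
            "Dirichlet regression (common parametrization, log link)",
            f"n obs: {self.model.n}   classes: {self.model.D}   "
            f"params: {self.df_model}   logLik: {self.llf:.3f}   "
            f"converged: {self.converged}",
            "",
            "coefficients (rows: covariates, cols: classes):",
        ]
        header = "              " + "  ".join(f"{c:>10}" for c in self.model.class_names)
        lines.append(header)
        for j, name in enumerate(self.model.exog_names):
            row = "  ".join(f"{self.params[j, d]:10.4f}" for d in range(self.model.D))
            lines.append(f"{name:>13} {row}")
        lines.append("")
        lines.append("expected compositions by design row:")
        lines.append(self.group_compositions().to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


def lrt_global(fit_full: DirichletRegressionResults,
               fit_null: DirichletRegressionResults,
               tol: float = 1e-6) -> TestResult:
    """Likelihood-ratio test of the full (group) model against the
    nested intercept-only model; chi-square with D*(G-1) df."""
    df = fit_full.df_model - fit_null.df_model
    if df <= 0:
        raise ValueError("null model is not nested in the full model")
    stat = 2.0 * (fit_full.llf - fit_null.llf)
    if stat < -tol:
        raise RuntimeError(
            f"full-model log-likelihood below null ({stat/2:.3g}); optimization failure"
        )
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, df))
    return TestResult(statistic=float(stat), df=df, pvalue=p, label="global LRT")


# ---------------------------------------------------------------------
# component-wise beta regression


def beta_component_tests(table: pd.DataFrame, classes, group: str,
                         method: str = "lrt") -> list:
    """Per-class beta regression of each proportion on the group factor.

    Each class is fit by maximum likelihood with a logit mean link and
    constant precision; the group effect is tested by likelihood ratio
    (``method="lrt"``) or Wald (``method="wald"``).  A class whose
    values are numerically constant is reported with status
    ``"degenerate"`` and excluded from the BH family.
    """
    if method not in ("lrt", "wald"):
        raise ValueError("method must be 'lrt' or 'wald'")
    levels = sorted(pd.unique(table[group]).tolist(), key=str)
    if len(levels) < 2:
        raise ValueError("group factor needs >= 2 levels")
    n = len(table)
    X_full = np.column_stack(
        [np.ones(n)] + [(table[group] == lev).to_numpy(dtype=float) for lev in levels[1:]]
    )
    X_null = np.ones((n, 1))
    df_eff = len(levels) - 1
    results = []
    for lab in classes:
        y = table[lab].to_numpy(dtype=float)
        # classes that are constant to numerical precision (including
        # all-zero classes after pseudocount closure) cannot be fit
        if np.ptp(y) < max(1e-8, 1e-3 * float(np.mean(y))):
            results.append(TestResult(np.nan, df_eff, np.nan, label=lab, status="degenerate"))
            continue
        # lbfgs copes better than bfgs with the near-flat precision
        # direction of tight small-n proportion data
        full = BetaModel(y, X_full).fit(method="lbfgs", maxiter=2000, disp=False)
        if method == "lrt":
            null = BetaModel(y, X_null).fit(method="lbfgs", maxiter=2000, disp=False)
            stat = max(2.0 * (full.llf - null.llf), 0.0)
            p = float(sps.chi2.sf(stat, df_eff))
        else:
            contrast = np.zeros((df_eff, full.params.size))
            for i in range(df_eff):
                contrast[i, 1 + i] = 1.0
            w = full.wald_test(contrast, scalar=True)
            stat = float(w.statistic)
            p = float(w.pvalue)
        results.append(TestResult(float(stat), df_eff, p, label=lab))
    ok = [r for r in results if r.status == "ok"]
    if ok:
        qs = bh_adjust(np.array([r.pvalue for r in ok]))
        for r, q in zip(ok, qs):
            r.qvalue = float(q)
    return results


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
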