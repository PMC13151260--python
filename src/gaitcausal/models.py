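"""Confirmatory outcome models on the graph-selected variables.

Maximum-likelihood logistic regression quantifies each selected factor's
association with the binary outcome as an odds ratio with a 95% Wald
confidence interval.  L1-penalized (LASSO) logistic regression with a
cross-validated penalty re-checks the robustness of the variable
selection: standardized columns, a 100-point log-spaced lambda grid from
the full-shrinkage point down four decades, five-fold stratified CV on
binomial deviance, and bootstrap-percentile intervals for the
exponentiated coefficients at the selected penalty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import BinaryDesign

__all__ = [
    "ModelFit",
    "LassoFit",
    "LassoConfig",
    "fit_logistic",
    "fit_lasso_logistic",
    "forest_table",
]

SEPARATION_COEF_BOUND = 15.0


@dataclass
class ModelFit:
    """Unpenalized logistic fit: one entry per term (intercept excluded
    from the odds-ratio table but kept on the object)."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    or_: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    intercept: float
    converged: bool
    separation_flag: bool
    n_used: int


@dataclass
class LassoConfig:
    folds: int = 5
    n_lambda: int = 100
    lambda_decades: float = 4.0
    n_bootstrap_ci: int = 500
    seed: int = 0
    #: "min" picks the deviance-minimizing lambda; "1se" the largest lambda
    #: within one standard error of that minimum.
    rule: str = "min"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.rule not in ("min", "1se"):
            raise ValueError("rule must be 'min' or '1se'")


@dataclass
class LassoFit:
    terms: list[str]
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray
    cv_deviance_se: np.ndarray
    lambda_star: float
    coef: np.ndarray                    # standardized scale, at lambda_star
    or_: np.ndarray                     # exp(coef); exactly 1 for zeroed terms
    ci_low: np.ndarray                  # bootstrap percentile; NaN for zeroed terms
    ci_high: np.ndarray
    intercept: float
    fold_seed: int
    n_used: int

    @property
    def selected(self) -> list[str]:
        return [t for t, c in zip(self.terms, self.coef) if c != 0.0]


# ---------------------------------------------------------------------------
# maximum-likelihood logistic regression
# ---------------------------------------------------------------------------

def fit_logistic(design: BinaryDesign, terms: list[str] | None = None) -> ModelFit:
    """MLE logistic regression of the outcome on the given design columns.

    Wald standard errors come from the observed information matrix;
    95% CI = exp(coef +/- 1.96 * SE); two-sided Wald p-values.  A diverging
    coefficient (|coef| > 15 on the logit scale) flags quasi-separation:
    the fit is still returned, with a warning.
    """
    if terms is None:
        terms = design.columns
    missing = set(terms) - set(design.columns)
    if missing:
        raise KeyError(f"terms not in design: {sorted(missing)}")
    y = np.asarray(design.outcome)
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    X = sm.add_constant(design.matrix[terms].to_numpy(dtype=float),
                        has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8,
                                     method="newton")
        except np.linalg.LinAlgError:
            # singular Hessian (perfect separation): quasi-Newton still
            # returns a usable, flaggable fit
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="lbfgs")
    coef = res.params[1:]
    se = res.bse[1:]
    separation = bool(np.any(np.abs(res.params) > SEPARATION_COEF_BOUND))
    if separation:
        warnings.warn("possible separation: a coefficient exceeds 15 in "
                      "absolute value; estimates are unreliable")
    z = stats.norm.ppf(0.975)
    return ModelFit(
        terms=list(terms),
        coef=coef,
        se=se,
        or_=np.exp(coef),
        ci_low=np.exp(coef - z * se),
        ci_high=np.exp(coef + z * se),
        p_values=res.pvalues[1:],
        intercept=float(res.params[0]),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_flag=separation,
        n_used=len(y),
    )


# ---------------------------------------------------------------------------
# L1-penalized logistic regression
# ---------------------------------------------------------------------------

def _lasso_solve(Xs: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Minimize mean binomial deviance + lam * ||w||_1 (intercept
    unpenalized) via liblinear; lam on the mean-loss scale maps to
    C = 1 / (n * lam)."""
    n = len(y)
    if not np.isfinite(lam) or lam < 0:
        raise ValueError("lambda must be nonnegative and finite")
    # lam == 0 degenerates to the unpenalized fit (numerically: huge C)
    C = 1e12 if lam == 0 else 1.0 / (n * lam)
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=5000,
        tol=1e-8, fit_intercept=True, intercept_scaling=100.0,
        random_state=0)
    clf.fit(Xs, y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def _mean_deviance(Xs, y, coef, intercept) -> float:
    eta = Xs @ coef + intercept
    # mean binomial deviance = 2 * mean negative log-likelihood
    return float(2.0 * np.mean(np.logaddexp(0.0, eta) - y * eta))


def lambda_max(Xs: np.ndarray, y: np.ndarray) -> float:
    """Smallest mean-loss-scale penalty that zeroes every coefficient of
    the standardized design (KKT bound at the intercept-only fit)."""
    n = len(y)
    p0 = y.mean()
    return float(np.max(np.abs(Xs.T @ (y - p0))) / n)


def fit_lasso_logistic(
    design: BinaryDesign,
    terms: list[str] | None = None,
    config: LassoConfig | None = None,
) -> LassoFit:
    """LASSO logistic path with cross-validated penalty.

    Columns are standardized to mean 0, SD 1; coefficients are reported on
    that scale and exponentiated (a zero coefficient reports OR = 1).  The
    CIs are 95% bootstrap percentile intervals of the exponentiated
    coefficients refit at the fixed selected penalty — a pragmatic,
    clearly-labelled choice, since no standard closed-form interval exists
    for LASSO estimates.
    """
    if config is None:
        config = LassoConfig()
    if terms is None:
        terms = design.columns
    missing = set(terms) - set(design.columns)
    if missing:
        raise KeyError(f"terms not in design: {sorted(missing)}")
    y = np.asarray(design.outcome, dtype=float)
    X = design.matrix[terms].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if np.any(sd == 0):
        bad = [t for t, s in zip(terms, sd) if s == 0]
        raise ValueError(f"constant design columns: {bad}")
    Xs = (X - mu) / sd

    lam_hi = lambda_max(Xs, y)
    grid = np.geomspace(lam_hi, lam_hi * 10.0 ** (-config.lambda_decades),
                        config.n_lambda)

    n_class = min(int(y.sum()), int((1 - y).sum()))
    folds = min(config.folds, n_class)
    if folds < 2:
        raise ValueError("cannot form >= 2 folds with both classes present")
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(config.seed) % (2**31))
    dev = np.zeros((folds, len(grid)))
    for f, (tr, te) in enumerate(skf.split(Xs, y)):
        for g, lam in enumerate(grid):
            coef, b0 = _lasso_solve(Xs[tr], y[tr], lam)
            dev[f, g] = _mean_deviance(Xs[te], y[te], coef, b0)
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    g_min = int(np.argmin(cv_mean))
    if config.rule == "min":
        g_star = g_min
    else:
        within = np.nonzero(cv_mean <= cv_mean[g_min] + cv_se[g_min])[0]
        g_star = int(within[0])        # grid is decreasing: first = largest lambda
    lam_star = float(grid[g_star])

    coef, b0 = _lasso_solve(Xs, y, lam_star)

    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2**31), 2**20]))
    n = len(y)
    boot = np.full((max(config.n_bootstrap_ci, 1), len(terms)), np.nan)
    for b in range(config.n_bootstrap_ci):
        while True:
            idx = rng.integers(0, n, n)
            if 0 < y[idx].sum() < n:
                break
        Xb = X[idx]
        sdb = Xb.std(axis=0)
        keep = sdb > 0
        Xbs = np.zeros_like(Xb)
        Xbs[:, keep] = (Xb[:, keep] - Xb[:, keep].mean(axis=0)) / sdb[keep]
        cb, _ = _lasso_solve(Xbs, y[idx], lam_star)
        boot[b] = cb
    if config.n_bootstrap_ci > 0:
        ci_lo = np.exp(np.percentile(boot, 2.5, axis=0))
        ci_hi = np.exp(np.percentile(boot, 97.5, axis=0))
    else:  # CIs skipped (e.g. pure selection runs)
        ci_lo = np.full(len(terms), np.nan)
        ci_hi = np.full(len(terms), np.nan)
    zero = coef == 0.0
    ci_lo[zero] = np.nan
    ci_hi[zero] = np.nan

    return LassoFit(
        terms=list(terms),
        lambda_grid=grid,
        cv_deviance=cv_mean,
        cv_deviance_se=cv_se,
        lambda_star=lam_star,
        coef=coef,
        or_=np.exp(coef),
        ci_low=ci_lo,
        ci_high=ci_hi,
        intercept=b0,
        fold_seed=int(config.seed),
        n_used=n,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def forest_table(fit: ModelFit | LassoFit,
                 order: list[str] | None = None) -> pd.DataFrame:
    """One row per term: OR, CI bounds and (for the MLE fit) the Wald
    p-value, in the given selection order.  Zeroed LASSO terms report
    OR = 1.00 with no CI."""
    if order is None:
        order = fit.terms
    pos = {t: i for i, t in enumerate(fit.terms)}
    rows = []
    for t in order:
        i = pos[t]
        row = {
            "term": t,
            "or": float(fit.or_[i]),
            "ci_low": float(fit.ci_low[i]),
            "ci_high": float(fit.ci_high[i]),
        }
        if isinstance(fit, ModelFit):
            row["p"] = float(fit.p_values[i])
            row["significant"] = bool(fit.p_values[i] < 0.05)
        rows.append(row)
    cols = ["term", "or", "ci_low", "ci_high"]
    if rows and "p" in rows[0]:
        cols += ["p", "significant"]
    return pd.DataFrame(rows, columns=cols)


def forest_table_to_json(table: pd.DataFrame, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(table.to_dict(orient="records"), fh, indent=2,
                  default=lambda x: None if pd.isna(x) else float(x))
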