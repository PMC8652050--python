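"""Small linear models of irAE ROR with leave-one-out cross-validation.

With ~19 cancer types as observations, only bivariate and trivariate OLS
models (optionally augmented by one covariate at a time) are defensible;
designs with five or more predictors are refused by default.  Predictive
performance is the tie-aware Spearman correlation Rs between the pooled
held-out LOOCV predictions and the observed RORs, summarized as the
unexplained variance 1 - Rs^2.  Nested models are compared by the Gaussian
likelihood-ratio test at the maximum-likelihood variance (sigma^2 = RSS/n),
and multicollinearity is diagnosed by variance inflation factors with the
conventional VIF > 4 flag.

All model fitting goes through :mod:`statsmodels` OLS.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from irsplice.descriptors import DescriptorTable
from irsplice.errors import CollinearityError, InsufficientDataError, NestingError
from irsplice.screen import bh_adjust, spearman

__all__ = [
    "ModelFit",
    "ModelComparison",
    "unexplained_variance",
    "fit_ols",
    "loocv_evaluate",
    "lrt",
    "vif",
    "combination_search",
    "augment_model",
]

MAX_PREDICTORS = 4  # tiny-n guard: refuse >= 5 predictors unless overridden
VIF_CRITICAL = 4.0


@dataclass
class ModelFit:
    """A fitted linear model of ROR with its cross-validated diagnostics."""

    variables: tuple[str, ...]
    coefficients: pd.Series  # index: ["intercept", *variables]
    loocv_rs: float
    loocv_p: float
    unexplained_variance: float
    loglik: float
    n: int
    vif: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    predictions: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        assert abs(self.unexplained_variance - (1 - self.loocv_rs**2)) < 1e-12

    @property
    def max_vif(self) -> float:
        return float(self.vif.max()) if len(self.vif) else float("nan")


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of a reduced model against a nested full one."""

    reduced: "OlsFit | ModelFit"
    full: "OlsFit | ModelFit"
    lrt_stat: float
    df: int
    p_value: float


@dataclass
class OlsFit:
    """Raw OLS fit: coefficients and Gaussian log-likelihood at sigma^2 = RSS/n."""

    variables: tuple[str, ...]
    coefficients: pd.Series
    rss: float
    loglik: float
    n: int


def unexplained_variance(rs: float) -> float:
    """Fraction of rank-correlation variance left unexplained: 1 - Rs^2."""
    return 1.0 - rs**2


def _design(d: DescriptorTable | pd.DataFrame, variables, y: pd.Series):
    """Listwise-complete aligned design matrix and response."""
    values = d.values if isinstance(d, DescriptorTable) else d
    missing = [v for v in variables if v not in values.columns]
    if missing:
        raise KeyError(f"unknown model variables: {missing}")
    X = values.loc[:, list(variables)]
    common = X.index.intersection(y.index)
    X = X.loc[common]
    yv = y.loc[common].astype(float)
    ok = X.notna().all(axis=1) & yv.notna()
    return X.loc[ok], yv.loc[ok]


def fit_ols(X: pd.DataFrame, y: pd.Series) -> OlsFit:
    """Ordinary least squares of y on X with intercept.

    Raises :class:`CollinearityError` naming the offending columns when the
    design (with intercept) is rank-deficient, and
    :class:`InsufficientDataError` when n <= number of parameters.
    """
    if len(X.columns) > MAX_PREDICTORS:
        raise ValueError(
            f"{len(X.columns)} predictors exceed the small-n ceiling of {MAX_PREDICTORS}"
        )
    n, k = X.shape
    if n <= k + 1:
        raise InsufficientDataError(f"n={n} too small for {k} predictors plus intercept")
    exog = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        offenders = _rank_deficient_columns(exog)
        raise CollinearityError(f"rank-deficient design; offending columns: {offenders}")
    res = sm.OLS(y.astype(float), exog).fit()
    coef = res.params.copy()
    coef.index = ["intercept", *X.columns]
    # res.llf is the Gaussian log-likelihood at the ML variance RSS/n
    return OlsFit(
        variables=tuple(X.columns),
        coefficients=coef,
        rss=float(res.ssr),
        loglik=float(res.llf),
        n=n,
    )


def _rank_deficient_columns(exog: pd.DataFrame) -> list[str]:
    """Greedy scan for columns that do not increase the design rank."""
    cols: list[str] = []
    kept = np.empty((len(exog), 0))
    for name in exog.columns:
        cand = np.column_stack([kept, exog[name].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            cols.append(str(name))
    return cols


def loocv_evaluate(
    variables,
    d: DescriptorTable | pd.DataFrame,
    y: pd.Series,
    min_n: int = 6,
) -> ModelFit:
    """Leave-one-out cross-validated fit of ROR on the given descriptors.

    Each cancer type is predicted from a model fitted on the remaining n-1;
    the pooled held-out predictions are compared with the observed RORs by
    tie-aware Spearman Rs.  The returned fit also carries the full-data
    coefficients, log-likelihood and (for >= 2 predictors) VIFs.
    """
    variables = tuple(variables)
    X, yv = _design(d, variables, y)
    n = len(X)
    if n < min_n:
        raise InsufficientDataError(f"LOOCV needs n >= {min_n}, got {n}")
    full = fit_ols(X, yv)
    preds = pd.Series(index=X.index, dtype=float)
    Xn = X.to_numpy(dtype=float)
    yn = yv.to_numpy(dtype=float)
    exog = np.column_stack([np.ones(n), Xn])
    for i in range(n):
        mask = np.arange(n) != i
        A, b = exog[mask], yn[mask]
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise CollinearityError(f"rank-deficient design in LOOCV fold {X.index[i]!r}")
        beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        preds.iloc[i] = exog[i] @ beta
    rs, p = spearman(preds.to_numpy(), yn)
    vifs = vif(X) if len(variables) >= 2 else pd.Series(dtype=float)
    return ModelFit(
        variables=variables,
        coefficients=full.coefficients,
        loocv_rs=rs,
        loocv_p=p,
        unexplained_variance=unexplained_variance(rs),
        loglik=full.loglik,
        n=n,
        vif=vifs,
        predictions=preds,
    )


def lrt(reduced, full) -> ModelComparison:
    """Likelihood-ratio test of a reduced model against a nested full model.

    Both fits must come from the same observations; the statistic is
    2 * (loglik_full - loglik_reduced) on df = difference in parameter count,
    referred to the chi-square upper tail.
    """
    rv, fv = set(reduced.variables), set(full.variables)
    if not rv <= fv:
        raise NestingError(f"{sorted(rv)} is not nested in {sorted(fv)}")
    if reduced.n != full.n:
        raise NestingError(f"different observation counts: {reduced.n} vs {full.n}")
    df = len(fv) - len(rv)
    stat = 2.0 * (full.loglik - reduced.loglik)
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return ModelComparison(reduced=reduced, full=full, lrt_stat=stat, df=df, p_value=p)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    R^2_j is from regressing column j on the remaining columns with an
    intercept.  Perfectly collinear columns are reported as ``inf`` rather
    than raising.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 variables")
    if len(X) <= X.shape[1] + 1:
        raise InsufficientDataError("n too small for VIF auxiliary regressions")
    out = {}
    Xn = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        others = np.delete(Xn, j, axis=1)
        exog = np.column_stack([np.ones(len(Xn)), others])
        beta, *_ = np.linalg.lstsq(exog, Xn[:, j], rcond=None)
        resid = Xn[:, j] - exog @ beta
        tss = ((Xn[:, j] - Xn[:, j].mean()) ** 2).sum()
        if tss == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - (resid**2).sum() / tss
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def combination_search(
    candidates,
    d: DescriptorTable | pd.DataFrame,
    y: pd.Series,
    sizes: tuple[int, ...] = (2, 3),
) -> pd.DataFrame:
    """Evaluate every 2- and 3-variable combination of the candidate features.

    All C(k,2)+C(k,3) variable sets (for the default sizes and k candidates)
    are scored by :func:`loocv_evaluate`; the table is ranked by LOOCV Rs
    (ties: fewer variables, then lexicographic variable ids) and carries
    Benjamini–Hochberg q-values over the whole search family.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("combination search needs at least 2 candidate features")
    rows = []
    for size in sorted(sizes):
        for combo in itertools.combinations(sorted(candidates), size):
            fit = loocv_evaluate(combo, d, y)
            rows.append(
                {
                    "variables": ";".join(combo),
                    "n_variables": size,
                    "loocv_rs": fit.loocv_rs,
                    "loocv_p": fit.loocv_p,
                    "unexplained_variance": fit.unexplained_variance,
                    "max_vif": fit.max_vif,
                }
            )
    res = pd.DataFrame(rows)
    res["q_value"] = bh_adjust(res["loocv_p"].to_numpy())
    res = res.sort_values(
        ["loocv_rs", "n_variables", "variables"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return res


def augment_model(
    base_variables,
    extra: str,
    d: DescriptorTable | pd.DataFrame,
    y: pd.Series,
) -> tuple[ModelComparison, ModelFit]:
    """Add one feature to a base model and test whether it improves the fit.

    Returns the likelihood-ratio comparison (base vs augmented, refitted on
    the shared complete observations) and the augmented LOOCV fit with its
    VIFs.
    """
    base_variables = tuple(base_variables)
    if extra in base_variables:
        raise ValueError(f"{extra!r} already in the base model")
    aug_vars = (*base_variables, extra)
    X_aug, y_aug = _design(d, aug_vars, y)
    base_fit = fit_ols(X_aug[list(base_variables)], y_aug)
    full_fit = fit_ols(X_aug, y_aug)
    comparison = lrt(base_fit, full_fit)
    aug_loocv = loocv_evaluate(aug_vars, X_aug, y_aug)
    return comparison, aug_loocv


def write_models(res: pd.DataFrame, path) -> None:
    res.to_csv(path, sep="\t", index=False)
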