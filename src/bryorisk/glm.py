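"""Binary logistic GLM core and auxiliary statistics.

Thin, typed layer over statsmodels: maximum-likelihood logistic fits with
Wald inference, variance inflation factors, Pearson chi-square association
tests and binned-residual diagnostics — the statistical toolkit the
trait-screening and model-selection stages are built from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

MAX_ITER = 100
TOL = 1e-8


class SeparationError(RuntimeError):
    """The two outcome classes are perfectly separated by the predictors."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


@dataclass
class GLMFit:
    """A fitted binary logistic regression.

    Coefficients are on the logit scale; ``aic = -2*llf + 2*k`` where k is
    the number of estimated coefficients (intercept included).
    """

    predictor_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    aic: float
    n: int
    df_residual: int
    fitted_probabilities: np.ndarray
    n_dropped: int = 0

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.predictor_names.index(name)])

    def summary_frame(self, level: float = 0.95) -> pd.DataFrame:
        half = wald_ci(self, level)
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "ci_half_width": half,
                "z_value": self.z_values,
                "p_value": self.p_values,
            },
            index=self.predictor_names,
        )


def _check_separation(y: np.ndarray, p: np.ndarray, params: np.ndarray) -> None:
    # Diverging coefficients with fitted probabilities pinned at the labels
    # are the IRLS signature of (quasi-)complete separation.
    eps = 1e-8
    pinned = np.all((p > 1 - eps) == (y == 1)) and np.all((p < eps) == (y == 0))
    if pinned or not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e3:
        raise SeparationError(
            "complete or quasi-complete separation detected; "
            "coefficient estimates do not exist"
        )


def fit_logistic(response, design: pd.DataFrame | None) -> GLMFit:
    """Fit ``logit(P(y=1)) = intercept + X beta`` by maximum likelihood.

    ``design`` holds the predictor columns (no intercept column; one is
    added); ``None`` or an empty frame fits the intercept-only model.
    Records with any missing predictor or response are dropped (complete
    cases), with the count kept on the returned fit.
    """
    y = pd.Series(response).reset_index(drop=True)
    if design is None or (hasattr(design, "shape") and design.shape[1] == 0):
        X = pd.DataFrame(index=y.index)
    else:
        X = pd.DataFrame(design).reset_index(drop=True).astype(float)

    complete = y.notna().to_numpy()
    if X.shape[1]:
        complete &= X.notna().all(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    y = y[complete].astype(float).to_numpy()
    X = X.loc[complete]

    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 records in each outcome class")

    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")

    model = sm.GLM(y, Xc, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.simplefilter(
            "error", category=sm.tools.sm_exceptions.PerfectSeparationWarning
        )
        try:
            res = model.fit(maxiter=MAX_ITER, tol=TOL)
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            RuntimeWarning,
        ) as exc:
            raise SeparationError(str(exc)) from exc
    if not res.converged:
        raise ConvergenceError(f"IRLS did not converge in {MAX_ITER} iterations")
    _check_separation(y, res.fittedvalues, res.params.to_numpy())

    names = ["Intercept"] + list(X.columns)
    k = len(names)
    llf = float(res.llf)
    return GLMFit(
        predictor_names=names,
        coefficients=res.params.to_numpy(),
        standard_errors=res.bse.to_numpy(),
        z_values=res.tvalues.to_numpy(),
        p_values=res.pvalues.to_numpy(),
        log_likelihood=llf,
        aic=-2.0 * llf + 2.0 * k,
        n=len(y),
        df_residual=len(y) - k,
        fitted_probabilities=np.asarray(res.fittedvalues, dtype=float),
        n_dropped=n_dropped,
    )


def wald_ci(fit: GLMFit, level: float = 0.95) -> np.ndarray:
    """Per-coefficient Wald half-widths: z_{(1+level)/2} × SE.

    Intervals are reported in the estimate ± half-width convention.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    zq = st.norm.ppf(0.5 + level / 2.0)
    return zq * fit.standard_errors


@dataclass
class VIFReport:
    """Variance inflation factors, VIF_j = 1/(1−R²_j)."""

    vifs: dict[str, float]
    collinear_pairs: list[tuple[str, str]]

    def max(self) -> float:
        return max(self.vifs.values())


def vif(design: pd.DataFrame) -> VIFReport:
    """VIF of each predictor from an OLS regression on the others.

    Exact collinearity is reported as infinity together with the culprit
    pair (the two most correlated columns involving the offender).
    """
    X = pd.DataFrame(design).astype(float).dropna()
    if X.shape[1] < 2:
        raise ValueError("need >= 2 predictors for VIF")
    if (X.std(ddof=0) == 0).any():
        bad = X.columns[(X.std(ddof=0) == 0)].tolist()
        raise ValueError(f"zero-variance predictors: {bad}")

    vifs: dict[str, float] = {}
    collinear: list[tuple[str, str]] = []
    corr = X.corr().abs()
    for col in X.columns:
        others = X.drop(columns=[col])
        r2 = sm.OLS(X[col], sm.add_constant(others)).fit().rsquared
        if r2 > 1 - 1e-12:
            vifs[col] = np.inf
            partner = corr[col].drop(col).idxmax()
            pair = tuple(sorted((col, partner)))
            if pair not in collinear:
                collinear.append(pair)
        else:
            vifs[col] = float(1.0 / (1.0 - r2))
    return VIFReport(vifs=vifs, collinear_pairs=collinear)


@dataclass
class ContingencyTest:
    """Pearson chi-square test of independence on a 2×2 table."""

    statistic: float
    df: int
    p_value: float
    table: np.ndarray

    @property
    def odds_ratio(self) -> float:
        a, b = self.table[0]
        c, d = self.table[1]
        return (a * d) / (b * c) if b * c > 0 else np.inf


def chisq_association(a, b) -> ContingencyTest:
    """Pearson chi-square (no continuity correction) for two binary traits.

    Pairs with a missing value in either trait are dropped first.
    """
    df = pd.DataFrame({"a": pd.Series(a), "b": pd.Series(b)}).dropna()
    table = pd.crosstab(df["a"], df["b"]).to_numpy()
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2×2 table, got shape {table.shape}")
    expected = st.contingency.expected_freq(table)
    if (expected == 0).any():
        raise ValueError("zero expected cell count")
    stat, p, dof, _ = st.chi2_contingency(table, correction=False)
    return ContingencyTest(statistic=float(stat), df=int(dof), p_value=float(p), table=table)


def binned_residuals(fit: GLMFit, response, n_bins: int = 10) -> pd.DataFrame:
    """Average residuals in bins of fitted probability, with ±2 SE bands.

    Records are sorted by fitted probability and split into near-equal bins;
    the residual is observed − fitted.  A well-specified model keeps ~95% of
    bin means inside the band.
    """
    y = np.asarray(response, dtype=float)
    p = fit.fitted_probabilities
    if len(y) != len(p):
        raise ValueError("response length must match fitted probabilities")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > len(y):
        raise ValueError("more bins than records")

    order = np.argsort(p, kind="stable")
    rows = []
    for idx in np.array_split(order, n_bins):
        pb, yb = p[idx], y[idx]
        resid = yb - pb
        se = np.sqrt(np.mean(pb * (1 - pb)) / len(idx))
        rows.append(
            {
                "bin_mean_fitted": float(pb.mean()),
                "mean_residual": float(resid.mean()),
                "band_half_width": float(2.0 * se),
                "n": len(idx),
            }
        )
    return pd.DataFrame(rows)
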