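"""Random-effects meta-regression for proportion outcomes.

The model for study i with observed abstinence rate y_i is

    y_i = x_i' beta + u_i + e_i,   u_i ~ N(0, tau^2),   e_i ~ N(0, v_i)

where v_i is the known within-study sampling variance (binomial for a rate
outcome) and tau^2 the between-study variance.  Fitting proceeds in the
standard two stages: estimate tau^2 (REML by default, or the
method-of-moments generalization of the Q statistic), then solve the
weighted least-squares normal equations with weights w_i = 1/(v_i + tau^2).

Heterogeneity is summarized by tau^2 and by I^2 = tau^2/(tau^2 + s^2) with
s^2 the "typical" within-study variance, and model fit by the adjusted R^2,
the proportional reduction of tau^2 relative to the intercept-only model on
the same studies (which may be negative).  Coefficient tests use a
t reference with k - p - 1 degrees of freedom by default (k studies, p
slope terms), optionally with the Knapp-Hartung variance inflation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

Tau2Method = Literal["reml", "mom"]
TestMethod = Literal["t", "z"]


@dataclass
class MetaDataset:
    """Study-level outcomes, within-study variances, and a design matrix.

    ``X`` has one row per study with the intercept as its first column;
    ``term_names`` labels the columns.
    """

    y: np.ndarray
    v: np.ndarray
    X: np.ndarray
    study_ids: Sequence[str] | None = None
    term_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.X = X
        k, m = self.X.shape
        if self.y.shape != (k,) or self.v.shape != (k,):
            raise ValueError("y, v, and X must agree on the number of studies")
        if np.any(self.v <= 0):
            raise ValueError("all within-study variances must be positive")
        if np.linalg.matrix_rank(self.X) < m:
            raise ValueError("design matrix is rank-deficient")
        if self.term_names is None:
            self.term_names = ["intercept"] + [f"x{j}" for j in range(1, m)]
        if len(self.term_names) != m:
            raise ValueError("term_names must match the design matrix columns")
        if self.study_ids is None:
            self.study_ids = [f"s{i}" for i in range(k)]

    @property
    def k(self) -> int:
        """Number of studies."""
        return self.X.shape[0]

    @property
    def p(self) -> int:
        """Number of slope terms (design columns minus the intercept)."""
        return self.X.shape[1] - 1

    def validate_size(self) -> None:
        if self.k < self.p + 2:
            raise ValueError(
                f"insufficient studies: k={self.k} with {self.p} slope term(s) "
                f"requires k >= {self.p + 2}"
            )


@dataclass
class MetaRegressionResult:
    """Fitted coefficients, their covariance, and heterogeneity summaries."""

    beta: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    pval: np.ndarray
    cov: np.ndarray
    tau2: float
    i2: float
    adjusted_r2: float | None
    tau2_null: float | None
    k: int
    p: int
    term_names: Sequence[str]
    tau2_method: Tau2Method
    test_method: TestMethod
    knapp_hartung: bool
    df: float

    def coefficient_table(self):
        """Coefficient summary as a pandas DataFrame (estimate, se, stat, p)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "term": list(self.term_names),
                "estimate": self.beta,
                "se": self.se,
                "stat": self.stat,
                "p_value": self.pval,
            }
        )


@dataclass(frozen=True)
class Prediction:
    """Model-based point prediction with a confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    covariates: tuple
    alpha: float


def within_study_variance(
    n_abstinent: int, n: int, correction: Literal["boundary", "none"] = "boundary"
) -> float:
    """Binomial sampling variance of an observed proportion, p(1-p)/n.

    At the boundary (0 or n events) the plain formula collapses to zero and
    would give the study infinite weight; the default policy substitutes the
    shrunk proportion (n_abstinent + 1/2)/(n + 1) before applying the
    formula.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not (0 <= n_abstinent <= n):
        raise ValueError(f"n_abstinent={n_abstinent} outside [0, {n}]")
    p = n_abstinent / n
    if correction == "boundary" and (n_abstinent == 0 or n_abstinent == n):
        p = (n_abstinent + 0.5) / (n + 1)
    elif correction not in ("boundary", "none"):
        raise ValueError(f"unknown correction policy {correction!r}")
    if p in (0.0, 1.0):
        raise ValueError("degenerate proportion with correction disabled")
    return p * (1.0 - p) / n


def _gls(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve the weighted normal equations; returns (beta, (X'WX)^-1)."""
    XtW = X.T * w
    XtWX = XtW @ X
    XtWX_inv = np.linalg.inv(XtWX)
    beta = XtWX_inv @ (XtW @ y)
    return beta, XtWX_inv


def _q_statistic(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> float:
    beta, _ = _gls(y, X, w)
    resid = y - X @ beta
    return float(np.sum(w * resid**2))


def _tau2_mom(data: MetaDataset) -> float:
    """Method-of-moments (generalized Q) estimator, truncated at zero.

    With fixed-effect weights w = 1/v:  tau2 = (Q - df) / C, where
    Q is the weighted residual sum of squares of the w-weighted fit,
    df = k - p - 1, and C = tr(W) - tr((X'WX)^-1 X'W^2X).
    """
    w = 1.0 / data.v
    X = data.X
    Q = _q_statistic(data.y, X, w)
    df = data.k - data.p - 1
    XtWX_inv = np.linalg.inv((X.T * w) @ X)
    C = float(np.sum(w) - np.trace(XtWX_inv @ ((X.T * w**2) @ X)))
    if C <= 0:
        return 0.0
    return max(0.0, (Q - df) / C)


def _reml_nll(tau2: float, y: np.ndarray, X: np.ndarray, v: np.ndarray) -> float:
    """Negative restricted log-likelihood (constants dropped)."""
    w = 1.0 / (v + tau2)
    XtWX = (X.T * w) @ X
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    Q = _q_statistic(y, X, w)
    return 0.5 * (-np.sum(np.log(w)) + logdet + Q)


def estimate_tau2(
    data: MetaDataset, method: Tau2Method = "reml", upper: float | None = None
) -> float:
    """Estimate the between-study variance tau^2.

    ``reml`` maximizes the restricted log-likelihood over [0, upper] by
    bounded scalar optimization (upper defaults to max(10 * var(y), 10 *
    max(v)), generous for proportion outcomes); ``mom`` is the
    method-of-moments generalization of the Q statistic.  Both are
    deterministic given identical inputs.
    """
    data.validate_size()
    if method == "mom":
        return _tau2_mom(data)
    if method != "reml":
        raise ValueError(f"unknown tau2 method {method!r}")
    y, X, v = data.y, data.X, data.v
    if upper is None:
        upper = max(10.0 * float(np.var(y)), 10.0 * float(np.max(v)), 1e-6)
    res = optimize.minimize_scalar(
        _reml_nll,
        bounds=(0.0, upper),
        args=(y, X, v),
        method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = float(res.x)
    # the bounded minimizer never lands exactly on a boundary: probe it
    if _reml_nll(0.0, y, X, v) <= res.fun:
        tau2 = 0.0
    return _reml_polish(tau2, y, X, v, upper)


def _reml_score(tau2: float, y: np.ndarray, X: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Gradient of the restricted log-likelihood in tau^2, and Fisher info.

    With P = W - WX(X'WX)^-1 X'W:  score = (y'PPy - tr(P))/2, info = tr(PP)/2.
    """
    w = 1.0 / (v + tau2)
    WX = X * w[:, None]
    P = np.diag(w) - WX @ np.linalg.solve(X.T @ WX, WX.T)
    Py = P @ y
    score = 0.5 * (Py @ Py - np.trace(P))
    info = 0.5 * float(np.sum(P * P))
    return float(score), info


def _reml_polish(tau2: float, y, X, v, upper: float, max_iter: int = 25) -> float:
    """Fisher-scoring refinement: the scalar search localizes the optimum
    only to ~1e-10 (the likelihood is flat to float precision there); the
    gradient root is a sharper, order-stable characterization."""
    for _ in range(max_iter):
        score, info = _reml_score(tau2, y, X, v)
        if tau2 == 0.0 and score <= 0.0:
            return 0.0  # boundary optimum
        if info <= 0:
            break
        step = score / info
        new = min(max(tau2 + step, 0.0), upper)
        if abs(new - tau2) < 1e-15 * max(1.0, tau2):
            return new
        tau2 = new
    return tau2


def i_squared(tau2: float, v: Sequence[float], p: int = 0) -> float:
    """Residual heterogeneity fraction I^2 = tau^2 / (tau^2 + s^2).

    s^2 is the "typical" within-study variance
    s^2 = (k - p - 1) * sum(w) / ((sum w)^2 - sum(w^2)),  w = 1/v,
    so that with equal variances and no slopes s^2 reduces to v itself.
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0 or np.any(v <= 0):
        raise ValueError("v must be a nonempty list of positive variances")
    if tau2 < 0:
        raise ValueError(f"tau2 must be non-negative, got {tau2}")
    w = 1.0 / v
    k = v.size
    denom = np.sum(w) ** 2 - np.sum(w**2)
    if denom <= 0:
        raise ValueError("degenerate typical-variance denominator (need k >= 2)")
    s2 = (k - p - 1) * np.sum(w) / denom
    if s2 <= 0:
        raise ValueError("degenerate typical within-study variance")
    return float(tau2 / (tau2 + s2))


def adjusted_r2(tau2_null: float, tau2_model: float) -> float:
    """Proportional reduction in tau^2 relative to the intercept-only model.

    Negative when covariates inflate the estimated between-study variance.
    Defined as 0 when both variances are 0; -inf when the null model has no
    heterogeneity but the covariate model does (flagged downstream).
    """
    if tau2_null < 0 or tau2_model < 0:
        raise ValueError("tau2 values must be non-negative")
    if tau2_null == 0:
        return 0.0 if tau2_model == 0 else -math.inf
    return 1.0 - tau2_model / tau2_null


def fit_meta_regression(
    data: MetaDataset,
    tau2_method: Tau2Method = "reml",
    test: TestMethod = "t",
    knapp_hartung: bool = False,
    with_adjusted_r2: bool = True,
) -> MetaRegressionResult:
    """Fit the random-effects meta-regression.

    Stages: estimate tau^2, then weighted GLS with weights 1/(v_i + tau^2).
    The coefficient covariance is (X'WX)^-1, optionally inflated by the
    Knapp-Hartung scale factor Q_gen/(k - p - 1).  Tests use a t reference
    with k - p - 1 df (default) or the standard normal.

    When the design has slope terms and ``with_adjusted_r2`` is set, the
    intercept-only model is refit on the same studies with the same tau^2
    method to obtain the adjusted R^2.
    """
    data.validate_size()
    tau2 = estimate_tau2(data, tau2_method)
    y, X, v = data.y, data.X, data.v
    w = 1.0 / (v + tau2)
    beta, cov = _gls(y, X, w)
    df = data.k - data.p - 1
    if knapp_hartung:
        resid = y - X @ beta
        scale = float(np.sum(w * resid**2)) / df
        cov = cov * max(scale, 1.0)  # truncated form: never deflate below GLS
    se = np.sqrt(np.diag(cov))
    stat = beta / se
    if test == "t":
        pval = 2.0 * stats.t.sf(np.abs(stat), df)
    elif test == "z":
        pval = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        raise ValueError(f"unknown test method {test!r}")
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    i2 = i_squared(tau2, v, data.p)

    tau2_null = None
    adj_r2 = None
    if with_adjusted_r2 and data.p >= 1:
        null_data = MetaDataset(
            y=y, v=v, X=np.ones((data.k, 1)), study_ids=data.study_ids, term_names=["intercept"]
        )
        tau2_null = estimate_tau2(null_data, tau2_method)
        adj_r2 = adjusted_r2(tau2_null, tau2)

    return MetaRegressionResult(
        beta=beta,
        se=se,
        stat=stat,
        pval=pval,
        cov=cov,
        tau2=tau2,
        i2=i2,
        adjusted_r2=adj_r2,
        tau2_null=tau2_null,
        k=data.k,
        p=data.p,
        term_names=list(data.term_names),
        tau2_method=tau2_method,
        test_method=test,
        knapp_hartung=knapp_hartung,
        df=float(df),
    )


def predict(
    result: MetaRegressionResult, covariates: Sequence[float], alpha: float = 0.05
) -> Prediction:
    """Predicted mean outcome at a covariate vector, with a CI.

    point = x'beta; the interval uses the coefficient covariance and the
    result's test reference (t with k - p - 1 df, or normal).  Values are on
    the proportion scale and deliberately not clipped to [0, 1]; reporting
    layers may display negative lower bounds.
    """
    x = np.asarray(covariates, dtype=float)
    if x.shape != result.beta.shape:
        raise ValueError(
            f"covariate vector of length {x.size} does not conform to "
            f"{result.beta.size} coefficients"
        )
    point = float(x @ result.beta)
    se = float(np.sqrt(x @ result.cov @ x))
    if result.test_method == "t":
        crit = float(stats.t.ppf(1.0 - alpha / 2.0, result.df))
    else:
        crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return Prediction(
        point=point,
        ci_low=point - crit * se,
        ci_high=point + crit * se,
        covariates=tuple(x),
        alpha=alpha,
    )
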