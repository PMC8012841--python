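"""Survival engine: Kaplan-Meier, log-rank/Wilcoxon, Cox PH, parametric
exponential PH with interactions, and Weibull/exponential AFT with
event-time ratios.

Nonparametric estimation and the Cox partial likelihood are delegated to
lifelines (Efron tie handling, log-log Greenwood confidence bands); the
exponential proportional-hazards regression is a direct Newton maximum
likelihood fit, which keeps full control over interaction columns and Wald
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter, WeibullAFTFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass
class KMCurve:
    """Product-limit estimate with pointwise 95% CI and median."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    median: float           # NaN when S never reaches 0.5
    median_ci: tuple[float, float]
    n: int

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median)


@dataclass
class SurvFit:
    """Regression fit summary on the hazard or log-time scale."""

    model: str
    coefficients: pd.Series
    se: pd.Series
    wald_chisq: pd.Series
    p: pd.Series
    log_likelihood: float
    hazard_ratios: pd.Series | None = None
    event_time_ratios: pd.Series | None = None
    extra: dict = field(default_factory=dict)


def _check_samples(time: np.ndarray, event: np.ndarray) -> None:
    if len(time) == 0:
        raise ValueError("empty survival sample")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be positive and finite")
    if len(event) != len(time):
        raise ValueError("time and event must have equal length")


def km_estimate(time, event, alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier estimate with Greenwood log-log 95% confidence band.

    The median is the earliest time at which S(t) <= 0.5 and is flagged
    undefined (NaN) when the curve never reaches 0.5.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_samples(time, event)

    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(time, event)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_survival_function_
    ts = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy(float)
    med = kmf.median_survival_time_
    med = float(med) if np.isfinite(med) else np.nan
    from lifelines.utils import median_survival_times
    mci = median_survival_times(kmf.confidence_interval_)
    med_lo, med_hi = float(mci.iloc[0, 0]), float(mci.iloc[0, 1])
    at_risk = np.array([(time >= t).sum() for t in ts])
    return KMCurve(times=ts, survival=surv,
                   ci_lower=ci.iloc[:, 0].to_numpy(float),
                   ci_upper=ci.iloc[:, 1].to_numpy(float),
                   n_at_risk=at_risk, median=med,
                   median_ci=(med_lo, med_hi), n=len(time))


def logrank_test(time, event, group, variant: str = "logrank"):
    """Multi-group log-rank (or Wilcoxon/Gehan-Breslow) chi-square test.

    The Wilcoxon variant weights each event time by the number at risk,
    emphasizing early differences.  Returns ``(statistic, p, df)``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    _check_samples(time, event)
    if len(np.unique(group)) < 2:
        raise ValueError("logrank_test needs >= 2 groups")
    if event.sum() == 0:
        raise ValueError("logrank_test needs >= 1 event")
    if variant == "logrank":
        res = multivariate_logrank_test(time, group, event)
    elif variant == "wilcoxon":
        res = multivariate_logrank_test(time, group, event, weightings="wilcoxon")
    else:
        raise ValueError(f"unknown variant {variant!r}")
    df = len(np.unique(group)) - 1
    return float(res.test_statistic), float(res.p_value), df


def _wald(coefs: pd.Series, se: pd.Series) -> tuple[pd.Series, pd.Series]:
    chisq = (coefs / se) ** 2
    p = pd.Series(stats.chi2.sf(chisq, df=1), index=coefs.index)
    return chisq, p


def _design(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Covariate matrix; ``'a*b'`` entries become product interaction columns."""
    X = pd.DataFrame(index=df.index)
    for name in covariates:
        if "*" in name:
            a, b = (s.strip() for s in name.split("*", 1))
            X[name] = df[a].to_numpy(float) * df[b].to_numpy(float)
        else:
            X[name] = df[name].to_numpy(float)
    return X


def _reject_constant(X: pd.DataFrame) -> None:
    for c in X.columns:
        if np.ptp(X[c].to_numpy(float)) == 0:
            raise ValueError(f"constant covariate: {c!r}")


def cox_fit(df: pd.DataFrame, covariates: list[str],
            time_col: str = "survival_days", event_col: str = "event") -> SurvFit:
    """Cox proportional-hazards fit (Efron ties) with per-covariate Wald tests."""
    X = _design(df, covariates)
    _check_samples(df[time_col].to_numpy(float), df[event_col].to_numpy(int))
    if df[event_col].sum() == 0:
        raise ValueError("cox_fit needs >= 1 event")
    _reject_constant(X)
    data = X.reset_index(drop=True)
    data["_T"], data["_E"] = df[time_col].to_numpy(float), df[event_col].to_numpy(int)
    cph = CoxPHFitter()
    cph.fit(data, duration_col="_T", event_col="_E")
    coefs = cph.params_.rename(None)
    se = cph.standard_errors_.rename(None)
    chisq, p = _wald(coefs, se)
    return SurvFit(model="cox", coefficients=coefs, se=se,
                   wald_chisq=chisq, p=p,
                   log_likelihood=float(cph.log_likelihood_),
                   hazard_ratios=np.exp(coefs))


def parametric_fit(df: pd.DataFrame, covariates: list[str],
                   time_col: str = "survival_days", event_col: str = "event",
                   max_iter: int = 100, tol: float = 1e-10) -> SurvFit:
    """Exponential proportional-hazards regression by full maximum likelihood.

    Hazard ``lambda_i = exp(b0 + x_i . b)``; supports ``'a*b'`` product
    interaction terms.  The log-likelihood is concave in the coefficients,
    so Newton iteration from the null-model start converges globally.
    Covariates are standardized internally; reported coefficients are on the
    original scale.
    """
    X = _design(df, covariates)
    t = df[time_col].to_numpy(float)
    d = df[event_col].to_numpy(int)
    _check_samples(t, d)
    if d.sum() == 0:
        raise ValueError("parametric_fit needs >= 1 event")
    _reject_constant(X)

    mu = X.mean().to_numpy()
    sd = X.std(ddof=0).to_numpy()
    Z = np.column_stack([np.ones(len(X)), (X.to_numpy(float) - mu) / sd])

    beta = np.zeros(Z.shape[1])
    beta[0] = np.log(d.sum() / t.sum())  # null-model MLE
    ll_prev = -np.inf
    for it in range(max_iter):
        eta = Z @ beta
        lam = np.exp(eta)
        ll = float(np.sum(d * eta - t * lam))
        grad = Z.T @ (d - t * lam)
        H = -(Z * (t * lam)[:, None]).T @ Z
        step = np.linalg.solve(H, grad)
        beta = beta - step
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            break
        ll_prev = ll
    else:
        raise RuntimeError(f"parametric_fit did not converge in {max_iter} iterations")

    eta = Z @ beta
    ll = float(np.sum(d * eta - t * np.exp(eta)))
    cov_z = np.linalg.inv((Z * (t * np.exp(eta))[:, None]).T @ Z)
    # back-transform standardized coefficients to the original covariate scale
    names = ["intercept"] + list(X.columns)
    A = np.eye(len(beta))
    for j in range(1, len(beta)):
        A[j, j] = 1.0 / sd[j - 1]
        A[0, j] = -mu[j - 1] / sd[j - 1]
    b_orig = A @ beta
    cov = A @ cov_z @ A.T
    coefs = pd.Series(b_orig, index=names)
    se = pd.Series(np.sqrt(np.diag(cov)), index=names)
    chisq, p = _wald(coefs, se)
    return SurvFit(model="exponential_ph", coefficients=coefs, se=se,
                   wald_chisq=chisq, p=p, log_likelihood=ll,
                   hazard_ratios=np.exp(coefs),
                   extra={"iterations": it + 1})


def aft_fit(df: pd.DataFrame, covariates: list[str],
            time_col: str = "survival_days", event_col: str = "event",
            distribution: str = "weibull") -> SurvFit:
    """Accelerated-failure-time fit; event-time ratio = exp(coef) per covariate.

    Default Weibull family (lifelines); ``distribution='exponential'`` uses
    the exponential AFT, whose coefficients are the negated exponential-PH
    coefficients (ETR = 1/HR duality).
    """
    X = _design(df, covariates)
    _check_samples(df[time_col].to_numpy(float), df[event_col].to_numpy(int))
    if df[event_col].sum() == 0:
        raise ValueError("aft_fit needs >= 1 event")
    _reject_constant(X)

    if distribution == "exponential":
        ph = parametric_fit(df, covariates, time_col, event_col)
        coefs = -ph.coefficients
        se = ph.se
        chisq, p = _wald(coefs, se)
        return SurvFit(model="exponential_aft", coefficients=coefs, se=se,
                       wald_chisq=chisq, p=p,
                       log_likelihood=ph.log_likelihood,
                       event_time_ratios=np.exp(coefs))
    if distribution != "weibull":
        raise ValueError(f"unknown distribution {distribution!r}")

    data = X.reset_index(drop=True)
    data["_T"], data["_E"] = df[time_col].to_numpy(float), df[event_col].to_numpy(int)
    aft = WeibullAFTFitter()
    aft.fit(data, duration_col="_T", event_col="_E")
    coefs = aft.params_.loc["lambda_"].drop("Intercept", errors="ignore")
    se = aft.standard_errors_.loc["lambda_"].drop("Intercept", errors="ignore")
    chisq, p = _wald(coefs, se)
    return SurvFit(model="weibull_aft", coefficients=coefs, se=se,
                   wald_chisq=chisq, p=p,
                   log_likelihood=float(aft.log_likelihood_),
                   event_time_ratios=np.exp(coefs),
                   extra={"rho": float(np.exp(aft.params_.loc[("rho_", "Intercept")]))})
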