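"""Treatment-response inference from a historical-control survival model.

The central procedure: fit an exponential generalized linear model with a
reciprocal link — mean survival mu_i = 1/(x_i . beta) — on *deceased*
historical-control patients (covariates: ALSFRS-R slope, age, treatment
latency), predict individual survival for every patient, and classify
treated patients by the signed residual observed - predicted:

* responder        : residual > +threshold (censored patients qualify too,
                     since they have already outlived their prediction);
* non-responder    : residual < -threshold and death observed (a censored
                     shortfall is unprovable);
* non-assignable   : everything else (the residual sits inside the band, or
                     censoring blocks the call).

With eta_i = x_i . beta > 0 the exponential log-likelihood
``sum(log eta_i - t_i * eta_i)`` is concave, so Newton iteration with
step-halving to preserve positivity converges globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import survival as _surv

DEFAULT_COVARIATES = ("alsfrs_slope", "age", "latency_days")
LABELS = ("responder", "non-responder", "non-assignable")


@dataclass
class SurvivalGLM:
    """Exponential reciprocal-link survival model (rate scale, day^-1 units)."""

    coefficients: pd.Series      # intercept + covariates
    cov: np.ndarray              # asymptotic covariance of the coefficients
    log_likelihood: float
    n_train: int
    covariates: tuple[str, ...]

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)),
                         index=self.coefficients.index)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X = np.column_stack([np.ones(len(df))] +
                            [df[c].to_numpy(float) for c in self.covariates]) \
            if self.covariates else np.ones((len(df), 1))
        return X @ self.coefficients.to_numpy()


@dataclass
class ResponderLabels:
    """Per-patient prediction, residual and three-level response label."""

    table: pd.DataFrame  # patient_id, predicted, observed, censored, residual, label
    threshold: float
    n_unpredictable: int = 0

    def counts(self) -> dict[str, int]:
        c = self.table["label"].value_counts()
        return {lab: int(c.get(lab, 0)) for lab in LABELS}


def winsorize_slopes(slopes: pd.Series, ceiling: float = -0.05) -> pd.Series:
    """Cap measured ALSFRS-R slopes at a small negative ceiling.

    Measurement noise can push a short-series slope estimate above zero;
    with the reciprocal link such values force the fitted slope coefficient
    toward zero to keep the linear predictor positive, so both training and
    scoring slopes are winsorized with the same ceiling (points/month).
    """
    return slopes.clip(upper=ceiling)


def fit_survival_glm(train: pd.DataFrame,
                     covariates=DEFAULT_COVARIATES,
                     time_col: str = "survival_days",
                     event_col: str = "event",
                     max_iter: int = 200, tol: float = 1e-8) -> SurvivalGLM:
    """Maximum-likelihood exponential GLM with reciprocal link on deceased patients.

    All training patients must have observed events and defined covariates;
    at least 10 patients per coefficient are required.  Covariates are
    standardized internally for the Newton iteration and reported back on
    their original scales.  Convergence: relative log-likelihood change
    below ``tol``.
    """
    need = [time_col, event_col, *covariates]
    sub = train[need].dropna()
    if len(sub) < len(train):
        raise ValueError("training patients with undefined covariates; "
                         "drop or impute before fitting")
    if not np.all(sub[event_col].to_numpy(int) == 1):
        raise ValueError("training set must contain deceased patients only")
    p = len(covariates) + 1
    if len(sub) < 10 * p:
        raise ValueError(f"need >= {10 * p} training patients for {p} coefficients")

    t = sub[time_col].to_numpy(float)
    if covariates:
        Xr = np.column_stack([sub[c].to_numpy(float) for c in covariates])
        mu_x, sd_x = Xr.mean(axis=0), Xr.std(axis=0, ddof=0)
        if np.any(sd_x == 0):
            bad = [c for c, s in zip(covariates, sd_x) if s == 0]
            raise ValueError(f"constant covariate(s): {bad}")
        Z = np.column_stack([np.ones(len(sub)), (Xr - mu_x) / sd_x])
    else:
        mu_x = sd_x = np.empty(0)
        Z = np.ones((len(sub), 1))

    # start from OLS on 1/t, pulled toward the intercept-only MLE if needed
    beta = np.linalg.lstsq(Z, 1.0 / t, rcond=None)[0]
    if np.any(Z @ beta <= 0):
        beta = np.array([1.0 / t.mean()] + [0.0] * (p - 1))

    def loglik(b):
        eta = Z @ b
        if np.any(eta <= 0):
            return -np.inf
        return float(np.sum(np.log(eta) - t * eta))

    ll = loglik(beta)
    for _ in range(max_iter):
        eta = Z @ beta
        grad = Z.T @ (1.0 / eta - t)
        H = -(Z / (eta ** 2)[:, None]).T @ Z
        step = np.linalg.solve(H, grad)
        scale = 1.0
        for _half in range(50):
            cand = beta - scale * step
            ll_new = loglik(cand)
            if ll_new > -np.inf:
                break
            scale *= 0.5
        else:
            raise RuntimeError(
                "nonpositive linear predictor persists; rescale covariates")
        beta, ll_prev, ll = cand, ll, ll_new
        if abs(ll - ll_prev) <= tol * (1 + abs(ll)):
            break
    else:
        raise RuntimeError(f"fit_survival_glm did not converge in {max_iter} "
                           f"iterations (last ll={ll:.6g})")

    eta = Z @ beta
    cov_z = np.linalg.inv((Z / (eta ** 2)[:, None]).T @ Z)
    # map standardized-scale coefficients back to the original covariate scale
    A = np.eye(p)
    A[0, 1:] = -mu_x / sd_x
    for j in range(1, p):
        A[j, j] = 1.0 / sd_x[j - 1]
    names = ["intercept", *covariates]
    return SurvivalGLM(coefficients=pd.Series(A @ beta, index=names),
                       cov=A @ cov_z @ A.T, log_likelihood=ll,
                       n_train=len(sub), covariates=tuple(covariates))


def predict_survival(model: SurvivalGLM, patients: pd.DataFrame) -> pd.Series:
    """Predicted mean survival in days, ``mu_i = 1/(x_i . beta)``.

    Patients with a missing covariate or a nonpositive linear predictor get
    NaN (flagged unpredictable) rather than failing the whole batch.
    """
    out = np.full(len(patients), np.nan)
    cols = list(model.covariates)
    ok = patients[cols].notna().all(axis=1).to_numpy()
    if ok.any():
        eta = model.linear_predictor(patients.loc[ok, cols])
        pred = np.where(eta > 0, 1.0 / np.where(eta > 0, eta, 1.0), np.nan)
        out[np.nonzero(ok)[0]] = pred
    return pd.Series(out, index=patients.index, name="predicted_days")


def classify_response(patients: pd.DataFrame, predicted: pd.Series,
                      threshold: float = 60.0,
                      time_col: str = "survival_days",
                      event_col: str = "event") -> ResponderLabels:
    """Three-level responder classification from the survival residual.

    ``residual = observed - predicted`` (days).  ``threshold`` is the
    negligible-difference band: residuals inside ``+-threshold`` are
    non-assignable, as are censored patients whose shortfall cannot be
    proven.  Patients without a prediction are labelled non-assignable and
    counted in ``n_unpredictable``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    obs = patients[time_col].to_numpy(float)
    event = patients[event_col].to_numpy(int)
    pred = predicted.to_numpy(float)
    resid = obs - pred

    labels = np.full(len(obs), "non-assignable", dtype=object)
    labels[resid > threshold] = "responder"
    labels[(resid < -threshold) & (event == 1)] = "non-responder"
    unpredictable = ~np.isfinite(pred)
    labels[unpredictable] = "non-assignable"

    table = pd.DataFrame({
        "patient_id": patients["patient_id"].to_numpy(),
        "predicted_days": pred,
        "observed_days": obs,
        "censored": 1 - event,
        "residual_days": resid,
        "label": labels,
    })
    return ResponderLabels(table=table, threshold=float(threshold),
                           n_unpredictable=int(unpredictable.sum()))


def waterfall(labels: ResponderLabels) -> pd.DataFrame:
    """Residuals sorted descending (waterfall order); ties broken by patient id."""
    t = labels.table
    if len(t) == 0:
        raise ValueError("no labeled patients")
    out = t.sort_values(["residual_days", "patient_id"],
                        ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)


def response_survival_contrast(labels: ResponderLabels, patients: pd.DataFrame,
                               time_col: str = "survival_days",
                               event_col: str = "event",
                               groups=("responder", "non-responder")):
    """KM curves per label group plus a log-rank test between them.

    Returns ``(curves, statistic, p)``; the test is flagged undefined
    (NaN) when fewer than two groups have both >= 2 patients and >= 1 event.
    """
    merged = labels.table.merge(patients[["patient_id", time_col, event_col]],
                                on="patient_id")
    curves: dict[str, _surv.KMCurve] = {}
    testable = []
    for g in groups:
        sub = merged[merged["label"] == g]
        if len(sub) == 0:
            continue
        curves[g] = _surv.km_estimate(sub[time_col], sub[event_col])
        if len(sub) >= 2 and sub[event_col].sum() >= 1:
            testable.append(g)
    if len(testable) >= 2:
        sub = merged[merged["label"].isin(testable)]
        stat, p, _ = _surv.logrank_test(sub[time_col], sub[event_col],
                                        sub["label"])
    else:
        stat, p = np.nan, np.nan
    return curves, stat, p


def residual_group_test(labels_a: ResponderLabels | pd.Series,
                        labels_b: ResponderLabels | pd.Series,
                        paired: bool = False) -> tuple[float, float]:
    """Wilcoxon comparison of two residual distributions (rank-sum default)."""
    xa = (labels_a.table["residual_days"] if isinstance(labels_a, ResponderLabels)
          else pd.Series(labels_a)).dropna()
    xb = (labels_b.table["residual_days"] if isinstance(labels_b, ResponderLabels)
          else pd.Series(labels_b)).dropna()
    if paired:
        res = stats.wilcoxon(xa, xb)
    else:
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
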