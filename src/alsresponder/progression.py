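"""Functional-decline modeling.

Per-patient ALSFRS-R slopes by the Theil-Sen estimator (median of all
pairwise slopes, robust to single aberrant visits) and population decline
models: linear mixed-effects regression of ALSFRS-R on a three-knot
restricted cubic spline of month, a group-by-month interaction quantifying
the difference in steepness of decline, and an optional three-way
group-by-month-by-latency interaction testing whether the treatment
contrast shrinks with treatment latency.

Random structure is a per-patient intercept and slope (REML, statsmodels
MixedLM) with an automatic fall-back to intercept-only when the
random-effects covariance is singular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SlopeEstimate:
    patient_id: str
    slope: float      # points/month; NaN when undefined
    n_visits: int
    method: str

    @property
    def defined(self) -> bool:
        return np.isfinite(self.slope)


@dataclass
class DeclineModelFit:
    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    interaction_term: str
    interaction_p: float
    predicted: pd.DataFrame          # month grid x group mean trajectory
    random_structure: str            # "intercept+slope" or "intercept"
    fallback: bool = False
    extra: dict = field(default_factory=dict)

    def group_difference(self, month: float, latency_months: float | None = None) -> float:
        """Model-estimated group contrast in ALSFRS-R points at ``month``.

        For the three-way model the contrast is evaluated at the stated
        treatment latency (months).
        """
        diff = self.params.get("group", 0.0) + self.params.get("group:month", 0.0) * month
        if latency_months is not None:
            diff += self.params.get("group:latency_m", 0.0) * latency_months
            diff += self.params.get("group:month:latency_m", 0.0) * month * latency_months
        return float(diff)


def robust_slope(visits: pd.DataFrame, month_col: str = "month",
                 score_col: str = "alsfrs", method: str = "theil-sen",
                 patient_id: str = "") -> SlopeEstimate:
    """Theil-Sen slope: median of all pairwise (delta score / delta month).

    Patients with fewer than two distinct visit times get an undefined-slope
    marker (NaN) rather than an exception so they remain joinable downstream.
    ``method='ols'`` switches to the ordinary least-squares slope.
    """
    m = visits[month_col].to_numpy(float)
    s = visits[score_col].to_numpy(float)
    n = len(m)
    if len(np.unique(m)) < 2:
        return SlopeEstimate(patient_id, np.nan, n, "undefined")
    if method == "theil-sen":
        i, j = np.triu_indices(n, k=1)
        dm = m[j] - m[i]
        keep = dm != 0
        slope = float(np.median((s[j] - s[i])[keep] / dm[keep]))
    elif method == "ols":
        slope = float(np.polyfit(m, s, 1)[0])
    else:
        raise ValueError(f"unknown method {method!r}")
    return SlopeEstimate(patient_id, slope, n, method)


def slopes_by_patient(visits: pd.DataFrame, method: str = "theil-sen",
                      max_month: float | None = None) -> pd.DataFrame:
    """Per-patient slope table (columns patient_id, alsfrs_slope, n_visits)."""
    sub = visits if max_month is None else visits[visits["month"] <= max_month]
    rows = []
    for pid, g in sub.groupby("patient_id", sort=True):
        est = robust_slope(g, method=method, patient_id=str(pid))
        rows.append((est.patient_id, est.slope, est.n_visits, est.method))
    return pd.DataFrame(rows, columns=["patient_id", "alsfrs_slope",
                                       "n_visits", "slope_method"])


def spline_basis(months, knots=None, n_knots: int = 3) -> pd.DataFrame:
    """Restricted (natural) cubic spline basis of month.

    Knots default to the 10th/50th/90th percentiles of the observed months.
    Returns the linear column plus k-2 nonlinear columns of the standard
    truncated-power construction, linear beyond the boundary knots.
    """
    x = np.asarray(months, dtype=float)
    if knots is None:
        if len(np.unique(x)) < n_knots + 1:
            raise ValueError("need more distinct month values than knots")
        knots = np.quantile(np.unique(x), [0.10, 0.50, 0.90]) if n_knots == 3 \
            else np.quantile(np.unique(x), np.linspace(0.05, 0.95, n_knots))
    knots = np.sort(np.asarray(knots, dtype=float))
    k = len(knots)
    out = pd.DataFrame({"month": x})
    denom = (knots[-1] - knots[0]) ** 2

    def tp(v, t):  # truncated cube
        return np.clip(v - t, 0.0, None) ** 3

    for j in range(k - 2):
        term = (tp(x, knots[j])
                - tp(x, knots[k - 2]) * (knots[-1] - knots[j]) / (knots[-1] - knots[k - 2])
                + tp(x, knots[-1]) * (knots[k - 2] - knots[j]) / (knots[-1] - knots[k - 2]))
        out[f"month_rcs{j + 1}"] = term / denom
    out.attrs["knots"] = knots
    return out


def _decline_design(data: pd.DataFrame, group_col: str, threeway: bool,
                    covariates: list[str], knots=None) -> tuple[pd.DataFrame, list[str]]:
    basis = spline_basis(data["month"].to_numpy(float), knots=knots)
    X = pd.DataFrame({"const": 1.0, "group": data["_group"].to_numpy(float),
                      "month": basis["month"].to_numpy(float)})
    for c in basis.columns[1:]:
        X[c] = basis[c].to_numpy()
    X["group:month"] = X["group"] * X["month"]
    if threeway:
        lat = data["latency_m"].to_numpy(float)
        X["latency_m"] = lat
        X["month:latency_m"] = X["month"] * lat
        X["group:latency_m"] = X["group"] * lat
        X["group:month:latency_m"] = X["group"] * X["month"] * lat
    for c in covariates:
        X[c] = data[c].to_numpy(float)
    X.attrs["knots"] = basis.attrs["knots"]
    return X, list(X.columns)


def fit_decline(visits: pd.DataFrame, patients: pd.DataFrame,
                group_col: str = "cohort", treated_label: str = "treated",
                month_window: float = 6.0,
                covariates: list[str] = ["baseline_alsfrs", "age",
                                         "latency_days", "sex_female"],
                threeway: bool = False,
                random_slope: bool = True,
                eval_month: float = 6.0,
                eval_latency_months: float | None = None) -> DeclineModelFit:
    """Mixed-effects model of ALSFRS-R decline over the analysis window.

    Fixed effects: group, three-knot restricted cubic spline of month,
    group x month interaction (difference in steepness of decline), and the
    adjustment covariates; with ``threeway=True`` the latency two- and
    three-way interaction terms are added (latency in months).  Random
    effects: per-patient intercept and slope by REML; a singular
    random-effects fit is retried with intercept only and flagged.
    """
    import statsmodels.api as sm

    data = visits[visits["month"] <= month_window].merge(
        patients.drop(columns=[c for c in ("cohort",) if c in patients.columns
                               and c in visits.columns]),
        on="patient_id", how="inner", suffixes=("", "_pat"))
    groups_present = data[group_col].nunique()
    if groups_present < 2:
        raise ValueError("need >= 2 groups in the visit table")
    data["_group"] = (data[group_col] == treated_label).astype(float)
    data["latency_m"] = data["latency_days"].to_numpy(float) / 30.44

    covs = [c for c in covariates if c != "latency_days"]
    if not threeway and "latency_days" in covariates:
        covs = covs + ["latency_m"]
    X, names = _decline_design(data, group_col, threeway, covs)
    y = data["alsfrs"].to_numpy(float)

    def _fit(exog_re_cols):
        exog_re = data.assign(const=1.0)[exog_re_cols].to_numpy(float)
        model = sm.MixedLM(y, X.to_numpy(float), groups=data["patient_id"],
                           exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=True, method="lbfgs", maxiter=200)

    structures = ([("intercept+slope", ["const", "month"])] if random_slope else [])
    structures.append(("intercept", ["const"]))
    res, structure, fallback = None, "none", False
    for idx, (sname, cols) in enumerate(structures):
        try:
            res = _fit(cols)
        except (np.linalg.LinAlgError, ValueError):
            res, fallback = None, True
            continue
        singular = (np.linalg.cond(res.cov_re) > 1e8
                    or np.any(np.diag(res.cov_re) <= 1e-12))
        if singular and idx + 1 < len(structures):
            res, fallback = None, True
            continue
        structure = sname
        fallback = fallback or idx > 0 and random_slope
        break
    if res is not None:
        params = pd.Series(res.fe_params, index=names)
        se = pd.Series(res.bse_fe, index=names)
        converged = bool(res.converged)
    else:
        # zero patient-level variance: ordinary least squares limit
        ols = sm.OLS(y, X.to_numpy(float)).fit()
        params = pd.Series(ols.params, index=names)
        se = pd.Series(ols.bse, index=names)
        structure, fallback, converged = "none", True, True
    z = params / se
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
    interaction = "group:month:latency_m" if threeway else "group:month"

    # predicted mean trajectory per group at covariate reference (sample means)
    grid = np.linspace(0.0, float(data["month"].max()), 25)
    pred_rows = {}
    ref = {c: float(data[c].mean()) for c in covs}
    if threeway:
        ref_lat = (eval_latency_months if eval_latency_months is not None
                   else float(data["latency_m"].mean()))
    for gval, gname in ((0.0, "control"), (1.0, treated_label)):
        gb = spline_basis(grid, knots=X.attrs["knots"])
        Xg = pd.DataFrame({"const": 1.0, "group": gval, "month": grid})
        for c in gb.columns[1:]:
            Xg[c] = gb[c].to_numpy()
        Xg["group:month"] = gval * grid
        if threeway:
            Xg["latency_m"] = ref_lat
            Xg["month:latency_m"] = grid * ref_lat
            Xg["group:latency_m"] = gval * ref_lat
            Xg["group:month:latency_m"] = gval * grid * ref_lat
        for c in covs:
            Xg[c] = ref[c]
        pred_rows[gname] = Xg[names].to_numpy(float) @ params.to_numpy()
    predicted = pd.DataFrame({"month": grid, **pred_rows})

    return DeclineModelFit(params=params, se=se, pvalues=pvals,
                           interaction_term=interaction,
                           interaction_p=float(pvals[interaction]),
                           predicted=predicted,
                           random_structure=structure, fallback=fallback,
                           extra={"n_obs": len(data),
                                  "n_patients": int(data["patient_id"].nunique()),
                                  "converged": converged})


def fit_decline_threeway(visits: pd.DataFrame, patients: pd.DataFrame,
                         eval_latency_months: float = 10.0,
                         **kwargs) -> DeclineModelFit:
    """Decline model extended by the group x month x latency interaction."""
    return fit_decline(visits, patients, threeway=True,
                       eval_latency_months=eval_latency_months, **kwargs)
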