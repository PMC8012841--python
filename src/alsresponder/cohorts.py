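"""Synthetic ALS cohort generator.

Emulates the data shapes of a pooled historical-control ALS database
(demographics, riluzole use, onset site, treatment latency, right-censored
survival) and of a small treated cohort with a latent responder subgroup,
plus longitudinal ALSFRS-R trajectories and multimodal biomarker panels.

Survival follows an exponential law with log-linear covariate effects on
the hazard; treated responders have their event time multiplied by an
event-time ratio before administrative censoring.  All generators are
deterministic given their spec (the seed lives inside the spec).

Internal time unit is days; months are converted at 30.44 days/month.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_MONTH = 30.44

#: Covariate columns every patient table carries.
PATIENT_COLUMNS = [
    "patient_id", "cohort", "age", "sex_female", "onset_bulbar",
    "baseline_alsfrs", "latency_days", "riluzole",
    "survival_days", "event",
]

#: Column name reserved for generator truth; analysis stages must never read it.
LATENT_FLAG_COLUMN = "latent_responder"


class SpecValidationError(ValueError):
    """A generator spec field violates its domain."""


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise SpecValidationError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated ALS cohort.

    Hazard for patient *i* is ``baseline_hazard * exp(x_i . betas)`` where
    the covariates in ``log_hazard_betas`` are centered at the spec means
    (binary covariates at 0), so ``baseline_hazard`` is the hazard of the
    mean patient.  Administrative censoring at ``censor_window`` days.
    """

    n_patients: int
    age_mean: float = 58.4
    age_sd: float = 10.5
    frac_female: float = 0.394
    frac_bulbar: float = 0.31
    baseline_alsfrs_mean: float = 36.9
    baseline_alsfrs_sd: float = 5.5
    latency_mean: float = 557.0
    latency_sd: float = 320.0
    riluzole_prob: float = 1.0
    baseline_hazard: float = np.log(2) / 398.0  # median ~13.1 months
    log_hazard_betas: Mapping[str, float] = field(default_factory=dict)
    censor_window: float = 1460.0
    seed: int = 0
    cohort_label: str = "control"

    def validate(self) -> None:
        _check(self.n_patients >= 1, "n_patients", "must be >= 1")
        for name in ("frac_female", "frac_bulbar", "riluzole_prob"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, f"proportion out of [0, 1]: {v}")
        _check(self.baseline_hazard > 0, "baseline_hazard", "must be > 0")
        _check(self.censor_window > 0, "censor_window", "must be > 0")
        for name in ("age_sd", "baseline_alsfrs_sd", "latency_sd"):
            _check(getattr(self, name) >= 0, name, "must be >= 0")
        known = {"age", "sex_female", "onset_bulbar", "baseline_alsfrs",
                 "latency_days", "riluzole"}
        for key in self.log_hazard_betas:
            _check(key in known, "log_hazard_betas", f"unknown covariate {key!r}")


@dataclass(frozen=True)
class TreatedSpec:
    """Treated cohort with a latent responder subgroup.

    Responder status is Bernoulli with probability
    ``expit(logit(responder_fraction) + age_interaction * (age - age_mean))``;
    a negative ``age_interaction`` makes younger patients more likely to
    respond.  Responder event times are multiplied by ``responder_etr``
    (> 1 prolongs survival) before censoring.
    """

    base: CohortSpec
    responder_fraction: float = 0.5
    responder_etr: float = 2.5
    age_interaction: float = 0.0

    def validate(self) -> None:
        self.base.validate()
        _check(0.0 <= self.responder_fraction <= 1.0,
               "responder_fraction", "proportion out of [0, 1]")
        _check(self.responder_etr > 0, "responder_etr", "must be > 0")


@dataclass(frozen=True)
class TrajectorySpec:
    """Longitudinal ALSFRS-R decline: linear slope + noise, clipped to [floor, 48].

    ``slope_survival_coupling`` (rho in [0, 1]) ties the per-patient slope to
    the patient's survival percentile through a Gaussian copula: fast
    decliners die sooner, the defining link between progression rate and
    survival in ALS, while the marginal slope law stays
    N(slope_mean, slope_sd) and the survival law is untouched.
    """

    visit_months: Sequence[float] = tuple(range(0, 13))
    slope_mean: float = -0.9       # points/month
    slope_sd: float = 0.8
    floor: float = 0.0
    noise_sd: float = 1.5
    responder_slope_attenuation: float = 0.5
    attenuation_onset_month: float = 3.0
    slope_survival_coupling: float = 0.9
    slope_max: float = -0.05  # ALSFRS-R never improves systematically

    def validate(self) -> None:
        months = list(self.visit_months)
        _check(len(months) >= 1, "visit_months", "must be non-empty")
        _check(months[0] == 0, "visit_months", "first visit must be month 0")
        _check(all(b > a for a, b in zip(months, months[1:])),
               "visit_months", "must be strictly increasing")
        _check(0.0 <= self.floor <= 48.0, "floor", "must be in [0, 48]")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _check(0.0 < self.responder_slope_attenuation <= 1.0,
               "responder_slope_attenuation", "must be in (0, 1]")
        _check(self.attenuation_onset_month >= 0,
               "attenuation_onset_month", "must be >= 0")
        _check(0.0 <= self.slope_survival_coupling <= 1.0,
               "slope_survival_coupling", "must be in [0, 1]")


@dataclass(frozen=True)
class BiomarkerSpec:
    """Factor-model biomarker panel: values = L.(f + effect*flag) + noise.

    ``loading_matrix`` is variable x factor; ``responder_effect`` shifts the
    factor means of latent responders.  Ordinal variables are discretized by
    within-variable quantile bins (preserving the monotone relation to the
    latent factor); entries are then deleted completely at random.
    """

    var_names: Sequence[str]
    loading_matrix: np.ndarray  # (n_vars, n_factors)
    responder_effect: Sequence[float]
    noise_sd: float = 1.0
    ordinal_vars: Mapping[str, int] = field(default_factory=dict)
    missing_rate: float = 0.0
    timepoints: Sequence[float] = (3.0, 6.0, 12.0)
    seed: int = 0

    def validate(self) -> None:
        L = np.asarray(self.loading_matrix, dtype=float)
        _check(L.ndim == 2, "loading_matrix", "must be 2-D")
        _check(L.shape[0] == len(self.var_names),
               "loading_matrix", "row count must match var_names")
        _check(L.shape[1] == len(list(self.responder_effect)),
               "responder_effect", "length must match factor count")
        _check(not np.any(np.all(L == 0, axis=1)),
               "loading_matrix", "all-zero row makes a variable unidentifiable")
        _check(np.all(np.any(L != 0, axis=0)),
               "loading_matrix", "every factor needs >= 1 loading variable")
        _check(0.0 <= self.missing_rate < 1.0, "missing_rate", "must be in [0, 1)")
        for name, bins in self.ordinal_vars.items():
            _check(name in set(self.var_names), "ordinal_vars", f"unknown variable {name!r}")
            _check(bins >= 2, "ordinal_vars", f"{name}: bin count must be >= 2")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _draw_covariates(spec: CohortSpec, rng: np.random.Generator,
                     id_prefix: str) -> pd.DataFrame:
    n = spec.n_patients
    df = pd.DataFrame({
        "patient_id": [f"{id_prefix}{i:05d}" for i in range(n)],
        "cohort": spec.cohort_label,
        "age": rng.normal(spec.age_mean, spec.age_sd, n).clip(18.0, 95.0),
        "sex_female": (rng.random(n) < spec.frac_female).astype(int),
        "onset_bulbar": (rng.random(n) < spec.frac_bulbar).astype(int),
        "baseline_alsfrs": rng.normal(spec.baseline_alsfrs_mean,
                                      spec.baseline_alsfrs_sd, n).clip(0.0, 48.0),
        "latency_days": rng.normal(spec.latency_mean, spec.latency_sd, n).clip(30.0, None),
        "riluzole": (rng.random(n) < spec.riluzole_prob).astype(int),
    })
    return df


def _linear_predictor(df: pd.DataFrame, spec: CohortSpec) -> np.ndarray:
    """Centered log-hazard contribution of the covariates."""
    centers = {"age": spec.age_mean, "baseline_alsfrs": spec.baseline_alsfrs_mean,
               "latency_days": spec.latency_mean}
    lp = np.zeros(len(df))
    for name, beta in spec.log_hazard_betas.items():
        lp += beta * (df[name].to_numpy(float) - centers.get(name, 0.0))
    return lp


def _simulate(spec: CohortSpec | TreatedSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared generator core; returns ``(patient table, latent truth frame)``.

    The latent frame carries the responder flag and ``survival_z``, the
    normal score of the patient's *base* (pre-multiplier, pre-censoring)
    event-time percentile within their own exponential law.  It drives the
    slope-survival copula in :func:`generate_trajectories` and is never part
    of the patient table.
    """
    if isinstance(spec, TreatedSpec):
        treated, base = spec, spec.base
    else:
        treated, base = None, spec
    rng = np.random.default_rng(base.seed)
    prefix = "T" if treated is not None else base.cohort_label[:1].upper()
    df = _draw_covariates(base, rng, id_prefix=prefix)

    if treated is not None:
        from scipy.special import expit, logit
        if treated.responder_fraction in (0.0, 1.0):
            p_resp = np.full(len(df), treated.responder_fraction)
        else:
            eta = logit(treated.responder_fraction) + treated.age_interaction * (
                df["age"].to_numpy(float) - base.age_mean)
            p_resp = expit(eta)
        flags = rng.random(len(df)) < p_resp
        etr = treated.responder_etr
    else:
        flags = np.zeros(len(df), dtype=bool)
        etr = 1.0

    hazard = base.baseline_hazard * np.exp(_linear_predictor(df, base))
    t_base = np.maximum(rng.exponential(1.0 / hazard), 1e-6)
    t_event = np.where(flags, t_base * etr, t_base)
    df["survival_days"] = np.minimum(t_event, base.censor_window)
    df["event"] = (t_event <= base.censor_window).astype(int)

    u = 1.0 - np.exp(-hazard * t_base)  # exact uniform percentile of the base draw
    z = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    latent = pd.DataFrame({LATENT_FLAG_COLUMN: flags.astype(int),
                           "survival_z": z},
                          index=pd.Index(df["patient_id"], name="patient_id"))
    return df[PATIENT_COLUMNS], latent


def generate_control_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a historical-control patient table.

    Survival time is ``min(T, censor_window)`` with ``T`` exponential at
    hazard ``baseline_hazard * exp(lp)``; ``event`` is 1 exactly when the
    censoring horizon did not bind.
    """
    spec.validate()
    return _simulate(spec)[0]


def generate_treated_cohort(spec: TreatedSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a treated cohort; returns ``(table, latent_flags)``.

    The latent responder flags are returned *separately* from the patient
    table: downstream analysis stages must not join them (only the generator
    truth files and test code may).
    """
    spec.validate()
    df, latent = _simulate(spec)
    return df, latent[LATENT_FLAG_COLUMN]


def latent_truth(spec: CohortSpec | TreatedSpec) -> pd.DataFrame:
    """Regenerate the generator-truth frame for a spec (deterministic).

    Columns: ``latent_responder`` (0 for control cohorts) and
    ``survival_z``, the copula normal score behind the slope-survival link.
    Analysis stages must not consume this; the trajectory generator and
    test code may.
    """
    spec.validate()
    return _simulate(spec)[1]


def generate_trajectories(patients: pd.DataFrame, spec: TrajectorySpec,
                          responder_flags: pd.Series | None = None,
                          seed: int = 0,
                          survival_z: pd.Series | None = None) -> pd.DataFrame:
    """Longitudinal ALSFRS-R visits for every patient.

    Per patient: ``score(m) = clip(baseline + slope*m + noise, floor, 48)``
    at each visit month strictly before death/censoring.  Responder decline
    is multiplied by ``responder_slope_attenuation`` from
    ``attenuation_onset_month`` onward (shallower decline after an
    induction period).
    When ``survival_z`` (from :func:`latent_truth`) is given, slopes follow
    the Gaussian copula ``slope = mean + sd * (rho*z + sqrt(1-rho^2)*eps)``
    so that long survivors decline more slowly.
    """
    spec.validate()
    if "baseline_alsfrs" not in patients:
        raise SpecValidationError("patients: baseline_alsfrs column required")
    rng = np.random.default_rng(seed)
    months = np.asarray(list(spec.visit_months), dtype=float)

    eps = rng.normal(size=len(patients))
    if survival_z is not None and spec.slope_survival_coupling > 0:
        rho = spec.slope_survival_coupling
        z = patients["patient_id"].map(survival_z).fillna(0.0).to_numpy(float)
        zmix = rho * z + np.sqrt(1.0 - rho ** 2) * eps
    else:
        zmix = eps
    slopes = np.minimum(spec.slope_mean + spec.slope_sd * zmix, spec.slope_max)
    n = len(patients)
    if responder_flags is not None:
        is_resp = patients["patient_id"].map(responder_flags).fillna(0).to_numpy() > 0
    else:
        is_resp = np.zeros(n, dtype=bool)

    surv = patients["survival_days"].to_numpy(float)
    base = patients["baseline_alsfrs"].to_numpy(float)
    keep = np.less.outer(months * DAYS_PER_MONTH, surv)  # (n_months, n)
    noise = rng.normal(0.0, spec.noise_sd, size=(len(months), n)) \
        if spec.noise_sd > 0 else np.zeros((len(months), n))
    # responders decline at the full rate until the attenuation onset (the
    # treatment effect on progression needs an induction period), then at the
    # attenuated rate; non-responders decline linearly throughout
    pre = np.minimum(months, spec.attenuation_onset_month)[:, None]
    post = np.maximum(months - spec.attenuation_onset_month, 0.0)[:, None]
    atten = np.where(is_resp, spec.responder_slope_attenuation, 1.0)[None, :]
    eff_months = pre + atten * post
    scores = np.clip(base[None, :] + slopes[None, :] * eff_months + noise,
                     spec.floor, 48.0)
    midx, pidx = np.nonzero(keep)
    out = pd.DataFrame({
        "patient_id": patients["patient_id"].to_numpy()[pidx],
        "cohort": patients["cohort"].to_numpy()[pidx],
        "month": months[midx],
        "alsfrs": scores[midx, pidx],
    })
    return out.sort_values(["patient_id", "month"], kind="stable",
                           ignore_index=True)


def generate_biomarkers(patients: pd.DataFrame, spec: BiomarkerSpec,
                        responder_flags: pd.Series | None = None,
                        ) -> dict[float, pd.DataFrame]:
    """Wide biomarker panels, one patient-by-variable table per timepoint.

    Latent factor scores are drawn fresh at every timepoint; responder
    patients get a constant per-factor mean shift, so group structure is
    present at each visit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = np.asarray(spec.loading_matrix, dtype=float)
    n_vars, n_factors = L.shape
    effect = np.asarray(list(spec.responder_effect), dtype=float)
    ids = patients["patient_id"].to_numpy()
    n = len(ids)
    if responder_flags is not None:
        flag = patients["patient_id"].map(responder_flags).fillna(0).to_numpy(float)
    else:
        flag = np.zeros(n)

    panels: dict[float, pd.DataFrame] = {}
    for tp in spec.timepoints:
        factors = rng.normal(size=(n, n_factors)) + np.outer(flag, effect)
        values = factors @ L.T + rng.normal(0.0, spec.noise_sd, size=(n, n_vars))
        panel = pd.DataFrame(values, index=pd.Index(ids, name="patient_id"),
                             columns=list(spec.var_names))
        for name, bins in spec.ordinal_vars.items():
            col = panel[name]
            edges = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
            panel[name] = np.searchsorted(edges, col).astype(float)
        if spec.missing_rate > 0:
            mask = rng.random(size=panel.shape) < spec.missing_rate
            panel = panel.mask(mask)
        panels[float(tp)] = panel
    return panels


# ---------------------------------------------------------------------------
# default study scenario
# ---------------------------------------------------------------------------

def default_control_spec(n_patients: int = 2000, seed: int = 0) -> CohortSpec:
    """Historical-control cohort at the descriptors of the riluzole+placebo pool."""
    return CohortSpec(
        n_patients=n_patients, seed=seed,
        log_hazard_betas={"age": 0.02, "baseline_alsfrs": -0.05,
                          "onset_bulbar": 0.35, "latency_days": -0.0005,
                          "sex_female": -0.05},
    )


def default_treated_spec(n_patients: int = 36, seed: int = 1) -> TreatedSpec:
    """36-patient treated cohort: younger, later-treated, latent responders."""
    base = replace(default_control_spec(n_patients, seed),
                   age_mean=51.9, age_sd=10.5, frac_female=0.306,
                   frac_bulbar=8 / 36, baseline_alsfrs_mean=37.6,
                   latency_mean=595.0, cohort_label="treated")
    return TreatedSpec(base=base, responder_fraction=0.5, responder_etr=2.5,
                       age_interaction=-0.05)


def default_biomarker_specs(seed: int = 0) -> dict[str, BiomarkerSpec]:
    """Three biomarker packages: DTI imaging, cytokines, hematology/stem cells.

    Each package follows a 2-factor model; the first factor separates
    responders (imaging: preserved fractional anisotropy; cytokines: *less*
    inflammation, hence negative shift; hematology: stronger stem-cell
    mobilization).  Imaging is absent before month 12, mirroring typical
    scan-availability gaps.
    """
    rng = np.random.default_rng(seed)

    def loadings(n_vars: int, strong: float) -> np.ndarray:
        L = np.zeros((n_vars, 2))
        half = n_vars // 2
        L[:half, 0] = strong * rng.uniform(0.7, 1.0, half)
        L[half:, 1] = rng.uniform(0.5, 0.9, n_vars - half)
        return L

    fa_names = [f"fa_roi_{i:02d}" for i in range(24)]
    cyto_names = ["il6", "mcp1", "eotaxin", "tnf_beta", "mcp4", "il7",
                  "il8", "il10", "ifn_gamma", "vegf", "il1b", "il2",
                  "il4", "il12", "il13", "tnf_alpha"]
    heme_names = ["cd34_pos", "cd34_cd38_neg", "wbc", "monocytes",
                  "lymphocytes", "neutrophils", "platelets", "hemoglobin",
                  "hematocrit", "rbc", "basophils", "eosinophils"]
    return {
        "imaging": BiomarkerSpec(
            var_names=fa_names, loading_matrix=loadings(24, 0.9),
            responder_effect=(1.2, 0.0), noise_sd=0.8,
            missing_rate=0.10, timepoints=(12.0,), seed=seed * 3 + 11),
        "cytokines": BiomarkerSpec(
            var_names=cyto_names, loading_matrix=loadings(16, 1.0),
            responder_effect=(-1.5, 0.0), noise_sd=0.8,
            missing_rate=0.08, timepoints=(3.0, 6.0, 12.0), seed=seed * 3 + 12),
        "hematology": BiomarkerSpec(
            var_names=heme_names, loading_matrix=loadings(12, 0.9),
            responder_effect=(1.3, 0.0), noise_sd=0.8,
            ordinal_vars={"basophils": 4, "eosinophils": 5},
            missing_rate=0.08, timepoints=(3.0, 6.0, 12.0), seed=seed * 3 + 13),
    }
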