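"""End-to-end analysis pipeline with reproducible run manifests.

Stage order mirrors the analysis sequence: simulate -> survive -> match ->
decline -> respond -> signature.  Every artifact is a delimited text file
written with a content hash recorded in ``manifest.json``; identical config
and seeds give byte-identical artifacts.  The latent responder truth is
written to a separate ``truth_*`` file that no analysis stage reads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarkers as bm
from . import cohorts, matched, progression, responder, survival

STAGES = ("simulate", "survive", "match", "decline", "respond", "signature")


@dataclass
class RunConfig:
    """Single-file configuration mapping 1:1 to the generator/analysis knobs."""

    out_dir: str = "runs/default"
    seed: int = 0
    stages: tuple[str, ...] = STAGES

    # cohorts
    n_control: int = 2000
    n_treated: int = 36
    responder_fraction: float = 0.5
    responder_etr: float = 2.5
    age_interaction: float = -0.05
    censor_window: float = 1460.0

    # trajectories
    visit_months: tuple[float, ...] = tuple(float(m) for m in range(0, 13))
    slope_mean: float = -0.9
    slope_sd: float = 0.8
    traj_noise_sd: float = 1.5
    responder_slope_attenuation: float = 0.5

    # analysis knobs
    responder_threshold_days: float = 60.0
    treated_slope_window_months: float = 3.0
    slope_ceiling: float = -0.05
    loading_cutoff: float = 0.5
    alpha: float = 0.05
    tost_margin_sd: float = 0.5
    match_k: int = 10
    match_covariates: tuple[str, ...] = ("age", "baseline_alsfrs")
    bootstrap_draws: int = 200
    bootstrap_subsample: int = 9
    decline_month_window: float = 6.0
    eval_latency_months: float = 10.0
    roc_permutations: int = 2000
    signature_timepoints: tuple[float, ...] = (3.0, 6.0, 12.0)
    write_truth: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "visit_months", "match_covariates",
                    "signature_timepoints"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 16 + STAGES.index(stage)) % (2 ** 31 - 1)


class MissingUpstreamError(RuntimeError):
    pass


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(out: Path, filename: str, stage: str) -> Path:
    p = out / filename
    if not p.exists():
        raise MissingUpstreamError(
            f"missing artifact {filename!r}; enable stage {stage!r} first")
    return p


def _specs(cfg: RunConfig):
    ctrl = replace(cohorts.default_control_spec(cfg.n_control,
                                                seed=cfg.stage_seed("simulate")),
                   censor_window=cfg.censor_window)
    treated = cohorts.default_treated_spec(cfg.n_treated,
                                           seed=cfg.stage_seed("simulate") + 1)
    treated = replace(treated,
                      base=replace(treated.base, censor_window=cfg.censor_window),
                      responder_fraction=cfg.responder_fraction,
                      responder_etr=cfg.responder_etr,
                      age_interaction=cfg.age_interaction)
    traj = cohorts.TrajectorySpec(
        visit_months=cfg.visit_months, slope_mean=cfg.slope_mean,
        slope_sd=cfg.slope_sd, noise_sd=cfg.traj_noise_sd,
        responder_slope_attenuation=cfg.responder_slope_attenuation)
    return ctrl, treated, traj


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    ctrl_spec, treated_spec, traj_spec = _specs(cfg)
    ctrl = cohorts.generate_control_cohort(ctrl_spec)
    trt, flags = cohorts.generate_treated_cohort(treated_spec)
    lat_ctrl = cohorts.latent_truth(ctrl_spec)
    lat_trt = cohorts.latent_truth(treated_spec)
    v_ctrl = cohorts.generate_trajectories(ctrl, traj_spec, None,
                                           seed=cfg.stage_seed("simulate") + 2,
                                           survival_z=lat_ctrl["survival_z"])
    v_trt = cohorts.generate_trajectories(trt, traj_spec, flags,
                                          seed=cfg.stage_seed("simulate") + 3,
                                          survival_z=lat_trt["survival_z"])
    visits = pd.concat([v_ctrl, v_trt], ignore_index=True)

    files = []
    for name, df in (("control_patients.csv", ctrl),
                     ("treated_patients.csv", trt),
                     ("visits.csv", visits)):
        _write(df, out / name)
        files.append(out / name)

    bio_specs = cohorts.default_biomarker_specs(seed=cfg.stage_seed("simulate") + 4)
    rows = []
    for pkg, spec in sorted(bio_specs.items()):
        panels = cohorts.generate_biomarkers(trt, spec, flags)
        for month, panel in sorted(panels.items()):
            long = panel.reset_index().melt(id_vars="patient_id",
                                            var_name="variable",
                                            value_name="value")
            long.insert(1, "package", pkg)
            long.insert(2, "month", month)
            rows.append(long)
    biomarkers_long = pd.concat(rows, ignore_index=True)
    _write(biomarkers_long, out / "biomarkers.csv")
    files.append(out / "biomarkers.csv")

    if cfg.write_truth:
        truth = flags.rename_axis("patient_id").reset_index()
        _write(truth, out / "truth_latent_responder.csv")
        files.append(out / "truth_latent_responder.csv")
    return files


def _load_patients(out: Path, stage: str):
    ctrl = pd.read_csv(_require(out, "control_patients.csv", "simulate"))
    trt = pd.read_csv(_require(out, "treated_patients.csv", "simulate"))
    return ctrl, trt


def stage_survive(cfg: RunConfig, out: Path) -> list[Path]:
    ctrl, trt = _load_patients(out, "survive")
    both = pd.concat([ctrl, trt], ignore_index=True)
    both["treated"] = (both["cohort"] == "treated").astype(int)

    rows = []
    for label, df in (("control", ctrl), ("treated", trt)):
        km = survival.km_estimate(df["survival_days"], df["event"])
        rows.append({"cohort": label, "n": km.n,
                     "median_days": km.median,
                     "median_ci_low": km.median_ci[0],
                     "median_ci_high": km.median_ci[1]})
    km_summary = pd.DataFrame(rows)

    stat_lr, p_lr, _ = survival.logrank_test(both["survival_days"], both["event"],
                                             both["cohort"])
    stat_w, p_w, _ = survival.logrank_test(both["survival_days"], both["event"],
                                           both["cohort"], variant="wilcoxon")

    covs = ["treated", "age", "sex_female", "baseline_alsfrs",
            "onset_bulbar", "latency_days"]
    cox = survival.cox_fit(both, covs)
    par = survival.parametric_fit(both, covs)
    aft = survival.aft_fit(both, covs)

    def fit_frame(fit, model):
        f = pd.DataFrame({"model": model, "term": fit.coefficients.index,
                          "coef": fit.coefficients.values, "se": fit.se.values,
                          "wald_chisq": fit.wald_chisq.values, "p": fit.p.values})
        if fit.hazard_ratios is not None:
            f["hazard_ratio"] = fit.hazard_ratios.values
        if fit.event_time_ratios is not None:
            f["event_time_ratio"] = fit.event_time_ratios.values
        return f

    fits = pd.concat([fit_frame(cox, "cox"), fit_frame(par, "exponential_ph"),
                      fit_frame(aft, "weibull_aft")], ignore_index=True)
    tests = pd.DataFrame([
        {"test": "logrank", "statistic": stat_lr, "p": p_lr},
        {"test": "wilcoxon", "statistic": stat_w, "p": p_w},
    ])
    _write(km_summary, out / "km_summary.csv")
    _write(fits, out / "survival_fits.csv")
    _write(tests, out / "survival_tests.csv")
    return [out / "km_summary.csv", out / "survival_fits.csv",
            out / "survival_tests.csv"]


def stage_match(cfg: RunConfig, out: Path) -> list[Path]:
    ctrl, trt = _load_patients(out, "match")
    covs = list(cfg.match_covariates)
    sets = matched.match_controls(trt, ctrl, covariates=covs, k=cfg.match_k,
                                  seed=cfg.stage_seed("match"))
    set_rows = [{"treated_id": s.treated_id, "rank": r + 1,
                 "control_id": cid, "distance": d}
                for s in sets
                for r, (cid, d) in enumerate(zip(s.control_ids, s.distances))]
    sets_df = pd.DataFrame(set_rows)

    matched_ids = sets_df["control_id"].unique()
    msub = ctrl.set_index("patient_id").loc[matched_ids]
    tost_rows = []
    for c in covs:
        x = trt[c].to_numpy(float)
        y = msub[c].to_numpy(float)
        pooled_sd = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
        res = matched.tost_equivalence(x, y, margin=cfg.tost_margin_sd * pooled_sd)
        tost_rows.append({"covariate": c, "margin": res.margin,
                          "p_lower": res.p_lower, "p_upper": res.p_upper,
                          "equivalent": int(res.equivalent),
                          "degenerate": int(res.degenerate)})

    boot = matched.bootstrap_compare(sets, trt, ctrl, draws=cfg.bootstrap_draws,
                                     subsample=cfg.bootstrap_subsample,
                                     seed=cfg.stage_seed("match") + 1)
    per_draw = boot.per_draw
    if len(per_draw) > 1000:  # thin very large draw tables
        per_draw = per_draw.iloc[:: len(per_draw) // 1000 + 1]
    summary = pd.DataFrame([{
        "draws": boot.draws,
        "mean_of_medians_treated": boot.mean_of_medians_treated,
        "mean_of_medians_control": boot.mean_of_medians_control,
        "median_p": boot.median_p,
        "p_min": boot.p_range[0], "p_max": boot.p_range[1],
    }])
    _write(sets_df, out / "matched_sets.csv")
    _write(pd.DataFrame(tost_rows), out / "matched_tost.csv")
    _write(summary, out / "matched_bootstrap.csv")
    _write(per_draw, out / "matched_bootstrap_draws.csv")
    return [out / "matched_sets.csv", out / "matched_tost.csv",
            out / "matched_bootstrap.csv", out / "matched_bootstrap_draws.csv"]


def stage_decline(cfg: RunConfig, out: Path) -> list[Path]:
    ctrl, trt = _load_patients(out, "decline")
    visits = pd.read_csv(_require(out, "visits.csv", "simulate"))
    pats = pd.concat([ctrl, trt], ignore_index=True)
    fit = progression.fit_decline(visits, pats,
                                  month_window=cfg.decline_month_window)
    fit3 = progression.fit_decline_threeway(
        visits, pats, eval_latency_months=cfg.eval_latency_months,
        month_window=cfg.decline_month_window)

    def coef_frame(f, model):
        return pd.DataFrame({"model": model, "term": f.params.index,
                             "estimate": f.params.values, "se": f.se.values,
                             "p": f.pvalues.values})

    coefs = pd.concat([coef_frame(fit, "twoway"), coef_frame(fit3, "threeway")],
                      ignore_index=True)
    summary = pd.DataFrame([
        {"model": "twoway", "interaction_term": fit.interaction_term,
         "interaction_p": fit.interaction_p,
         "group_diff_at_eval":
             fit.group_difference(cfg.decline_month_window),
         "random_structure": fit.random_structure, "fallback": int(fit.fallback)},
        {"model": "threeway", "interaction_term": fit3.interaction_term,
         "interaction_p": fit3.interaction_p,
         "group_diff_at_eval":
             fit3.group_difference(cfg.decline_month_window,
                                   cfg.eval_latency_months),
         "random_structure": fit3.random_structure,
         "fallback": int(fit3.fallback)},
    ])
    _write(coefs, out / "decline_coefficients.csv")
    _write(summary, out / "decline_summary.csv")
    _write(fit.predicted, out / "decline_predicted.csv")
    return [out / "decline_coefficients.csv", out / "decline_summary.csv",
            out / "decline_predicted.csv"]


def stage_respond(cfg: RunConfig, out: Path) -> list[Path]:
    ctrl, trt = _load_patients(out, "respond")
    visits = pd.read_csv(_require(out, "visits.csv", "simulate"))

    ctrl_slopes = progression.slopes_by_patient(
        visits[visits["cohort"] == "control"])
    trt_slopes = progression.slopes_by_patient(
        visits[visits["cohort"] == "treated"],
        max_month=cfg.treated_slope_window_months)
    ctrl_m = ctrl.merge(ctrl_slopes, on="patient_id")
    trt_m = trt.merge(trt_slopes, on="patient_id")
    for frame in (ctrl_m, trt_m):
        frame["alsfrs_slope"] = responder.winsorize_slopes(
            frame["alsfrs_slope"], cfg.slope_ceiling)

    train = ctrl_m[(ctrl_m["event"] == 1)
                   & ctrl_m["alsfrs_slope"].notna()]
    model = responder.fit_survival_glm(train)

    coefs = pd.DataFrame({"term": model.coefficients.index,
                          "coef_per_day": model.coefficients.values,
                          "se": model.se.values})

    pred_ctrl = responder.predict_survival(model, ctrl_m)
    pred_trt = responder.predict_survival(model, trt_m)
    labels = responder.classify_response(trt_m, pred_trt,
                                         threshold=cfg.responder_threshold_days)
    wf = responder.waterfall(labels)
    _curves, stat, p = responder.response_survival_contrast(labels, trt_m)

    ctrl_resid = pd.DataFrame({
        "patient_id": ctrl_m["patient_id"],
        "predicted_days": pred_ctrl,
        "observed_days": ctrl_m["survival_days"],
        "residual_days": ctrl_m["survival_days"] - pred_ctrl})
    wstat, wp = responder.residual_group_test(
        labels.table["residual_days"], ctrl_resid["residual_days"].dropna())

    counts = labels.counts()
    summary = pd.DataFrame([{
        **{f"n_{k.replace('-', '_')}": v for k, v in counts.items()},
        "n_unpredictable": labels.n_unpredictable,
        "threshold_days": labels.threshold,
        "logrank_stat_responder_vs_non": stat,
        "logrank_p_responder_vs_non": p,
        "wilcoxon_stat_treated_vs_control_residuals": wstat,
        "wilcoxon_p_treated_vs_control_residuals": wp,
        "train_n": model.n_train,
        "mean_training_residual_days":
            float((train["survival_days"]
                   - responder.predict_survival(model, train)).mean()),
    }])
    _write(coefs, out / "responder_glm.csv")
    _write(labels.table, out / "responder_labels.csv")
    _write(wf, out / "responder_waterfall.csv")
    _write(ctrl_resid, out / "control_residuals.csv")
    _write(summary, out / "responder_summary.csv")
    return [out / "responder_glm.csv", out / "responder_labels.csv",
            out / "responder_waterfall.csv", out / "control_residuals.csv",
            out / "responder_summary.csv"]


def stage_signature(cfg: RunConfig, out: Path) -> list[Path]:
    labels_df = pd.read_csv(_require(out, "responder_labels.csv", "respond"))
    bio = pd.read_csv(_require(out, "biomarkers.csv", "simulate"))

    lab = labels_df.set_index("patient_id")["label"]
    binary = lab[lab.isin(["responder", "non-responder"])].map(
        {"responder": 1, "non-responder": 0})

    packages: dict[str, dict[float, pd.DataFrame]] = {}
    for (pkg, month), g in bio.groupby(["package", "month"]):
        wide = g.pivot(index="patient_id", columns="variable", values="value")
        packages.setdefault(pkg, {})[float(month)] = wide

    # cytokine AUC contrasts over the first 9 months (baseline = month 3 panel
    # is the earliest available; the generator emits no month-0 panel, so the
    # month-3 panel anchors the polyline)
    auc_rows = []
    cyto = packages.get("cytokines", {})
    months_avail = sorted(cyto)
    if len(months_avail) >= 2:
        base_month = months_avail[0]
        baseline = cyto[base_month]
        later = {m - base_month: cyto[m] for m in months_avail[1:]}
        areas = bm.auc_table(later, baseline, months=tuple(sorted(later)))
        for res in bm.auc_group_test(areas, binary):
            auc_rows.append({"variable": res.variable, "p": res.p,
                             "flagged": int(res.flagged)})
    auc_df = pd.DataFrame(auc_rows, columns=["variable", "p", "flagged"])

    sig_rows, pc_rows = [], []
    for tp in cfg.signature_timepoints:
        res = bm.evaluate_signature(
            packages, binary, timepoint=tp,
            loading_cutoff=cfg.loading_cutoff, alpha=cfg.alpha,
            n_permutations=cfg.roc_permutations,
            seed=cfg.stage_seed("signature") + int(tp))
        for name, p in sorted(res.pc_pvalues.items()):
            pc_rows.append({"timepoint": tp, "pc": name, "p": p,
                            "significant": int(p < cfg.alpha),
                            "n_retained_vars": len(res.retained.get(name, []))})
        sig_rows.append({
            "timepoint": tp,
            "n_significant_pcs": len(res.significant),
            "meta_pc_auc": res.roc.auc if res.roc else np.nan,
            "meta_pc_p": res.roc.p if res.roc else np.nan,
        })
    _write(auc_df, out / "signature_cytokine_auc.csv")
    _write(pd.DataFrame(pc_rows), out / "signature_pc_tests.csv")
    _write(pd.DataFrame(sig_rows), out / "signature_summary.csv")
    return [out / "signature_cytokine_auc.csv",
            out / "signature_pc_tests.csv", out / "signature_summary.csv"]


_STAGE_FUNCS = {"simulate": stage_simulate, "survive": stage_survive,
                "match": stage_match, "decline": stage_decline,
                "respond": stage_respond, "signature": stage_signature}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    unknown = set(cfg.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": {}}
    log_path = out / "run_log.jsonl"
    log_path.write_text("")
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        files = _STAGE_FUNCS[stage](cfg, out)
        entry = {
            "seed": cfg.stage_seed(stage),
            "artifacts": {f.name: _sha256(f) for f in files},
        }
        manifest["stages"][stage] = entry
        with log_path.open("a") as fh:
            fh.write(json.dumps({"stage": stage, **entry}, sort_keys=True)
                     + "\n")
    for key, val in manifest["config"].items():
        if isinstance(val, tuple):
            manifest["config"][key] = list(val)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def sensitivity_sweep(cfg: RunConfig, grid: dict[str, list]) -> pd.DataFrame:
    """One pipeline run per grid point (common seed); headline outputs tabulated.

    Grid keys must be RunConfig fields; each run lands in a subdirectory of
    ``cfg.out_dir``.  Headline columns: responder label counts, the decline
    interaction p, and the latest meta-PC AUC.
    """
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in grid:
        if key not in known:
            raise ValueError(f"unknown config key: {key!r}")
    if not grid:
        return pd.DataFrame()
    import itertools
    keys = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        overrides = dict(zip(keys, combo))
        sub = replace(cfg, **overrides,
                      out_dir=str(Path(cfg.out_dir) /
                                  ("sweep_" + "_".join(f"{k}={v}" for k, v in
                                                       overrides.items()))))
        run_pipeline(sub)
        outp = Path(sub.out_dir)
        row = dict(overrides)
        if (outp / "responder_summary.csv").exists():
            rs = pd.read_csv(outp / "responder_summary.csv").iloc[0]
            row.update(n_responder=int(rs["n_responder"]),
                       n_non_responder=int(rs["n_non_responder"]),
                       n_non_assignable=int(rs["n_non_assignable"]))
        if (outp / "decline_summary.csv").exists():
            ds = pd.read_csv(outp / "decline_summary.csv")
            row["decline_interaction_p"] = float(
                ds.loc[ds["model"] == "twoway", "interaction_p"].iloc[0])
        if (outp / "signature_summary.csv").exists():
            ss = pd.read_csv(outp / "signature_summary.csv")
            row["meta_pc_auc_last"] = float(ss["meta_pc_auc"].iloc[-1])
        rows.append(row)
    return pd.DataFrame(rows)
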