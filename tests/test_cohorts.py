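"""Synthetic-cohort generator: closed-form checks, determinism, validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from alsresponder import cohorts
from alsresponder.cohorts import (BiomarkerSpec, CohortSpec, SpecValidationError,
                                  TrajectorySpec, TreatedSpec)


def null_spec(n, seed=7, hazard=1 / 300):
    return CohortSpec(n_patients=n, seed=seed, baseline_hazard=hazard,
                      log_hazard_betas={}, censor_window=np.inf)


class TestControlCohort:
    def test_exponential_median_closed_form(self):
        # all betas zero -> plain exponential; median = ln2 / hazard
        df = cohorts.generate_control_cohort(null_spec(20_000))
        assert df["event"].all()
        med = df["survival_days"].median()
        assert med == pytest.approx(300 * np.log(2), rel=0.02)

    def test_determinism_same_seed(self):
        a = cohorts.generate_control_cohort(null_spec(500, seed=7))
        b = cohorts.generate_control_cohort(null_spec(500, seed=7))
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_invalid_proportion_rejected(self):
        spec = dataclasses.replace(null_spec(10), frac_bulbar=1.3)
        with pytest.raises(SpecValidationError, match="frac_bulbar"):
            cohorts.generate_control_cohort(spec)

    def test_censoring_flag_matches_window(self):
        spec = dataclasses.replace(null_spec(2000, seed=3), censor_window=200.0)
        df = cohorts.generate_control_cohort(spec)
        censored = df["event"] == 0
        assert np.all(df.loc[censored, "survival_days"] == 200.0)
        assert np.all(df.loc[~censored, "survival_days"] <= 200.0)
        assert (df["survival_days"] > 0).all()

    def test_covariates_shift_hazard(self):
        spec = dataclasses.replace(null_spec(20_000, seed=9),
                                   log_hazard_betas={"onset_bulbar": 1.0},
                                   frac_bulbar=0.5)
        df = cohorts.generate_control_cohort(spec)
        m_bulbar = df.loc[df.onset_bulbar == 1, "survival_days"].median()
        m_limb = df.loc[df.onset_bulbar == 0, "survival_days"].median()
        assert m_limb / m_bulbar == pytest.approx(np.e, rel=0.08)


class TestTreatedCohort:
    def test_subgroup_median_ratio_matches_etr(self):
        spec = TreatedSpec(base=null_spec(10_000, seed=21),
                           responder_fraction=0.5, responder_etr=2.5,
                           age_interaction=0.0)
        df, flags = cohorts.generate_treated_cohort(spec)
        joined = df.set_index("patient_id").join(flags)
        med_r = joined.loc[joined.latent_responder == 1, "survival_days"].median()
        med_n = joined.loc[joined.latent_responder == 0, "survival_days"].median()
        assert med_r / med_n == pytest.approx(2.5, rel=0.07)

    def test_zero_fraction_all_negative(self):
        spec = TreatedSpec(base=null_spec(200, seed=2), responder_fraction=0.0)
        _, flags = cohorts.generate_treated_cohort(spec)
        assert (flags == 0).all()

    def test_null_etr_matches_control_law(self):
        base = null_spec(5000, seed=5)
        spec = TreatedSpec(base=base, responder_fraction=0.5, responder_etr=1.0)
        trt, _ = cohorts.generate_treated_cohort(spec)
        ctrl = cohorts.generate_control_cohort(
            dataclasses.replace(base, seed=55))
        from scipy.stats import ks_2samp
        p = ks_2samp(trt["survival_days"], ctrl["survival_days"]).pvalue
        assert p > 1e-3  # same law; failure probability ~0.1% under the null

    def test_age_interaction_favors_young(self):
        spec = TreatedSpec(base=null_spec(20_000, seed=6),
                           responder_fraction=0.5, age_interaction=-0.08)
        df, flags = cohorts.generate_treated_cohort(spec)
        joined = df.set_index("patient_id").join(flags)
        young = joined.age < joined.age.median()
        assert joined.loc[young, "latent_responder"].mean() > \
            joined.loc[~young, "latent_responder"].mean() + 0.1


class TestTrajectories:
    def make_patients(self, n=4, baseline=40.0, surv=10_000.0):
        return pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)], "cohort": "control",
            "baseline_alsfrs": baseline, "survival_days": surv, "event": 1})

    def test_noise_free_line(self):
        spec = TrajectorySpec(visit_months=(0, 3, 6), slope_mean=-1.0,
                              slope_sd=0.0, noise_sd=0.0,
                              slope_survival_coupling=0.0)
        v = cohorts.generate_trajectories(self.make_patients(1), spec)
        assert v.loc[v.month == 6, "alsfrs"].iloc[0] == pytest.approx(34.0)

    def test_visits_truncated_at_death(self):
        spec = TrajectorySpec(visit_months=tuple(range(13)))
        pats = self.make_patients(1, surv=4 * cohorts.DAYS_PER_MONTH)
        v = cohorts.generate_trajectories(pats, spec)
        assert v["month"].max() == 3.0

    def test_attenuation_halves_group_slope(self):
        n = 2000
        pats = self.make_patients(n)
        flags = pd.Series(np.arange(n) % 2, index=pats["patient_id"])
        spec = TrajectorySpec(visit_months=(0, 2, 4, 6), slope_mean=-1.0,
                              slope_sd=0.0, noise_sd=0.5,
                              responder_slope_attenuation=0.5,
                              attenuation_onset_month=0.0,
                              slope_survival_coupling=0.0)
        v = cohorts.generate_trajectories(pats, spec, flags, seed=4)
        v["flag"] = v["patient_id"].map(flags)
        slopes = {}
        for f, g in v.groupby("flag"):  # pooled least-squares slope oracle
            slopes[f] = np.polyfit(g["month"], g["alsfrs"], 1)[0]
        assert slopes[0] / slopes[1] == pytest.approx(2.0, abs=0.05)

    def test_scores_bounded_and_before_death(self):
        spec = cohorts.default_control_spec(300, seed=8)
        pats = cohorts.generate_control_cohort(spec)
        v = cohorts.generate_trajectories(pats, TrajectorySpec(), seed=1)
        assert v["alsfrs"].between(0, 48).all()
        merged = v.merge(pats[["patient_id", "survival_days"]], on="patient_id")
        assert (merged["month"] * cohorts.DAYS_PER_MONTH
                < merged["survival_days"]).all()

    def test_empty_visit_months_rejected(self):
        with pytest.raises(SpecValidationError, match="visit_months"):
            cohorts.generate_trajectories(
                self.make_patients(1), TrajectorySpec(visit_months=()))

    def test_coupling_links_slope_to_survival(self):
        spec = cohorts.default_control_spec(2000, seed=13)
        pats = cohorts.generate_control_cohort(spec)
        z = cohorts.latent_truth(spec)["survival_z"]
        tspec = TrajectorySpec(noise_sd=0.0, slope_survival_coupling=0.8)
        v = cohorts.generate_trajectories(pats, tspec, seed=2, survival_z=z)
        slopes = v.groupby("patient_id").apply(
            lambda g: np.polyfit(g.month, g.alsfrs, 1)[0]
            if g.month.nunique() > 1 else np.nan, include_groups=False)
        joined = pd.DataFrame({"slope": slopes, "z": z}).dropna()
        r = np.corrcoef(joined.slope, joined.z)[0, 1]
        assert r > 0.5  # long survivors decline more slowly


class TestBiomarkers:
    def two_factor_spec(self, **kw):
        L = np.vstack([np.column_stack([np.ones(5), np.zeros(5)]),
                       np.column_stack([np.zeros(5), np.ones(5)])])
        defaults = dict(var_names=[f"v{i}" for i in range(10)],
                        loading_matrix=L, responder_effect=(0.0, 0.0),
                        noise_sd=0.5, timepoints=(3.0,), seed=3)
        defaults.update(kw)
        return BiomarkerSpec(**defaults)

    def patients(self, n):
        return pd.DataFrame({"patient_id": [f"B{i}" for i in range(n)]})

    def test_missing_fraction_concentrates(self):
        spec = self.two_factor_spec(missing_rate=0.10)
        panels = cohorts.generate_biomarkers(self.patients(36), spec)
        frac = panels[3.0].isna().to_numpy().mean()
        assert 0.05 <= frac <= 0.15

    def test_null_effect_centers_group_difference(self):
        spec = self.two_factor_spec()
        pats = self.patients(2000)
        flags = pd.Series(np.arange(2000) % 2, index=pats["patient_id"])
        panels = cohorts.generate_biomarkers(pats, spec, flags)
        p = panels[3.0]
        diffs = p[flags.values == 1].mean() - p[flags.values == 0].mean()
        assert np.abs(diffs).max() < 0.15

    def test_factor_covariance_oracle(self):
        spec = self.two_factor_spec(noise_sd=0.4)
        panels = cohorts.generate_biomarkers(self.patients(5000), spec)
        X = panels[3.0].to_numpy()
        S = np.cov(X, rowvar=False)
        L = np.asarray(spec.loading_matrix)
        expected = L @ L.T + 0.4 ** 2 * np.eye(10)
        assert np.abs(S - expected).max() < 0.1

    def test_all_zero_loading_row_rejected(self):
        L = np.vstack([np.zeros((1, 2)), np.ones((9, 2))])
        with pytest.raises(SpecValidationError, match="loading_matrix"):
            self.two_factor_spec(loading_matrix=L).validate()

    def test_ordinal_bins_and_determinism(self):
        spec = self.two_factor_spec(ordinal_vars={"v0": 4})
        a = cohorts.generate_biomarkers(self.patients(50), spec)
        b = cohorts.generate_biomarkers(self.patients(50), spec)
        assert a[3.0].equals(b[3.0])
        assert set(a[3.0]["v0"].dropna().unique()) <= {0.0, 1.0, 2.0, 3.0}
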