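"""Cytokine AUC, NLPCA, loading thresholds, meta-PC, and ROC evaluation."""

import numpy as np
import pandas as pd
import pytest

from alsresponder import biomarkers as bm
from alsresponder import cohorts


class TestCytokineAUC:
    def test_flat_series_zero(self):
        assert bm.cytokine_auc(10.0, {3: 10.0, 6: 10.0, 9: 10.0}) == 0.0

    def test_constant_elevation_trapezoids(self):
        # segments [0,3], [3,6], [6,9] with heights 0->10, 10, 10
        assert bm.cytokine_auc(10.0, {3: 20.0, 6: 20.0, 9: 20.0}) == \
            pytest.approx(15 + 30 + 30)

    def test_missing_midpoint_bridged(self):
        assert bm.cytokine_auc(10.0, {3: 20.0, 6: np.nan, 9: 20.0}) == \
            pytest.approx(15 + 60)

    def test_all_followups_missing_undefined(self):
        assert np.isnan(bm.cytokine_auc(10.0, {3: np.nan, 9: np.nan}))

    def test_matches_trapezoid_oracle_on_random_series(self, rng):
        for _ in range(300):
            base = rng.uniform(1, 30)
            vals = {m: (rng.uniform(0, 40) if rng.random() > 0.25 else np.nan)
                    for m in (3.0, 6.0, 9.0)}
            got = bm.cytokine_auc(base, vals)
            xs = [0.0] + [m for m in sorted(vals) if np.isfinite(vals[m])]
            ys = [0.0] + [vals[m] - base for m in sorted(vals)
                          if np.isfinite(vals[m])]
            expected = np.trapezoid(ys, xs) if len(xs) > 1 else np.nan
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, rel=1e-12)

    def test_linearity_invariants(self, rng):
        base = 12.0
        vals = {3: 20.0, 6: 17.0, 9: 25.0}
        a = bm.cytokine_auc(base, vals)
        scaled = bm.cytokine_auc(3 * base, {m: 3 * v for m, v in vals.items()})
        shifted = bm.cytokine_auc(base + 5, {m: v + 5 for m, v in vals.items()})
        assert scaled == pytest.approx(3 * a)
        assert shifted == pytest.approx(a)


class TestAUCGroupTest:
    def test_extreme_separation(self, rng):
        areas = pd.DataFrame({"il6": np.r_[np.zeros(10), 50 + rng.random(10)]},
                             index=[f"p{i}" for i in range(20)])
        labels = pd.Series(np.r_[np.zeros(10), np.ones(10)], index=areas.index)
        res = bm.auc_group_test(areas, labels)
        assert res[0].p < 0.01 and res[0].flagged

    def test_degenerate_variable_skipped(self):
        areas = pd.DataFrame({"flat": np.ones(10)},
                             index=[f"p{i}" for i in range(10)])
        labels = pd.Series([0] * 5 + [1] * 5, index=areas.index)
        assert bm.auc_group_test(areas, labels) == []

    def test_recovers_truly_shifted_variables(self):
        hits = 0
        for seed in range(25):
            r = np.random.default_rng(seed)
            n = 30
            labels = pd.Series(np.r_[np.zeros(15), np.ones(15)],
                               index=[f"p{i}" for i in range(n)])
            shifted = {"a", "b"}
            areas = {}
            for var in ("a", "b", "c", "d", "e", "f"):
                x = r.normal(0, 1, n)
                if var in shifted:
                    x[labels == 0] += 1.5
                areas[var] = x
            res = bm.auc_group_test(pd.DataFrame(areas, index=labels.index),
                                    labels)
            flagged = {r_.variable for r_ in res if r_.flagged}
            hits += shifted <= flagged
        assert hits >= 20  # flagged set covers the truly shifted set


class TestNLPCA:
    def test_equals_classical_pca_complete_scalar(self, rng):
        X = rng.normal(size=(80, 3)) @ rng.normal(size=(3, 9)) \
            + 0.4 * rng.normal(size=(80, 9))
        panel = pd.DataFrame(X, index=[f"p{i}" for i in range(80)])
        pcs = bm.nlpca_fit(panel, n_components=3)
        C = np.corrcoef(X, rowvar=False)
        w, v = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        for k, pc in enumerate(pcs):
            classical = v[:, order[k]] * np.sqrt(w[order[k]])
            mine = pc.loadings.to_numpy()
            cong = abs(classical @ mine) / np.linalg.norm(classical) \
                / np.linalg.norm(mine)
            assert cong > 0.999
            assert pc.vaf == pytest.approx(100 * w[order[k]] / 9, abs=0.01)

    def test_scores_normalized_and_orthogonal(self, rng):
        X = rng.normal(size=(60, 8))
        pcs = bm.nlpca_fit(pd.DataFrame(X), n_components=3)
        S = np.column_stack([pc.scores for pc in pcs])
        assert np.allclose(S.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(S.std(axis=0), 1, atol=1e-9)
        off = S.T @ S / len(S) - np.eye(3)
        assert np.abs(off).max() < 1e-8

    def test_constant_column_dropped_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        Xc = X.copy()
        Xc["flat"] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            pcs_c = bm.nlpca_fit(Xc, n_components=2)
        pcs = bm.nlpca_fit(X, n_components=2)
        np.testing.assert_allclose(pcs_c[0].loadings.to_numpy()[:6],
                                   pcs[0].loadings.to_numpy(), atol=1e-10)

    def test_two_factor_recovery_with_missing(self):
        # Tucker congruence after Procrustes alignment to the generating
        # loadings (the standard factor-recovery comparison)
        L = np.vstack([np.column_stack([np.full(10, 1.5), np.zeros(10)]),
                       np.column_stack([np.zeros(10), np.full(10, 0.8)])])
        spec = cohorts.BiomarkerSpec(
            var_names=[f"v{i}" for i in range(20)], loading_matrix=L,
            responder_effect=(0.0, 0.0), noise_sd=0.5, missing_rate=0.10,
            timepoints=(3.0,), seed=6)
        pats = pd.DataFrame({"patient_id": [f"q{i}" for i in range(200)]})
        panel = cohorts.generate_biomarkers(pats, spec)[3.0]
        pcs = bm.nlpca_fit(panel, n_components=2)
        A = np.column_stack([pc.loadings.to_numpy() for pc in pcs])
        U, _, Vt = np.linalg.svd(A.T @ L)
        Ar = A @ (U @ Vt)
        for j in range(2):
            phi = abs(Ar[:, j] @ L[:, j]) / np.linalg.norm(Ar[:, j]) \
                / np.linalg.norm(L[:, j])
            assert phi > 0.9

    def test_ordinal_variables_handled(self, rng):
        f = rng.normal(size=(120, 1))
        X = pd.DataFrame(f @ rng.uniform(0.7, 1.0, (1, 6)) +
                         0.5 * rng.normal(size=(120, 6)))
        X[0] = pd.cut(X[0], bins=4, labels=False).astype(float)
        pcs = bm.nlpca_fit(X, var_types={0: "ordinal"}, n_components=2)
        assert abs(pcs[0].loadings[0]) > 0.5  # ordinal var still loads

    def test_vaf_non_increasing(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 10)))
        pcs = bm.nlpca_fit(X, n_components=4)
        vafs = [pc.vaf for pc in pcs]
        assert all(a >= b - 1e-9 for a, b in zip(vafs, vafs[1:]))
        assert sum(vafs) <= 100.0 + 1e-9


class TestThresholdLoadings:
    def test_strictly_over_cutoff(self):
        pc = bm.PCResult(component=1,
                         loadings=pd.Series({"a": 0.6, "b": -0.7, "c": 0.4,
                                             "d": 0.5}),
                         scores=pd.Series(dtype=float), vaf=10.0)
        assert bm.threshold_loadings(pc, 0.5) == ["a", "b"]  # 0.5 excluded

    def test_zero_cutoff_keeps_all_nonzero(self):
        pc = bm.PCResult(component=1,
                         loadings=pd.Series({"a": 0.1, "b": 0.0}),
                         scores=pd.Series(dtype=float), vaf=5.0)
        assert bm.threshold_loadings(pc, 0.0) == ["a"]

    def test_invalid_cutoff(self):
        pc = bm.PCResult(component=1, loadings=pd.Series({"a": 0.6}),
                         scores=pd.Series(dtype=float), vaf=5.0)
        with pytest.raises(ValueError):
            bm.threshold_loadings(pc, 1.0)


class TestGroupTestsAndMeta:
    def test_single_timepoint_equals_t_test(self, rng):
        from scipy import stats
        ids = [f"p{i}" for i in range(30)]
        scores = pd.DataFrame({"patient_id": ids, "month": 3.0,
                               "score": rng.normal(0, 1, 30)})
        labels = pd.Series([0] * 15 + [1] * 15, index=ids)
        p = bm.pc_group_test(scores, labels)
        x = scores["score"][:15]
        y = scores["score"][15:]
        assert p == pytest.approx(stats.ttest_ind(x, y).pvalue, rel=1e-9)

    def test_group_shift_detected_across_timepoints(self):
        detected = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            ids = [f"p{i}" for i in range(30)]
            labels = pd.Series([0] * 15 + [1] * 15, index=ids)
            rows = []
            for m in (3.0, 6.0, 12.0):
                rows.append(pd.DataFrame({
                    "patient_id": ids, "month": m,
                    "score": r.normal(0, 1, 30) + 1.5 * labels.values}))
            p = bm.pc_group_test(pd.concat(rows), labels)
            detected += p < 0.05
        assert detected >= 18

    def test_meta_single_pc_is_that_pc(self, rng):
        ids = [f"p{i}" for i in range(20)]
        s = pd.Series(rng.normal(0, 1, 20), index=ids)
        labels = pd.Series((s > 0).astype(int), index=ids)
        meta = bm.build_meta_pc({"pkg_PC1": s}, labels)
        r = np.corrcoef(meta.scores, s)[0, 1]
        assert abs(r) > 0.999999

    def test_meta_two_correlated_pcs(self, rng):
        ids = [f"p{i}" for i in range(20)]
        s = pd.Series(rng.normal(0, 1, 20), index=ids)
        labels = pd.Series((s > 0).astype(int), index=ids)
        meta = bm.build_meta_pc({"a": s, "b": 2 * s + 1}, labels)
        assert abs(np.corrcoef(meta.scores, s)[0, 1]) > 0.999999

    def test_meta_oriented_toward_responders(self, rng):
        ids = [f"p{i}" for i in range(30)]
        s = pd.Series(rng.normal(0, 1, 30), index=ids)
        labels = pd.Series((s < 0).astype(int), index=ids)  # anti-aligned
        meta = bm.build_meta_pc({"a": s}, labels)
        assert meta.scores[labels == 1].mean() > meta.scores[labels == 0].mean()

    def test_empty_signature_not_exception(self):
        meta = bm.build_meta_pc({}, pd.Series(dtype=float))
        assert meta.empty and len(meta.scores) == 0

    def test_meta_separation_at_least_best_single_pc(self):
        wins = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            ids = [f"p{i}" for i in range(30)]
            labels = pd.Series([0] * 15 + [1] * 15, index=ids)
            pcs = {}
            for k in range(3):
                pcs[f"pc{k}"] = pd.Series(
                    r.normal(0, 1, 30) + 1.0 * labels.values, index=ids)
            meta = bm.build_meta_pc(pcs, labels)

            def smd(s):
                a, b = s[labels == 1], s[labels == 0]
                return abs(a.mean() - b.mean()) / np.sqrt(
                    (a.var(ddof=1) + b.var(ddof=1)) / 2)

            wins += smd(meta.scores) >= max(smd(s) for s in pcs.values())
        assert wins >= 21  # aggregation beats the best single PC usually


class TestROC:
    def test_perfect_separation(self):
        ids = [f"p{i}" for i in range(20)]
        s = pd.Series(np.r_[np.zeros(10), np.ones(10)], index=ids)
        y = pd.Series(np.r_[np.zeros(10), np.ones(10)], index=ids)
        assert bm.roc_evaluate(s, y, n_permutations=200).auc == 1.0

    def test_constant_scores_half(self):
        ids = [f"p{i}" for i in range(20)]
        s = pd.Series(np.ones(20), index=ids)
        y = pd.Series(np.r_[np.zeros(10), np.ones(10)], index=ids)
        assert bm.roc_evaluate(s, y, n_permutations=100).auc == 0.5

    def test_matches_sklearn_rank_oracle(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(100):
            n = int(rng.integers(10, 40))
            s = pd.Series(rng.normal(0, 1, n))
            y = pd.Series(rng.integers(0, 2, n))
            if y.nunique() < 2:
                continue
            got = bm.roc_evaluate(s, y, n_permutations=1).auc
            assert got == pytest.approx(roc_auc_score(y, s), rel=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        ids = list(range(30))
        s = pd.Series(rng.normal(0, 1, 30), index=ids)
        y = pd.Series(rng.integers(0, 2, 30), index=ids)
        if y.nunique() < 2:
            y.iloc[0] = 1 - y.iloc[0]
        a1 = bm.roc_evaluate(s, y, n_permutations=1).auc
        a2 = bm.roc_evaluate(np.exp(3 * s), y, n_permutations=1).auc
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_single_class_rejected(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            bm.roc_evaluate(s, pd.Series([1, 1], index=["a", "b"]), 10)


class TestSignatureStage:
    def test_top_vaf_selection_keeps_one_pc_per_package(self, rng):
        from collections import Counter
        f = rng.normal(size=(36, 2))
        L = np.vstack([np.column_stack([np.full(6, 1.4), np.zeros(6)]),
                       np.column_stack([np.zeros(6), np.full(6, 1.0)])])
        flags = pd.Series(np.arange(36) % 2,
                          index=[f"p{i}" for i in range(36)]).astype(float)
        X = (f + np.column_stack([flags, flags])) @ L.T \
            + 0.5 * rng.normal(size=(36, 12))
        panel = pd.DataFrame(X, index=flags.index)
        packages = {"cytokines": {3.0: panel}}
        res = bm.evaluate_signature(packages, flags, timepoint=3.0,
                                    n_permutations=50,
                                    pc_selection="top_vaf")
        counts = Counter(name.rsplit("_PC", 1)[0]
                         for name in res.meta.contributing)
        assert all(v == 1 for v in counts.values())

    def test_absent_package_at_timepoint_tolerated(self, rng):
        panel = pd.DataFrame(rng.normal(size=(30, 8)),
                             index=[f"p{i}" for i in range(30)])
        labels = pd.Series([0] * 15 + [1] * 15, index=panel.index).astype(float)
        packages = {"cytokines": {6.0: panel}}  # nothing at month 3
        res = bm.evaluate_signature(packages, labels, timepoint=3.0,
                                    n_permutations=50)
        assert res.meta.empty and res.roc is None
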