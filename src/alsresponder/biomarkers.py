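"""Multimodal biomarker signature of treatment response.

Stages: baseline-anchored cytokine AUC contrasts between responder groups,
non-linear principal component analysis (NLPCA) per biomarker package,
absolute-loading thresholding, PC-score group tests, a meta-PC built from
the significant PCs, and ROC evaluation of early response prediction.

NLPCA here is optimal-scaling alternating least squares: scalar variables
are standardized; ordinal variables are replaced by monotone quantifications
(isotonic regression against the current low-rank reconstruction) updated
every cycle; missing entries start at the variable mean and are re-imputed
from the current rank-r reconstruction each cycle.  In the complete,
all-scalar limit the procedure reduces exactly to classical PCA of the
correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AUCResult:
    variable: str
    areas: pd.Series          # per-patient signed concentration*months
    p: float
    flagged: bool             # p < 0.1 reporting flag


@dataclass
class PCResult:
    component: int            # 1-based
    loadings: pd.Series       # correlation of each variable with the score
    scores: pd.Series         # per-patient, normalized (mean 0, SD 1)
    vaf: float                # variance accounted for, percent
    retained: list[str] | None = None
    converged: bool = True
    n_iter: int = 0


@dataclass
class MetaPC:
    contributing: list[str]
    scores: pd.Series
    empty: bool = False


@dataclass
class ROCResult:
    auc: float
    p: float
    n_permutations: int
    curve: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# cytokine AUC
# ---------------------------------------------------------------------------

def cytokine_auc(baseline: float, followups: dict[float, float]) -> float:
    """Signed area between the biomarker polyline and its baseline level.

    The polyline runs from (0, baseline) through the available follow-up
    points (months 3/6/9 by convention); missing intermediate timepoints are
    bridged by connecting the available neighbors.  Units:
    concentration x months.  NaN when every follow-up is missing.
    """
    pts = [(0.0, float(baseline))]
    for m in sorted(followups):
        v = followups[m]
        if v is not None and np.isfinite(v):
            pts.append((float(m), float(v)))
    if len(pts) < 2:
        return np.nan
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts]) - float(baseline)
    return float(np.trapezoid(y, x))


def auc_table(panels: dict[float, pd.DataFrame], baseline: pd.DataFrame,
              months=(3.0, 6.0, 9.0)) -> pd.DataFrame:
    """Per-patient, per-variable cytokine AUC over the stated months."""
    variables = list(baseline.columns)
    out = {}
    for var in variables:
        areas = {}
        for pid in baseline.index:
            b = baseline.loc[pid, var]
            if not np.isfinite(b):
                areas[pid] = np.nan
                continue
            fu = {m: panels[m].loc[pid, var]
                  for m in months if m in panels and pid in panels[m].index}
            areas[pid] = cytokine_auc(b, fu)
        out[var] = pd.Series(areas)
    return pd.DataFrame(out)


def auc_group_test(areas: pd.DataFrame, labels: pd.Series,
                   test: str = "ranksum", flag_at: float = 0.1) -> list[AUCResult]:
    """Rank-sum (or t-test) comparison of per-patient areas between groups.

    Variables whose groups have fewer than two defined areas are skipped.
    Results are flagged at ``p < flag_at`` for reporting.
    """
    groups = labels.dropna().unique()
    if len(groups) != 2:
        raise ValueError("auc_group_test needs exactly two groups")
    results = []
    lab = labels.reindex(areas.index)
    for var in areas.columns:
        a = areas[var]
        x = a[lab == groups[0]].dropna()
        y = a[lab == groups[1]].dropna()
        if len(x) < 2 or len(y) < 2 or (np.ptp(x) == 0 and np.ptp(y) == 0):
            continue
        if test == "ranksum":
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        elif test == "ttest":
            p = float(stats.ttest_ind(x, y).pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        results.append(AUCResult(variable=var, areas=a, p=p, flagged=p < flag_at))
    return results


# ---------------------------------------------------------------------------
# NLPCA
# ---------------------------------------------------------------------------

def _isotonic_quantify(codes: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Monotone optimal scaling: isotonic category means fitted to ``target``."""
    cats = np.unique(codes)
    means = np.array([target[codes == c].mean() for c in cats])
    weights = np.array([(codes == c).sum() for c in cats], dtype=float)
    # pool-adjacent-violators on the category means
    vals = means.copy()
    w = weights.copy()
    blocks = [[i] for i in range(len(vals))]
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1]:
            merged = (vals[i] * w[i] + vals[i + 1] * w[i + 1]) / (w[i] + w[i + 1])
            vals[i] = merged
            w[i] += w[i + 1]
            blocks[i] += blocks[i + 1]
            del_idx = i + 1
            vals = np.delete(vals, del_idx)
            w = np.delete(w, del_idx)
            del blocks[del_idx]
            i = max(i - 1, 0)
        else:
            i += 1
    quant = np.empty(len(cats))
    for bval, block in zip(vals, blocks):
        for idx in block:
            quant[idx] = bval
    lookup = dict(zip(cats, quant))
    return np.array([lookup[c] for c in codes])


def nlpca_fit(panel: pd.DataFrame, var_types: dict[str, str] | None = None,
              n_components: int = 3, max_iter: int = 500,
              tol: float = 1e-6) -> list[PCResult]:
    """Optimal-scaling alternating-least-squares PCA with missing data.

    ``var_types`` maps variable name to ``'scalar'`` or ``'ordinal'``
    (default scalar).  Constant variables are dropped with a warning.
    Component signs are oriented so each PC's largest-|loading| variable
    loads positive.  Scores are normalized to mean 0, SD 1; VAF is the mean
    squared loading in percent.
    """
    X = panel.copy().astype(float)
    keep = [c for c in X.columns if X[c].dropna().nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping constant variable(s): {dropped}")
    X = X[keep]
    n, p = X.shape
    if p < 3 or n < 5:
        raise ValueError("nlpca_fit needs >= 3 variables and >= 5 patients")
    if not (0 < n_components < min(n, p)):
        raise ValueError("n_components must be in (0, min(n_patients, n_vars))")
    var_types = var_types or {}
    ordinals = [c for c in keep if var_types.get(c, "scalar") == "ordinal"]

    raw = X.to_numpy()
    observed = np.isfinite(raw)
    codes = {c: raw[:, j] for j, c in enumerate(keep) if c in ordinals}

    def standardize(M):
        mu = np.nanmean(M, axis=0)
        sd = np.nanstd(M, axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return (M - mu) / sd

    Z = standardize(raw)
    Z = np.where(observed, Z, 0.0)  # mean start for missing entries

    err_prev = np.inf
    converged = False
    for it in range(max_iter):
        Zc = Z - Z.mean(axis=0)
        U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
        recon = U[:, :n_components] * S[:n_components] @ Vt[:n_components] \
            + Z.mean(axis=0)
        # impute missing entries from the current low-rank reconstruction
        Z = np.where(observed, Z, recon)
        # monotone re-quantification of ordinal variables
        for j, c in enumerate(keep):
            if c in ordinals:
                obs_j = observed[:, j]
                q = _isotonic_quantify(codes[c][obs_j], recon[obs_j, j])
                Z[obs_j, j] = q
        # restandardize all columns
        Z = standardize(Z)
        err = float(np.mean((Z - recon) ** 2))
        if abs(err_prev - err) < tol:
            converged = True
            break
        err_prev = err

    Zc = Z - Z.mean(axis=0)
    U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    sd_cols = Zc.std(axis=0)
    results = []
    for k in range(n_components):
        score = U[:, k]
        score = (score - score.mean()) / score.std()
        load = (Zc.T @ score) / (n * sd_cols)
        jmax = int(np.argmax(np.abs(load)))
        if load[jmax] < 0:
            load, score = -load, -score
        results.append(PCResult(
            component=k + 1,
            loadings=pd.Series(load, index=keep),
            scores=pd.Series(score, index=X.index),
            vaf=float(np.mean(load ** 2) * 100.0),
            converged=converged, n_iter=it + 1))
    return results


def threshold_loadings(pc: PCResult, cutoff: float = 0.5) -> list[str]:
    """Variables with |loading| strictly greater than ``cutoff`` (sign kept)."""
    if not (0.0 <= cutoff < 1.0):
        raise ValueError("cutoff must be in [0, 1)")
    retained = [v for v, l in pc.loadings.items() if abs(l) > cutoff]
    pc.retained = retained
    return retained


# ---------------------------------------------------------------------------
# group tests, meta-PC, ROC
# ---------------------------------------------------------------------------

def pc_group_test(scores: pd.DataFrame, labels: pd.Series) -> float:
    """Responder-group test of PC scores, mixed model across timepoints.

    ``scores`` is long format with columns patient_id, month, score.  With
    several timepoints a linear mixed model (random patient intercept) tests
    the group effect; a single timepoint degrades to the equal-variance
    two-sample t-test (the LMM's degenerate case).
    """
    data = scores.copy()
    data["group"] = data["patient_id"].map(labels)
    data = data.dropna(subset=["group", "score"])
    glabels = sorted(pd.unique(data["group"]))
    if len(glabels) != 2:
        raise ValueError("pc_group_test needs exactly two groups")
    data["g"] = (data["group"] == glabels[1]).astype(float)
    if data["month"].nunique() <= 1:
        x = data.loc[data["g"] == 0, "score"]
        y = data.loc[data["g"] == 1, "score"]
        return float(stats.ttest_ind(x, y, equal_var=True).pvalue)
    import statsmodels.api as sm
    exog = np.column_stack([np.ones(len(data)), data["g"].to_numpy()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MixedLM(data["score"].to_numpy(), exog,
                         groups=data["patient_id"]).fit(reml=True)
    z = res.fe_params[1] / res.bse_fe[1]
    return float(2 * stats.norm.sf(abs(z)))


def build_meta_pc(pc_scores: dict[str, pd.Series],
                  labels: pd.Series) -> MetaPC:
    """First principal component of the patient x significant-PC score matrix.

    Missing scores are mean-imputed (logged via the returned table's NaN
    count upstream).  The sign is oriented so the responder group has the
    higher mean meta score.  Zero input PCs give an explicit empty result.
    """
    if len(pc_scores) == 0:
        return MetaPC(contributing=[], scores=pd.Series(dtype=float), empty=True)
    M = pd.DataFrame(pc_scores)
    filled = M.apply(lambda c: c.fillna(c.mean()))
    Z = (filled - filled.mean()) / filled.std().replace(0.0, 1.0)
    U, S, Vt = np.linalg.svd(Z.to_numpy() - Z.to_numpy().mean(axis=0),
                             full_matrices=False)
    meta = pd.Series(U[:, 0], index=M.index)
    meta = (meta - meta.mean()) / meta.std()
    lab = labels.reindex(M.index)
    resp = meta[lab == 1] if (lab == 1).any() else meta[lab == lab.max()]
    nonresp = meta[lab == 0] if (lab == 0).any() else meta[lab == lab.min()]
    if len(resp) and len(nonresp) and resp.mean() < nonresp.mean():
        meta = -meta
    return MetaPC(contributing=list(M.columns), scores=meta)


def roc_evaluate(scores: pd.Series, labels: pd.Series,
                 n_permutations: int = 10000, seed: int = 0,
                 with_curve: bool = False) -> ROCResult:
    """ROC AUC by the rank (Mann-Whitney) formulation + permutation p-value.

    AUC = U / (n1 * n0) with midranks for ties; the p-value is the
    one-sided label-permutation probability of an AUC at least as large.
    """
    s = scores.to_numpy(float)
    y = labels.reindex(scores.index).to_numpy(float)
    ok = np.isfinite(s) & np.isfinite(y)
    s, y = s[ok], y[ok]
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_evaluate needs both classes present")

    def auc_of(yv):
        r = stats.rankdata(s)
        u = r[yv == 1].sum() - n1 * (n1 + 1) / 2
        return u / (n1 * n0)

    auc = float(auc_of(y))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        exceed += auc_of(rng.permutation(y)) >= auc
    p = (1 + exceed) / (1 + n_permutations)

    curve = None
    if with_curve:
        order = np.argsort(-s, kind="stable")
        tp = np.cumsum(y[order] == 1) / n1
        fp = np.cumsum(y[order] == 0) / n0
        curve = pd.DataFrame({"fpr": np.r_[0.0, fp], "tpr": np.r_[0.0, tp]})
    return ROCResult(auc=auc, p=float(p), n_permutations=n_permutations,
                     curve=curve)


# ---------------------------------------------------------------------------
# full signature stage
# ---------------------------------------------------------------------------

@dataclass
class SignatureResult:
    timepoint: float
    pc_pvalues: dict[str, float]
    significant: list[str]
    meta: MetaPC
    roc: ROCResult | None
    retained: dict[str, list[str]] = field(default_factory=dict)


def evaluate_signature(packages: dict[str, dict[float, pd.DataFrame]],
                       labels: pd.Series, timepoint: float,
                       var_types: dict[str, str] | None = None,
                       n_components: int = 3, alpha: float = 0.05,
                       loading_cutoff: float = 0.5,
                       n_permutations: int = 2000,
                       seed: int = 0,
                       pc_selection: str = "significant") -> SignatureResult:
    """One evaluation window of the signature pipeline across packages.

    For each package, every panel measured at months up to ``timepoint`` is
    stacked (rows = patient visits) and analyzed by one NLPCA, so later
    windows accumulate repeated measures.  After loading thresholding, each
    PC's scores are tested for a responder-group difference with a linear
    mixed model across the repeated timepoints (two-sample test when only a
    single month is available).  PCs significant at ``alpha`` feed the
    meta-PC — built from per-patient mean scores — whose ROC against the
    responder labels is returned.  Packages with no data inside the window
    are tolerated and skipped.

    ``pc_selection`` chooses which PCs feed the meta-PC: ``"significant"``
    (every significant PC) or ``"top_vaf"`` (per package, only the
    highest-variance significant PC).
    """
    if pc_selection not in ("significant", "top_vaf"):
        raise ValueError(f"unknown pc_selection {pc_selection!r}")
    pvals: dict[str, float] = {}
    sig_scores: dict[str, pd.Series] = {}
    retained: dict[str, list[str]] = {}
    binary = labels.dropna()
    for pkg, panels in sorted(packages.items()):
        blocks = []
        for month in sorted(panels):
            if month > timepoint:
                continue
            panel = panels[month].loc[
                panels[month].index.intersection(binary.index)]
            panel = panel.copy()
            panel.index = pd.MultiIndex.from_arrays(
                [panel.index, np.full(len(panel), month)],
                names=["patient_id", "month"])
            blocks.append(panel)
        if not blocks:
            continue
        stacked = pd.concat(blocks)
        try:
            pcs = nlpca_fit(stacked, var_types=var_types,
                            n_components=n_components)
        except ValueError:
            continue
        pkg_sig: list[tuple[float, str, pd.Series]] = []
        for pc in pcs:
            name = f"{pkg}_PC{pc.component}"
            retained[name] = threshold_loadings(pc, loading_cutoff)
            long = pd.DataFrame({
                "patient_id": pc.scores.index.get_level_values("patient_id"),
                "month": pc.scores.index.get_level_values("month"),
                "score": pc.scores.values})
            try:
                p = pc_group_test(long, binary)
            except ValueError:
                continue
            pvals[name] = p
            if p < alpha:
                pkg_sig.append(
                    (pc.vaf, name, pc.scores.groupby(level="patient_id").mean()))
        if pc_selection == "top_vaf" and pkg_sig:
            pkg_sig = [max(pkg_sig, key=lambda t: t[0])]
        for _vaf, name, scores in pkg_sig:
            sig_scores[name] = scores
    meta = build_meta_pc(sig_scores, binary)
    roc = None
    if not meta.empty:
        roc = roc_evaluate(meta.scores, binary,
                           n_permutations=n_permutations, seed=seed)
    return SignatureResult(timepoint=timepoint, pc_pvalues=pvals,
                           significant=sorted(sig_scores), meta=meta, roc=roc,
                           retained=retained)
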