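"""Comparative-metagenomics statistics over abundance profiles.

Covers the cross-cohort analysis layer: per-feature Wilcoxon rank-sum
differential abundance with Benjamini-Hochberg correction and log2
fold-change thresholds, Fisher's combined probability test for significance
shared across independent cohorts, Kendall tau-b co-abundance matrices,
Ward-linkage hierarchical clustering, PERMANOVA on distance matrices,
Shannon-Wiener diversity, principal components, and leakage-safe
cross-validated marker evaluation with random forests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests


@dataclass
class CohortDataset:
    """Samples x features abundance matrix with a two-group label vector."""

    X: pd.DataFrame  # samples x features (ECs or pathways), values rho
    groups: pd.Series  # per-sample group label, two levels
    cohort: str = ""

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.X):
            raise ValueError("group labels must match the number of samples")
        levels = sorted(self.groups.unique())
        if len(levels) != 2:
            raise ValueError(f"expected exactly two groups, got {levels}")
        if min((self.groups == g).sum() for g in levels) < 2:
            raise ValueError("need >= 2 samples per group")
        self.levels = levels  # (reference, case) in sorted order


# ---------------------------------------------------------------------------
# differential abundance


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def wilcoxon_bh(
    data: CohortDataset,
    p_cut: float = 0.05,
    lfc_cut: float = 0.58,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney U with BH correction and log2 FC.

    The exact null distribution is enumerated when both groups have n <= 8
    and the feature has no ties; otherwise the normal approximation with tie
    and continuity corrections is used. A feature constant across all
    samples gets p = 1 by convention. Fold change is log2 of the ratio of
    group means after adding one pseudo effective count, case over
    reference (groups compared in sorted label order). Features are flagged
    significant when BH-adjusted p < p_cut and |lfc| > lfc_cut.
    """
    ref, case = data.levels
    a = data.X[data.groups == case]
    b = data.X[data.groups == ref]
    n1, n2 = len(a), len(b)
    rows = []
    for feat in data.X.columns:
        x, y = a[feat].to_numpy(float), b[feat].to_numpy(float)
        both = np.concatenate([x, y])
        if np.all(both == both[0]):
            u, p = np.nan, 1.0
        else:
            has_ties = len(np.unique(both)) < len(both)
            method = "exact" if (n1 <= 8 and n2 <= 8 and not has_ties) else "asymptotic"
            u, p = stats.mannwhitneyu(
                x, y, alternative="two-sided", method=method, use_continuity=True
            )
        lfc = float(np.log2((x.mean() + pseudocount) / (y.mean() + pseudocount)))
        rows.append((feat, u, p, lfc))
    res = pd.DataFrame(rows, columns=["feature", "U", "p", "log2fc"]).set_index("feature")
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    res["direction"] = np.sign(res["log2fc"]).astype(int)
    res["significant"] = (res["p_adj"] < p_cut) & (res["log2fc"].abs() > lfc_cut)
    return res


def fisher_combined(p_by_cohort: Sequence[pd.Series] | pd.DataFrame) -> pd.DataFrame:
    """Fisher's combined probability test across >= 2 independent cohorts.

    X^2 = -2 sum_i ln p_i per feature, referred to a chi-square with
    2 * n_cohorts degrees of freedom. Zero p values are clamped to the
    smallest positive double with a warning.
    """
    if isinstance(p_by_cohort, pd.DataFrame):
        P = p_by_cohort
    else:
        P = pd.concat(list(p_by_cohort), axis=1)
    if P.shape[1] < 2:
        raise ValueError("need p values from at least two cohorts")
    vals = P.to_numpy(float)
    if np.isnan(vals).any():
        raise ValueError("missing p values; align cohorts before combining")
    if (vals <= 0).any():
        warnings.warn("p values of 0 clamped to the smallest positive double", stacklevel=2)
        vals = np.clip(vals, np.finfo(float).tiny, 1.0)
    if (vals > 1).any():
        raise ValueError("p values must lie in (0, 1]")
    x2 = -2.0 * np.log(vals).sum(axis=1)
    df = 2 * P.shape[1]
    out = pd.DataFrame(
        {"X2": x2, "df": df, "p_combined": stats.chi2.sf(x2, df)}, index=P.index
    )
    for i, col in enumerate(P.columns):
        out[f"p_{col}"] = vals[:, i]
    return out


def shared_significant_features(
    results: dict[str, pd.DataFrame], p_combined_cut: float = 0.05
) -> pd.DataFrame:
    """Combine per-cohort differential results into shared-significance calls.

    Joins the per-cohort raw p values on the common feature set, applies
    Fisher's method, and flags per-cohort significance and direction
    concordance so downstream reports can distinguish features significant
    in both cohorts, in one, or only jointly.
    """
    cohorts = sorted(results)
    common = results[cohorts[0]].index
    for c in cohorts[1:]:
        common = common.intersection(results[c].index)
    P = pd.DataFrame({c: results[c].loc[common, "p"] for c in cohorts})
    comb = fisher_combined(P)
    comb["shared_significant"] = comb["p_combined"] < p_combined_cut
    for c in cohorts:
        comb[f"sig_{c}"] = results[c].loc[common, "significant"]
        comb[f"dir_{c}"] = results[c].loc[common, "direction"]
    dirs = comb[[f"dir_{c}" for c in cohorts]].to_numpy()
    comb["concordant"] = (dirs == dirs[:, [0]]).all(axis=1) & (dirs[:, 0] != 0)
    return comb


# ---------------------------------------------------------------------------
# co-abundance and clustering


def kendall_coabundance(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Kendall tau-b between features (columns) of a samples x
    features matrix. Returns the symmetric unit-diagonal tau matrix and the
    list of constant features whose correlations were set to 0."""
    if len(X) < 3:
        raise ValueError("need >= 3 samples for rank correlation")
    feats = list(X.columns)
    constant = [f for f in feats if X[f].nunique() <= 1]
    tau = np.eye(len(feats))
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            if feats[i] in constant or feats[j] in constant:
                t = 0.0
            else:
                t = stats.kendalltau(X[feats[i]], X[feats[j]]).statistic
                if np.isnan(t):
                    t = 0.0
            tau[i, j] = tau[j, i] = t
    return pd.DataFrame(tau, index=feats, columns=feats), constant


def ward_clusters(matrix: pd.DataFrame | np.ndarray, n_clusters: int) -> tuple[np.ndarray, np.ndarray]:
    """Ward-linkage hierarchical clustering of the rows of a square symmetric
    co-abundance (correlation) matrix, under Euclidean distance between rows.

    Returns (labels in 1..n_clusters, scipy linkage matrix).
    """
    M = matrix.to_numpy(float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("input must be a square symmetric matrix")
    n = M.shape[0]
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n} items")
    Z = linkage(M, method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return labels, Z


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int


def permanova(
    dist: np.ndarray | pd.DataFrame,
    labels: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the total sum of squared distances
    SS_total = (1/n) sum_{i<j} d_ij^2 into within-group
    (SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2) and between-group
    parts; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)). The p value
    counts label permutations whose pseudo-F reaches the observed one,
    with the +1 correction.
    """
    D = dist.to_numpy(float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    labels = np.asarray(labels)
    n = D.shape[0]
    if D.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix and labels disagree in size")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    uniq, inv = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2 or np.bincount(inv).min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    D2 = D**2
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    if ss_total == 0:
        raise ValueError("all distances are zero; pseudo-F undefined")

    def ss_within(assign: np.ndarray) -> float:
        s = 0.0
        for g in range(a):
            idx = np.nonzero(assign == g)[0]
            s += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        return s

    def f_stat(assign: np.ndarray) -> float:
        sw = ss_within(assign)
        sb = ss_total - sw
        if sw == 0:
            return np.inf
        return (sb / (a - 1)) / (sw / (n - a))

    f_obs = f_stat(inv)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(inv)) >= f_obs:
            hits += 1
    sw = ss_within(inv)
    return PermanovaResult(
        pseudo_f=f_obs,
        r2=(ss_total - sw) / ss_total,
        p=(1 + hits) / (1 + n_perm),
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# diversity and ordination


def shannon_diversity(profile: np.ndarray | pd.Series) -> float:
    """Shannon-Wiener index H = -sum q ln q of a relative-abundance profile."""
    q = np.asarray(profile, float)
    if (q < 0).any():
        raise ValueError("profile must be non-negative")
    total = q.sum()
    if total == 0:
        raise ValueError("all-zero profile has undefined diversity")
    q = q[q > 0] / total
    return float(-(q * np.log(q)).sum())


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    variance_fraction: np.ndarray


def principal_components(X: pd.DataFrame | np.ndarray, n_comp: int) -> PCAResult:
    """Column-centered SVD principal components with variance fractions."""
    A = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if A.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    A = A - A.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    if n_comp > rank:
        warnings.warn(f"n_comp={n_comp} exceeds rank {rank}; truncating", stacklevel=2)
        n_comp = rank
    var = S**2
    frac = var / var.sum() if var.sum() > 0 else var
    return PCAResult(
        scores=U[:, :n_comp] * S[:n_comp],
        loadings=Vt[:n_comp].T,
        variance_fraction=frac[:n_comp],
    )


# ---------------------------------------------------------------------------
# cross-validated marker evaluation


@dataclass
class MarkerCVResult:
    fold_aucs: list[float]
    mean_auc: float
    ci95: tuple[float, float]
    selected_per_fold: list[list[str]]
    leakage_mode: bool


def marker_cv(
    data: CohortDataset,
    n_folds: int = 5,
    select_p: float = 0.05,
    n_repeats: int = 5,
    seed: int = 0,
    leakage_mode: bool = False,
    n_estimators: int = 100,
) -> MarkerCVResult:
    """Stratified cross-validated random-forest evaluation of marker ECs.

    Within each fold, candidate features are those with raw rank-sum p <
    ``select_p`` computed on the training samples only, so no test-fold
    sample influences selection; ``leakage_mode=True`` deliberately selects
    on the whole dataset instead, reproducing the optimistic bias that
    fold-internal selection avoids. ``n_repeats`` forests with distinct
    seeds are averaged per fold and scored by AUC; the 95% CI across folds
    is mean +/- 1.96 sd/sqrt(n_folds).
    """
    y = (data.groups == data.levels[1]).to_numpy(int)
    X = data.X
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)

    def select(frame: pd.DataFrame, yy: np.ndarray) -> list[str]:
        keep = []
        for feat in frame.columns:
            x1 = frame.loc[yy == 1, feat].to_numpy(float)
            x0 = frame.loc[yy == 0, feat].to_numpy(float)
            both = np.concatenate([x1, x0])
            if np.all(both == both[0]):
                continue
            p = stats.mannwhitneyu(x1, x0, alternative="two-sided").pvalue
            if p < select_p:
                keep.append(feat)
        return keep

    global_selection = select(X, y) if leakage_mode else None
    aucs: list[float] = []
    selected: list[list[str]] = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("fold with a single class; stratification failed")
        feats = global_selection if leakage_mode else select(X.iloc[tr], y[tr])
        if not feats:  # nothing passes the screen: fall back to all features
            feats = list(X.columns)
        selected.append(list(feats))
        Xtr, Xte = X.iloc[tr][feats], X.iloc[te][feats]
        prob = np.zeros(len(te))
        for rep in range(n_repeats):
            rf = RandomForestClassifier(
                n_estimators=n_estimators, random_state=seed * 1000 + fold * 10 + rep
            )
            rf.fit(Xtr, y[tr])
            prob += rf.predict_proba(Xte)[:, 1]
        aucs.append(float(roc_auc_score(y[te], prob / n_repeats)))
    mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
    half = 1.96 * sd / np.sqrt(len(aucs))
    return MarkerCVResult(aucs, mean, (mean - half, mean + half), selected, leakage_mode)
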