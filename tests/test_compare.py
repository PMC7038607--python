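import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ecprofiler.compare import (
    CohortDataset,
    MarkerCVResult,
    bh_adjust,
    fisher_combined,
    kendall_coabundance,
    marker_cv,
    permanova,
    principal_components,
    shannon_diversity,
    shared_significant_features,
    ward_clusters,
    wilcoxon_bh,
)


def _dataset(case: np.ndarray, control: np.ndarray, features=None) -> CohortDataset:
    """Stack (n_samples x n_features) arrays into a CohortDataset."""
    X = np.vstack([control, case])
    n_c, n_k = len(control), len(case)
    idx = [f"c{i}" for i in range(n_c)] + [f"k{i}" for i in range(n_k)]
    cols = features or [f"f{j}" for j in range(X.shape[1])]
    return CohortDataset(
        X=pd.DataFrame(X, index=idx, columns=cols),
        groups=pd.Series(["a_control"] * n_c + ["b_case"] * n_k, index=idx),
    )


class TestWilcoxon:
    def test_exact_p_small_groups_by_enumeration(self):
        # (1,2,3) vs (4,5,6): U=0; among C(6,3)=20 assignments only one is as
        # extreme each way -> two-sided p = 2/20 = 0.1
        data = _dataset(case=np.array([[4], [5], [6]]), control=np.array([[1], [2], [3]]))
        res = wilcoxon_bh(data)
        assert res["p"].iloc[0] == pytest.approx(0.1)
        # U is reported for case-vs-control; (case ranks all above) -> U = 9
        assert res["U"].iloc[0] in (0.0, 9.0)

    def test_constant_feature_p_one_lfc_zero(self):
        data = _dataset(case=np.full((3, 1), 5.0), control=np.full((3, 1), 5.0))
        res = wilcoxon_bh(data)
        assert res["p"].iloc[0] == 1.0 and res["log2fc"].iloc[0] == 0.0
        assert not res["significant"].iloc[0]

    def test_direction_and_significance_flags(self):
        rng = np.random.default_rng(5)
        control = rng.normal(10, 1, size=(12, 3))
        case = control.copy() + np.array([30.0, 0.0, 0.0])
        res = wilcoxon_bh(_dataset(case, control))
        assert res.loc["f0", "significant"] and res.loc["f0", "direction"] == 1
        assert not res.loc["f1", "significant"]

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(11)
        data = _dataset(rng.normal(size=(6, 8)), rng.normal(size=(6, 8)))
        res = wilcoxon_bh(data)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """min over the rank tail of m*p/rank, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * p[i] / rank_from_top)
        adj[i] = running
    return adj


class TestBH:
    def test_stated_step_up_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_definition(self, p_list):
        p = np.array(p_list)
        assert np.allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-10, atol=1e-12)


def chi2_sf_df4(x: float) -> float:
    # closed form for 4 degrees of freedom: e^{-x/2} (1 + x/2)
    return math.exp(-x / 2) * (1 + x / 2)


class TestFisher:
    def test_two_cohorts_closed_form(self):
        P = pd.DataFrame({"c1": [0.05], "c2": [0.05]})
        res = fisher_combined(P)
        x2 = -2 * 2 * math.log(0.05)
        assert res["X2"].iloc[0] == pytest.approx(x2)
        assert res["df"].iloc[0] == 4
        assert res["p_combined"].iloc[0] == pytest.approx(chi2_sf_df4(x2), rel=1e-10)
        assert res["p_combined"].iloc[0] == pytest.approx(0.01748, abs=1e-4)

    def test_all_ones_combine_to_one(self):
        res = fisher_combined(pd.DataFrame({"c1": [1.0], "c2": [1.0]}))
        assert res["X2"].iloc[0] == 0.0 and res["p_combined"].iloc[0] == 1.0

    def test_against_quadrature_oracle(self):
        from scipy.integrate import quad

        for pvals in ([0.2, 0.7], [0.03, 0.5, 0.9], [0.6, 0.6]):
            P = pd.DataFrame({f"c{i}": [p] for i, p in enumerate(pvals)})
            res = fisher_combined(P)
            df = 2 * len(pvals)
            x2 = res["X2"].iloc[0]
            # integrate the chi-square density written out by hand
            dens = lambda t: t ** (df / 2 - 1) * math.exp(-t / 2) / (2 ** (df / 2) * math.gamma(df / 2))
            tail, _ = quad(dens, x2, np.inf)
            assert res["p_combined"].iloc[0] == pytest.approx(tail, rel=1e-8)

    def test_single_cohort_rejected(self):
        with pytest.raises(ValueError, match="two cohorts"):
            fisher_combined(pd.DataFrame({"c1": [0.5]}))

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            res = fisher_combined(pd.DataFrame({"c1": [0.0], "c2": [0.5]}))
        assert np.isfinite(res["X2"].iloc[0])


class TestKendall:
    def test_small_vector_oracle_by_pair_enumeration(self):
        X = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4], "z": [4, 3, 2, 1]})
        tau, flagged = kendall_coabundance(X)
        assert flagged == []
        assert np.allclose(np.diag(tau), 1.0)
        assert tau.loc["x", "z"] == pytest.approx(-1.0)
        # x vs y: 5 concordant, 1 discordant of 6 pairs -> (5-1)/6 = 2/3
        assert tau.loc["x", "y"] == pytest.approx(2 / 3)
        assert np.allclose(tau.values, tau.values.T)

    def test_constant_feature_zeroed_and_flagged(self):
        X = pd.DataFrame({"x": [1, 2, 3], "const": [5, 5, 5]})
        tau, flagged = kendall_coabundance(X)
        assert flagged == ["const"]
        assert tau.loc["x", "const"] == 0.0
        assert tau.loc["const", "const"] == 1.0

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            kendall_coabundance(pd.DataFrame({"x": [1, 2], "y": [2, 1]}))


def brute_force_ward(points: np.ndarray) -> list[float]:
    """Lance-Williams Ward recursion computed from first principles."""
    clusters = {i: [i] for i in range(len(points))}
    d = {
        (i, j): float(np.linalg.norm(points[i] - points[j]))
        for i in range(len(points))
        for j in range(i + 1, len(points))
    }
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        (i, j), dij = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(dij)
        ni, nj = len(clusters[i]), len(clusters[j])
        merged = clusters.pop(i) + clusters.pop(j)
        new_d = {}
        for k in clusters:
            nk = len(clusters[k])
            dki = d[tuple(sorted((k, i)))]
            dkj = d[tuple(sorted((k, j)))]
            new_d[(k, next_id)] = math.sqrt(
                ((ni + nk) * dki**2 + (nj + nk) * dkj**2 - nk * dij**2) / (ni + nj + nk)
            )
        d = {kv: v for kv, v in d.items() if i not in kv and j not in kv}
        d.update(new_d)
        clusters[next_id] = merged
        next_id += 1
    return heights


class TestWard:
    def test_two_separated_blobs_recovered(self):
        M = np.array(
            [
                [1.0, 0.9, 0.0, 0.0],
                [0.9, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.9],
                [0.0, 0.0, 0.9, 1.0],
            ]
        )
        labels, _ = ward_clusters(M, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3] and labels[0] != labels[2]

    def test_merge_heights_non_decreasing(self, rng):
        A = rng.normal(size=(6, 6))
        M = (A + A.T) / 2
        _, Z = ward_clusters(M, 2)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_five_point_hand_oracle(self, rng):
        A = rng.normal(size=(5, 5))
        M = (A + A.T) / 2
        _, Z = ward_clusters(M, 2)
        assert np.allclose(sorted(Z[:, 2]), sorted(brute_force_ward(M)), rtol=1e-10)

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            ward_clusters(np.eye(3), 4)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ward_clusters(np.arange(9.0).reshape(3, 3), 2)


class TestPermanova:
    def test_four_point_hand_algebra(self):
        # 1-D points 0,1 | 4,5: SS_total=17, SS_within=1, F=32, R2=16/17
        x = np.array([0.0, 1.0, 4.0, 5.0])
        D = np.abs(x[:, None] - x[None, :])
        res = permanova(D, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert res.pseudo_f == pytest.approx(32.0)
        assert res.r2 == pytest.approx(16 / 17)

    def test_maximal_separation_minimal_p(self):
        # large identical groups: the chance a permutation reproduces the
        # exact split (and thus ties the infinite F) is 2/C(20,10) ~ 1e-5
        x = np.array([0.0] * 10 + [9.0] * 10)
        D = np.abs(x[:, None] - x[None, :])
        res = permanova(D, ["a"] * 10 + ["b"] * 10, n_perm=99, seed=1)
        assert res.p == pytest.approx(1 / 100)
        assert res.r2 > 0.99

    def test_equals_anova_f_on_one_dimensional_data(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            g = np.array(["a"] * 6 + ["b"] * 6)
            D = np.abs(x[:, None] - x[None, :])
            res = permanova(D, g, n_perm=99, seed=0)
            f_classic = stats.f_oneway(x[g == "a"], x[g == "b"]).statistic
            assert res.pseudo_f == pytest.approx(f_classic, rel=1e-10)

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        X = rng.normal(size=(10, 4))
        D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
        g = ["a"] * 5 + ["b"] * 5
        ours = permanova(D, g, n_perm=99, seed=0)
        theirs = sk_permanova(DistanceMatrix(D), grouping=g, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            permanova(np.zeros((4, 4)), ["a", "a", "b", "b"], n_perm=99, seed=0)


class TestDiversity:
    def test_uniform_maximizes_entropy(self):
        assert shannon_diversity(np.ones(4)) == pytest.approx(math.log(4))

    def test_single_feature_zero(self):
        assert shannon_diversity([0.0, 7.0, 0.0]) == 0.0

    def test_direct_evaluation(self):
        q = [0.5, 0.25, 0.25]
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert shannon_diversity(q) == pytest.approx(expected)
        assert shannon_diversity(q) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_diversity([0.0, 0.0])


class TestPCA:
    def test_rank_one_explains_everything(self, rng):
        u, v = rng.normal(size=(8, 1)), rng.normal(size=(1, 5))
        with pytest.warns(UserWarning, match="rank"):
            res = principal_components(u @ v, n_comp=3)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_pc1_separates_blobs(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (5, 3)), rng.normal(10, 0.1, (5, 3))])
        res = principal_components(X, 2)
        side = res.scores[:, 0] > 0
        assert side[:5].all() != side[5:].all() and len(set(side[:5])) == 1

    def test_variance_matches_eigendecomposition(self, rng):
        X = rng.normal(size=(12, 6))
        res = principal_components(X, 6)
        C = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.allclose(res.variance_fraction, eig / eig.sum(), rtol=1e-8)
        assert res.variance_fraction.sum() <= 1 + 1e-12


class TestMarkerCV:
    @pytest.fixture()
    def planted(self):
        rng = np.random.default_rng(31)
        n = 30
        control = rng.lognormal(3, 0.5, size=(n, 12))
        case = rng.lognormal(3, 0.5, size=(n, 12))
        case[:, :3] *= 6.0  # strong planted markers
        return _dataset(case, control)

    def test_planted_markers_reach_high_auc(self, planted):
        res = marker_cv(planted, n_folds=5, n_repeats=2, seed=1)
        assert res.mean_auc > 0.9
        assert res.ci95[0] <= res.mean_auc <= res.ci95[1]

    def test_fold_internal_selection_uses_training_only(self, planted):
        res = marker_cv(planted, n_folds=5, n_repeats=1, seed=1)
        assert not res.leakage_mode and len(res.selected_per_fold) == 5
        # fold-internal selections may differ across folds...
        leak = marker_cv(planted, n_folds=5, n_repeats=1, seed=1, leakage_mode=True)
        # ...whole-dataset selection is one fixed set reused by every fold
        assert leak.leakage_mode
        assert all(s == leak.selected_per_fold[0] for s in leak.selected_per_fold)

    def test_structural_leakage_guard(self, planted):
        """Removing the test fold's samples changes nothing about selection."""
        from sklearn.model_selection import StratifiedKFold

        y = (planted.groups == planted.levels[1]).to_numpy(int)
        res = marker_cv(planted, n_folds=3, n_repeats=1, seed=7)
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=7)
        for (tr, te), sel in zip(skf.split(planted.X, y), res.selected_per_fold):
            sub = CohortDataset(X=planted.X.iloc[tr], groups=planted.groups.iloc[tr])
            # recompute the screen on training samples alone
            from scipy.stats import mannwhitneyu

            keep = []
            for feat in sub.X.columns:
                x1 = sub.X.loc[sub.groups == sub.levels[1], feat]
                x0 = sub.X.loc[sub.groups == sub.levels[0], feat]
                if mannwhitneyu(x1, x0, alternative="two-sided").pvalue < 0.05:
                    keep.append(feat)
            assert sel == (keep or list(planted.X.columns))


class TestSharedSignificance:
    def test_joins_cohorts_and_flags_concordance(self, rng):
        results = {}
        for c, seed in (("c1", 1), ("c2", 2)):
            r = np.random.default_rng(seed)
            control = r.lognormal(3, 0.4, size=(15, 6))
            case = r.lognormal(3, 0.4, size=(15, 6))
            case[:, :2] *= 5.0
            results[c] = wilcoxon_bh(_dataset(case, control))
        shared = shared_significant_features(results)
        assert shared.loc["f0", "shared_significant"]
        assert shared.loc["f0", "concordant"]
        assert shared["df"].iloc[0] == 4
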