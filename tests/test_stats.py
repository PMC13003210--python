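"""Cohort statistics: brute-force oracles for the rank tests, BH
properties, and PCA behavior."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from respimodal.stats import (
    PCAResult,
    aggregate_cohort,
    benjamini_hochberg,
    compare_pc1_groups,
    group_wilcoxon_bh,
    paired_wilcoxon,
    run_pca,
)

# ---------------------------------------------------------------------------
# independent oracles


def signed_rank_exact_p(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided exact signed-rank p by enumerating all sign assignments.

    Returns (W = positive-rank sum, p).  Assumes no zeros/ties in |d|.
    """
    d = np.asarray(diffs, dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    mu = ws.mean()
    p = np.mean(np.abs(ws - mu) >= np.abs(w_obs - mu) - 1e-12)
    return float(w_obs), float(p)


def rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    ws = np.array(
        [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)]
    )
    mu = ws.mean()
    p = np.mean(np.abs(ws - mu) >= np.abs(w_obs - mu) - 1e-12)
    return float(w_obs), float(p)


def _table(t1, t2=None, control=None) -> pd.DataFrame:
    rows = []
    for i, v in enumerate(t1):
        rows.append({"participant_id": f"P{i:02d}", "time_point": "T1", "f": v})
    for i, v in enumerate(t2 if t2 is not None else []):
        rows.append({"participant_id": f"P{i:02d}", "time_point": "T2", "f": v})
    for i, v in enumerate(control if control is not None else []):
        rows.append({"participant_id": f"C{i:02d}", "time_point": "control", "f": v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregation


class TestAggregateCohort:
    def _rec(self, pid, tp, values, group="patient"):
        return {
            "participant_id": pid,
            "group": group,
            "time_point": tp,
            "series": pd.DataFrame(
                {"window_start_s": np.arange(len(values)) * 8.0, "RR": values}
            ),
        }

    def test_constant_series(self):
        table = aggregate_cohort([self._rec("P01", "T1", [7.0, 7.0, 7.0])])
        assert table.loc[0, "RR"] == 7.0

    def test_mean_of_two_windows(self):
        table = aggregate_cohort([self._rec("P01", "T1", [10.0, 20.0])])
        assert table.loc[0, "RR"] == 15.0

    def test_duplicate_rejected(self):
        recs = [self._rec("P01", "T1", [1.0]), self._rec("P01", "T1", [2.0])]
        with pytest.raises(ValueError, match="duplicate"):
            aggregate_cohort(recs)

    def test_control_label_derived_from_group(self):
        table = aggregate_cohort([self._rec("C01", "single", [3.0], group="control")])
        assert table.loc[0, "time_point"] == "control"

    def test_excluded_feature_dropped(self):
        rec = self._rec("P01", "T1", [1.0])
        rec["series"]["R5kHz"] = 30.0
        table = aggregate_cohort([rec])
        assert "R5kHz" not in table.columns


# ---------------------------------------------------------------------------
# paired signed-rank


class TestPairedWilcoxon:
    def test_all_positive_differences_n5(self):
        # T1 - T2 differences (1, 2, 3, 4, 5): W = 15, exact p = 2/32
        t2 = [10.0, 10, 10, 10, 10]
        t1 = [11.0, 12, 13, 14, 15]
        res = paired_wilcoxon(_table(t1, t2), features=["f"])
        assert res.loc[0, "W"] == 15.0
        assert res.loc[0, "p"] == pytest.approx(0.0625)

    def test_antisymmetric_differences(self):
        res = paired_wilcoxon(_table([9.0, 11.0], [10.0, 10.0]), features=["f"])
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_all_zero_differences(self):
        res = paired_wilcoxon(_table([5.0, 5.0], [5.0, 5.0]), features=["f"])
        assert res.loc[0, "p"] == 1.0
        assert res.loc[0, "W"] == 0.0

    @pytest.mark.parametrize("n", [3, 5, 8, 10])
    def test_matches_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d = rng.standard_normal(n)
            d = d[np.abs(d) > 1e-3]
            if len(np.unique(np.abs(d))) < len(d) or len(d) < 2:
                continue
            t2 = np.full(len(d), 10.0)
            t1 = t2 + d
            res = paired_wilcoxon(_table(t1, t2), features=["f"])
            w_ref, p_ref = signed_rank_exact_p(d)
            assert res.loc[0, "W"] == pytest.approx(w_ref)
            assert res.loc[0, "p"] == pytest.approx(p_ref, abs=1e-12)

    def test_requires_paired_participants(self):
        df = _table([1.0, 2.0])
        df.loc[len(df)] = {"participant_id": "X99", "time_point": "T2", "f": 3.0}
        with pytest.raises(ValueError, match="both T1 and T2"):
            paired_wilcoxon(df, features=["f"])


# ---------------------------------------------------------------------------
# rank-sum with BH


class TestGroupWilcoxonBH:
    def test_separated_3v3(self):
        # {1,2,3} vs {4,5,6}: exact two-sided p = 2/20 = 0.1
        res = group_wilcoxon_bh(_table([1.0, 2, 3], control=[4.0, 5, 6]), features=["f"])
        assert res.loc[0, "p"] == pytest.approx(0.1)
        assert res.loc[0, "W"] == 6.0  # rank-sum of the patient group

    def test_identical_groups(self):
        res = group_wilcoxon_bh(
            _table([1.0, 2, 3], [1.0, 2, 3], control=[1.0, 2, 3]), features=["f"]
        )
        assert (res["p"] == 1.0).all()
        assert (res["p_adj"] == 1.0).all()

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (5, 5), (2, 8)])
    def test_matches_brute_force_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2) + 0.5
            if len(np.unique(np.concatenate([x, y]))) < n1 + n2:
                continue
            res = group_wilcoxon_bh(_table(x, control=y), features=["f"])
            w_ref, p_ref = rank_sum_exact_p(x, y)
            assert res.loc[0, "W"] == pytest.approx(w_ref)
            assert res.loc[0, "p"] == pytest.approx(p_ref, abs=1e-12)

    def test_missing_t2_skipped(self):
        res = group_wilcoxon_bh(_table([1.0, 2, 3], control=[4.0, 5, 6]), features=["f"])
        assert set(res["comparison"]) == {"T1-control"}


class TestBenjaminiHochberg:
    def test_m2_hand_computed(self):
        # BH with m=2: adj = (min(2 * 0.01, 0.04), 0.04)
        adj = benjamini_hochberg(np.array([0.01, 0.04]))
        assert adj == pytest.approx([0.02, 0.04])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 8))
            adj = benjamini_hochberg(p)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(size=9)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert benjamini_hochberg(p) == pytest.approx(ref)


# ---------------------------------------------------------------------------
# PCA


def _pca_table(X: np.ndarray, time_points=None) -> pd.DataFrame:
    df = pd.DataFrame(X, columns=[f"v{j}" for j in range(X.shape[1])])
    df.insert(0, "participant_id", [f"P{i:02d}" for i in range(len(df))])
    df.insert(1, "time_point", time_points or ["T1"] * len(df))
    return df


class TestRunPCA:
    def test_perfectly_correlated_two_features(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(20)
        X = np.column_stack([a, 2 * a + 1])
        res = run_pca(_pca_table(X), features=["v0", "v1"])
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert np.abs(res.loadings["PC1"].to_numpy()) == pytest.approx(
            [1 / np.sqrt(2)] * 2
        )

    def test_isotropic_gaussian_13_features(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 13))
        res = run_pca(_pca_table(X), features=[f"v{j}" for j in range(13)])
        assert res.explained_variance_ratio[0] == pytest.approx(1 / 13, abs=0.05)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 5))
        feats = [f"v{j}" for j in range(5)]
        res = run_pca(_pca_table(X), features=feats, n_components=5)
        Z = (X - X.mean(0)) / X.std(0)
        recon = res.scores[[f"PC{k + 1}" for k in range(5)]].to_numpy() @ res.loadings.to_numpy().T
        assert recon == pytest.approx(Z, abs=1e-9)

    def test_scores_invariant_to_feature_order(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((25, 4))
        feats = [f"v{j}" for j in range(4)]
        r1 = run_pca(_pca_table(X), features=feats)
        r2 = run_pca(_pca_table(X), features=feats[::-1])
        assert r1.scores["PC1"].to_numpy() == pytest.approx(
            r2.scores["PC1"].to_numpy(), abs=1e-9
        )

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.standard_normal(10), np.full(10, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = run_pca(_pca_table(X), features=["v0", "v1"])
        assert res.dropped_features == ["v1"]

    def test_explained_variance_properties(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 6)) * np.arange(1, 7)
        res = run_pca(_pca_table(X), features=[f"v{j}" for j in range(6)])
        evr = res.explained_variance_ratio
        assert evr.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(evr) <= 1e-12)

    def test_loadings_unit_norm(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 5))
        res = run_pca(_pca_table(X), features=[f"v{j}" for j in range(5)])
        norms = np.linalg.norm(res.loadings.to_numpy(), axis=0)
        assert norms == pytest.approx([1.0, 1.0])

    def test_sign_convention(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 5))
        res = run_pca(_pca_table(X), features=[f"v{j}" for j in range(5)])
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_needs_three_rows(self):
        with pytest.raises(ValueError, match="3 rows"):
            run_pca(_pca_table(np.ones((2, 3))), features=["v0", "v1", "v2"])


class TestComparePC1Groups:
    def test_extreme_separation_3v3(self):
        scores = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(6)],
                "time_point": ["T1"] * 3 + ["control"] * 3,
                "PC1": [-1.0, -2.0, -3.0, 1.0, 2.0, 3.0],
            }
        )
        pca = PCAResult(
            loadings=pd.DataFrame(), explained_variance_ratio=np.array([1.0]),
            scores=scores, pc1_ranking=[], dropped_features=[],
        )
        res = compare_pc1_groups(pca)
        assert res.loc[0, "p"] == pytest.approx(0.1)

    def test_identical_sets(self):
        scores = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(6)],
                "time_point": ["T1"] * 3 + ["control"] * 3,
                "PC1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            }
        )
        pca = PCAResult(
            loadings=pd.DataFrame(), explained_variance_ratio=np.array([1.0]),
            scores=scores, pc1_ranking=[], dropped_features=[],
        )
        res = compare_pc1_groups(pca)
        assert res.loc[0, "p"] == pytest.approx(1.0)
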