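"""Cohort-level statistics: per-time-point aggregation, paired
signed-rank and unpaired rank-sum tests with Benjamini-Hochberg
correction, and the 2-D PCA with PC1 loading ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from respimodal.config import StatsConfig
from respimodal.ls import MULTIMODAL_FEATURES

logger = logging.getLogger(__name__)

#: features excluded from statistical inputs (raw impedance magnitude is
#: not comparable across participants)
EXCLUDED_FEATURES = ("R5kHz", "raw_impedance_ohm")


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values: p_adj(i) = min_{j>=i} (m/j) p_(j)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _iqr(x: np.ndarray) -> float:
    return float(np.percentile(x, 75) - np.percentile(x, 25))


def aggregate_cohort(
    recordings: list[dict],
) -> pd.DataFrame:
    """Collapse each recording's feature time series to its mean.

    ``recordings`` is a list of dicts with keys ``participant_id``,
    ``group`` ("patient"/"control"), ``time_point`` ("T1"/"T2"/"single")
    and ``series`` (the windowed feature DataFrame).  Returns one row
    per (participant, time point) indexed by those keys, with the
    excluded raw-impedance feature dropped if present.
    """
    rows = []
    seen = set()
    for rec in recordings:
        tp = rec["time_point"]
        label = "control" if rec["group"] == "control" else tp
        key = (rec["participant_id"], label)
        if key in seen:
            raise ValueError(f"duplicate (participant, time point): {key}")
        seen.add(key)
        series = rec["series"]
        feats = [
            c
            for c in series.columns
            if c != "window_start_s"
            and not c.startswith("interpolated_")
            and c not in EXCLUDED_FEATURES
        ]
        row = {"participant_id": rec["participant_id"], "time_point": label}
        for f in feats:
            row[f] = float(series[f].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _signed_rank_w(diffs: np.ndarray) -> tuple[float, int]:
    """Positive-rank sum (zeros dropped, midranks for ties) and n used."""
    d = diffs[diffs != 0]
    if len(d) == 0:
        return 0.0, 0
    ranks = sps.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), len(d)


def paired_wilcoxon(
    table: pd.DataFrame, features: list[str] | None = None
) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank tests on paired T1-T2 differences.

    W is the positive-rank sum; the p-value is exact when n <= 25 with
    no ties or zeros, normal approximation otherwise.
    """
    features = features or [f for f in MULTIMODAL_FEATURES if f in table.columns]
    t1 = table[table.time_point == "T1"].set_index("participant_id")
    t2 = table[table.time_point == "T2"].set_index("participant_id")
    both = t1.index.intersection(t2.index)
    if len(both) == 0:
        raise ValueError("no participants with both T1 and T2")
    rows = []
    for f in features:
        x = t1.loc[both, f].to_numpy(dtype=float)
        y = t2.loc[both, f].to_numpy(dtype=float)
        d = x - y
        w, n_used = _signed_rank_w(d)
        if n_used == 0:
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sps.wilcoxon(
                    x, y, zero_method="wilcox", alternative="two-sided", method="auto"
                )
            p = float(res.pvalue)
        rows.append(
            {
                "feature": f,
                "comparison": "T1-T2",
                "n": len(both),
                "W": w,
                "p": p,
                "median_T1": float(np.median(x)),
                "iqr_T1": _iqr(x),
                "median_T2": float(np.median(y)),
                "iqr_T2": _iqr(y),
            }
        )
    return pd.DataFrame(rows)


def _rank_sum_w(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-sum statistic of the first-named group (midranks for ties)."""
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum())


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


def group_wilcoxon_bh(
    table: pd.DataFrame, features: list[str] | None = None
) -> pd.DataFrame:
    """Rank-sum tests of T1 vs control and T2 vs control per feature,
    with BH adjustment across the two comparisons of each feature.

    W is the rank-sum of the first-named (patient) group.
    """
    features = features or [f for f in MULTIMODAL_FEATURES if f in table.columns]
    ctrl = table[table.time_point == "control"]
    if ctrl.empty:
        raise ValueError("no control rows")
    rows = []
    for f in features:
        c = ctrl[f].to_numpy(dtype=float)
        raw: dict[str, dict] = {}
        for tp in ("T1", "T2"):
            g = table[table.time_point == tp]
            if g.empty:
                logger.info("group comparison %s-control skipped: empty group", tp)
                continue
            x = g[f].to_numpy(dtype=float)
            raw[tp] = {
                "feature": f,
                "comparison": f"{tp}-control",
                "n1": len(x),
                "n2": len(c),
                "W": _rank_sum_w(x, c),
                "p": _rank_sum_p(x, c),
                "median_patient": float(np.median(x)),
                "iqr_patient": _iqr(x),
                "median_control": float(np.median(c)),
                "iqr_control": _iqr(c),
            }
        if not raw:
            continue
        padj = benjamini_hochberg(np.array([raw[tp]["p"] for tp in raw]))
        for adj, tp in zip(padj, raw):
            raw[tp]["p_adj"] = float(adj)
            rows.append(raw[tp])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """Standardized-feature PCA projection of the cohort table."""

    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # rows x (participant_id, time_point, PC1, PC2, ...)
    pc1_ranking: list[str]  # features by |PC1 loading|, descending
    dropped_features: list[str]


def run_pca(
    table: pd.DataFrame,
    features: list[str] | None = None,
    n_components: int = 2,
) -> PCAResult:
    """PCA on z-scored features with a deterministic sign convention.

    Zero-variance features are dropped with a warning.  Each component
    is oriented so that its largest-magnitude loading is positive.
    """
    features = features or [f for f in MULTIMODAL_FEATURES if f in table.columns]
    if len(table) < 3:
        raise ValueError("PCA needs at least 3 rows")
    X = table[features].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    dropped = [f for f, s in zip(features, sd) if s == 0]
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
        features = [f for f in features if f not in dropped]
        X = table[features].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=0)
    Z = (X - X.mean(axis=0)) / sd
    n_components = min(n_components, Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()  # features x components
    for j in range(n_components):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    pc_cols = [f"PC{j + 1}" for j in range(n_components)]
    score_df = table[["participant_id", "time_point"]].reset_index(drop=True).copy()
    for j, c in enumerate(pc_cols):
        score_df[c] = scores[:, j]
    ranking = [
        features[i] for i in np.argsort(-np.abs(loadings[:, 0]), kind="stable")
    ]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=features, columns=pc_cols),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scores=score_df,
        pc1_ranking=ranking,
        dropped_features=dropped,
    )


def compare_pc1_groups(pca: PCAResult) -> pd.DataFrame:
    """Rank-sum tests of PC1 for T1 vs control and T2 vs control with BH
    adjustment across the two comparisons."""
    s = pca.scores
    ctrl = s[s.time_point == "control"]["PC1"].to_numpy(dtype=float)
    if len(ctrl) == 0:
        raise ValueError("no control rows in PCA scores")
    rows = []
    for tp in ("T1", "T2"):
        x = s[s.time_point == tp]["PC1"].to_numpy(dtype=float)
        if len(x) == 0:
            logger.info("PC1 comparison %s-control skipped: empty group", tp)
            continue
        rows.append(
            {
                "feature": "PC1",
                "comparison": f"{tp}-control",
                "n1": len(x),
                "n2": len(ctrl),
                "W": _rank_sum_w(x, ctrl),
                "p": _rank_sum_p(x, ctrl),
                "median_patient": float(np.median(x)),
                "iqr_patient": _iqr(x),
                "median_control": float(np.median(ctrl)),
                "iqr_control": _iqr(ctrl),
            }
        )
    if not rows:
        return pd.DataFrame()
    padj = benjamini_hochberg(np.array([r["p"] for r in rows]))
    for r, adj in zip(rows, padj):
        r["p_adj"] = float(adj)
    return pd.DataFrame(rows)


def run_cohort_stats(
    table: pd.DataFrame, config: StatsConfig | None = None
) -> dict[str, object]:
    """Paired tests, group tests, PCA and PC1 group comparison in one go."""
    config = config or StatsConfig()
    out: dict[str, object] = {}
    has_t1 = (table.time_point == "T1").any()
    has_t2 = (table.time_point == "T2").any()
    has_ctrl = (table.time_point == "control").any()
    if has_t1 and has_t2:
        t1_ids = set(table[table.time_point == "T1"].participant_id)
        t2_ids = set(table[table.time_point == "T2"].participant_id)
        if t1_ids & t2_ids:
            out["paired"] = paired_wilcoxon(table)
    if has_ctrl and (has_t1 or has_t2):
        out["group"] = group_wilcoxon_bh(table)
        pca = run_pca(table)
        out["pca"] = pca
        out["pc1_group"] = compare_pc1_groups(pca)
    return out
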