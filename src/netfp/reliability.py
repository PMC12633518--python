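"""Reliability and biological-specificity analyses.

* blocking comparison: per-scan median of the upper-triangle similarities
  before vs after target blockade, one-tailed Wilcoxon signed-rank test
  (alternative: post > pre);
* test-retest Spearman correlation per subject;
* edgewise ICC(3,1) (two-way mixed effects, single measurement,
  consistency) across test/retest sessions;
* retest identification: for each test scan, rank retest scans by Spearman
  correlation; a hit means the top match is the same subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr, wilcoxon

from .network import SimilarityMatrix, edge_index_pairs, median_mad

__all__ = [
    "BlockingResult",
    "TestRetestReport",
    "blocking_comparison",
    "testretest_correlation",
    "edgewise_icc",
    "identify_subjects",
]


@dataclass(frozen=True)
class BlockingResult:
    pre_medians: np.ndarray
    post_medians: np.ndarray
    mean_percent_increase: float
    p_value: float
    statistic: float


@dataclass(frozen=True)
class TestRetestReport:
    per_subject_rho: pd.Series
    rho_mean: float
    rho_sd: float
    icc: np.ndarray
    icc_median: float
    icc_mad: float
    identification_accuracy: float
    match_table: pd.DataFrame


def _upper_triangle_median(matrix: SimilarityMatrix) -> float:
    iu, ju = edge_index_pairs(len(matrix.roi_names))
    return float(np.median(matrix.values[iu, ju]))


def blocking_comparison(
    pre_matrices: list[SimilarityMatrix], post_matrices: list[SimilarityMatrix]
) -> BlockingResult:
    """Compare per-scan median similarity before/after blockade.

    Exact one-tailed signed-rank null for n <= 25, normal approximation with
    continuity correction above; zero differences are dropped.
    """
    if len(pre_matrices) != len(post_matrices):
        raise ValueError(
            f"unpaired lists: {len(pre_matrices)} pre vs {len(post_matrices)} post"
        )
    if len(pre_matrices) < 1:
        raise ValueError("need at least one pre/post pair")
    pre = np.array([_upper_triangle_median(m) for m in pre_matrices])
    post = np.array([_upper_triangle_median(m) for m in post_matrices])
    diffs = post - pre
    if np.all(diffs == 0):
        raise ValueError("no signed ranks: all paired differences are zero")
    method = "exact" if np.count_nonzero(diffs) <= 25 and np.unique(
        np.abs(diffs[diffs != 0])
    ).size == np.count_nonzero(diffs) else "approx"
    res = wilcoxon(
        post, pre, alternative="greater", zero_method="wilcox", method=method, correction=True
    )
    pct = float(np.mean((post - pre) / pre * 100.0))
    return BlockingResult(
        pre_medians=pre,
        post_medians=post,
        mean_percent_increase=pct,
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
    )


def testretest_correlation(
    test_edges: pd.DataFrame, retest_edges: pd.DataFrame
) -> pd.Series:
    """Per-subject Spearman rho between test and retest edge vectors.

    Both tables are indexed by subject and must share the same index.
    """
    if not test_edges.index.equals(retest_edges.index):
        raise ValueError("test and retest tables must share the same subject index")
    rhos = {}
    for subj in test_edges.index:
        rho = spearmanr(test_edges.loc[subj], retest_edges.loc[subj]).statistic
        rhos[subj] = float(rho)
    return pd.Series(rhos, name="spearman_rho")


def edgewise_icc(
    test_set: pd.DataFrame | np.ndarray, retest_set: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, float, float]:
    """ICC(3,1) per edge across two sessions.

    Two-way mixed effects, single measurement:
    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E) with k = 2 sessions.
    Returns (per-edge ICC, median, MAD).
    """
    a = np.asarray(test_set, dtype=float)
    b = np.asarray(retest_set, dtype=float)
    if a.shape != b.shape:
        raise ValueError("test and retest sets must have matching shapes")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"edgewise ICC needs >= 3 complete subject pairs, got {n}")
    y = np.stack([a, b], axis=1)  # n x 2 x E
    k = 2
    grand = y.mean(axis=(0, 1))
    row_means = y.mean(axis=1)  # n x E
    col_means = y.mean(axis=0)  # 2 x E
    ss_total = ((y - grand) ** 2).sum(axis=(0, 1))
    ss_rows = k * ((row_means - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_means - grand) ** 2).sum(axis=0)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    icc = np.where(np.isfinite(icc), icc, np.nan)
    finite = icc[np.isfinite(icc)]
    if finite.size == 0:
        raise ValueError("ICC undefined for every edge (no variance)")
    med, mad = median_mad(finite)
    return icc, med, mad


def identify_subjects(
    test_edge_vectors: pd.DataFrame, retest_edge_vectors: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Retest identification accuracy.

    For each test scan, rank all retest scans by Spearman correlation; the
    identification is correct when the top-ranked retest scan belongs to the
    same subject (index label).  Ties resolve to the first index with a
    warning.  Returns (accuracy, match table with columns rank1..rankN).
    """
    test_ranks = np.apply_along_axis(rankdata, 1, test_edge_vectors.to_numpy(dtype=float))
    retest_ranks = np.apply_along_axis(rankdata, 1, retest_edge_vectors.to_numpy(dtype=float))
    tr = (test_ranks - test_ranks.mean(axis=1, keepdims=True))
    rr = (retest_ranks - retest_ranks.mean(axis=1, keepdims=True))
    tr /= np.linalg.norm(tr, axis=1, keepdims=True)
    rr /= np.linalg.norm(rr, axis=1, keepdims=True)
    corr = tr @ rr.T  # test x retest Spearman

    retest_ids = list(retest_edge_vectors.index)
    rows = {}
    hits = 0
    for i, test_id in enumerate(test_edge_vectors.index):
        order = np.argsort(-corr[i], kind="stable")
        top_corr = corr[i][order[0]]
        if np.sum(np.isclose(corr[i], top_corr)) > 1:
            warnings.warn(
                f"identification tie for test scan {test_id!r}; taking first index",
                stacklevel=2,
            )
        ranked = [retest_ids[j] for j in order]
        rows[test_id] = ranked
        if ranked[0] == test_id:
            hits += 1
    match = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"rank{r + 1}" for r in range(len(retest_ids))]
    )
    return hits / len(test_edge_vectors), match
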