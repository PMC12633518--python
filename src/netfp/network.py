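"""Similarity-network construction.

Regional feature vectors are robust z-scored within tracer group (value
minus group median, divided by the raw median absolute deviation), then for
every region pair i < j the similarity is

    S_ij = 1 / (1 + d_ij)

with d_ij the Euclidean distance between the standardized feature vectors.
The upper triangle of S in canonical row-major order is the scan's edge
vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "StandardizationParams",
    "SimilarityMatrix",
    "robust_standardize",
    "pairwise_distance",
    "similarity_from_distance",
    "build_similarity_matrix",
    "edge_vector",
    "matrix_from_edges",
    "edge_names",
    "edge_index_pairs",
    "cohort_edge_table",
    "cohort_consistency",
    "spearman_matrix",
    "median_mad",
]


@dataclass(frozen=True)
class StandardizationParams:
    """Per tracer group and per feature: median and raw MAD."""

    median: pd.DataFrame  # index = group, columns = features
    mad: pd.DataFrame


@dataclass
class SimilarityMatrix:
    """Symmetric R x R similarity matrix for one scan."""

    scan_id: str
    roi_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.values = v
        r = len(self.roi_names)
        if v.shape != (r, r):
            raise ValueError(f"matrix shape {v.shape} does not match {r} ROIs")

    def validate(self, atol: float = 1e-10) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("similarity matrix diagonal must be 1")
        if np.any(v <= 0) or np.any(v > 1 + atol):
            raise ValueError("similarity values must lie in (0, 1]")


def median_mad(x: np.ndarray) -> tuple[float, float]:
    """Median and raw median absolute deviation (no 1.4826 scaling)."""
    x = np.asarray(x, dtype=float)
    m = float(np.median(x))
    return m, float(np.median(np.abs(x - m)))


def robust_standardize(
    feature_table: pd.DataFrame,
    tracer_grouping: Mapping[str, str] | pd.Series,
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Robust z-score per feature within tracer group.

    ``feature_table`` is indexed by (scan_id, roi); the median/MAD for each
    feature are pooled over all region x scan values of the group.
    """
    if isinstance(tracer_grouping, pd.Series):
        tracer_grouping = tracer_grouping.to_dict()
    scan_ids = feature_table.index.get_level_values("scan_id")
    missing = set(scan_ids) - set(tracer_grouping)
    if missing:
        raise ValueError(f"no tracer group for scan(s) {sorted(missing)[:5]}")
    groups = pd.Series([tracer_grouping[s] for s in scan_ids], index=feature_table.index)

    medians: dict[str, pd.Series] = {}
    mads: dict[str, pd.Series] = {}
    out = feature_table.copy()
    for group, sub in feature_table.groupby(groups):
        med = {}
        mad = {}
        for col in feature_table.columns:
            vals = sub[col].to_numpy()
            if np.unique(vals).size < 2:
                raise ValueError(
                    f"degenerate feature dispersion: feature {col!r} is constant "
                    f"in tracer group {group!r}"
                )
            m, s = median_mad(vals)
            if s == 0.0:
                raise ValueError(
                    f"degenerate feature dispersion: MAD of feature {col!r} is 0 "
                    f"in tracer group {group!r}"
                )
            med[col], mad[col] = m, s
        med_s, mad_s = pd.Series(med), pd.Series(mad)
        out.loc[sub.index] = (sub - med_s) / mad_s
        medians[group], mads[group] = med_s, mad_s

    params = StandardizationParams(
        median=pd.DataFrame(medians).T, mad=pd.DataFrame(mads).T
    )
    return out, params


def pairwise_distance(x_i, x_j) -> float:
    """Euclidean distance between two equal-length feature vectors."""
    a = np.asarray(x_i, dtype=float)
    b = np.asarray(x_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"feature-vector length mismatch: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("feature vectors must be finite")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def similarity_from_distance(d):
    """S = 1 / (1 + d), mapping distances [0, inf) to similarities (0, 1]."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    s = 1.0 / (1.0 + d)
    return float(s) if s.ndim == 0 else s


def build_similarity_matrix(
    features: pd.DataFrame, scan_id: str | None = None
) -> SimilarityMatrix:
    """Similarity matrix from one scan's standardized features.

    ``features`` is indexed by ROI name (registry order), one row per region.
    """
    x = features.to_numpy(dtype=float)
    d = squareform(pdist(x, metric="euclidean"))
    s = 1.0 / (1.0 + d)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(
        scan_id=scan_id or "", roi_names=list(features.index), values=s
    )


def edge_index_pairs(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical row-major upper-triangle (i, j) index arrays."""
    return np.triu_indices(n_rois, k=1)


def edge_names(roi_names: list[str]) -> list[str]:
    iu, ju = edge_index_pairs(len(roi_names))
    return [f"{roi_names[i]}|{roi_names[j]}" for i, j in zip(iu, ju)]


def edge_vector(matrix: SimilarityMatrix) -> pd.Series:
    """Canonical upper-triangle flattening of a similarity matrix."""
    iu, ju = edge_index_pairs(len(matrix.roi_names))
    return pd.Series(
        matrix.values[iu, ju], index=edge_names(matrix.roi_names), name=matrix.scan_id
    )


def matrix_from_edges(
    edges: pd.Series | np.ndarray, roi_names: list[str], scan_id: str = ""
) -> SimilarityMatrix:
    """Inverse of :func:`edge_vector` (diagonal restored to 1)."""
    vals = np.asarray(edges, dtype=float)
    r = len(roi_names)
    if vals.size != r * (r - 1) // 2:
        raise ValueError(
            f"edge vector length {vals.size} does not match {r} ROIs "
            f"(expected {r * (r - 1) // 2})"
        )
    m = np.ones((r, r))
    iu, ju = edge_index_pairs(r)
    m[iu, ju] = vals
    m[ju, iu] = vals
    return SimilarityMatrix(scan_id=scan_id, roi_names=list(roi_names), values=m)


def cohort_edge_table(matrices: list[SimilarityMatrix]) -> pd.DataFrame:
    """Rows = scans, columns = canonical edges."""
    return pd.DataFrame([edge_vector(m) for m in matrices])


def spearman_matrix(edge_df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations between rows (average ranks for ties)."""
    ranks = np.apply_along_axis(rankdata, 1, edge_df.to_numpy(dtype=float))
    c = np.corrcoef(ranks)
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=edge_df.index, columns=edge_df.index)


def cohort_consistency(
    edge_df: pd.DataFrame, tracer_grouping: Mapping[str, str] | pd.Series
) -> tuple[pd.DataFrame, dict]:
    """Inter-scan Spearman consistency with median +/- MAD summaries.

    Returns the scan x scan Spearman matrix and a summary dict with keys
    ``global``, ``intra_tracer`` (per tracer) and ``inter_tracer`` (per
    unordered tracer pair); each summary is ``(median, mad)`` over the
    off-diagonal pairs of the stratum.
    """
    if len(edge_df) < 2:
        raise ValueError("cohort consistency needs >= 2 scans")
    if isinstance(tracer_grouping, pd.Series):
        tracer_grouping = tracer_grouping.to_dict()
    corr = spearman_matrix(edge_df)
    tracers = np.array([tracer_grouping[s] for s in edge_df.index])
    c = corr.to_numpy()
    iu, ju = np.triu_indices(len(edge_df), k=1)
    vals = c[iu, ju]
    ti, tj = tracers[iu], tracers[ju]

    summary: dict = {"global": median_mad(vals), "intra_tracer": {}, "inter_tracer": {}}
    for t in np.unique(tracers):
        mask = (ti == t) & (tj == t)
        if mask.any():
            summary["intra_tracer"][t] = median_mad(vals[mask])
    uniq = list(np.unique(tracers))
    for a in range(len(uniq)):
        for b in range(a + 1, len(uniq)):
            mask = ((ti == uniq[a]) & (tj == uniq[b])) | ((ti == uniq[b]) & (tj == uniq[a]))
            if mask.any():
                summary["inter_tracer"][(uniq[a], uniq[b])] = median_mad(vals[mask])
    return corr, summary
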