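"""Module discovery: log/z transform, gap-statistic k selection, k-means.

The clustering recipe: per-feature z-scores of log2(x+1) abundances, k-means
with many random starts, and the gap statistic of Tibshirani et al. (2001)
with the "SE" selection rule (smallest k whose gap is within one standard
error of the next k's gap) to choose the number of modules. The reference
null draws each variable uniformly over its observed range, matching the
default of the classic clusGap implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import FeatureMatrix


@dataclass
class TransformedMatrix:
    values: pd.DataFrame  # features x conditions, row-z of log2(x+1)
    provenance: str = "log2(x+1) + row z-score"

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class GapResult:
    k_grid: list[int]
    gap: np.ndarray
    se: np.ndarray
    chosen_k: int
    B: int
    log_wk: np.ndarray = field(default=None)


@dataclass
class ClusterModel:
    assignment: pd.Series  # feature id -> module id (int)
    centroids: pd.DataFrame  # module x condition
    inertia: float
    k: int
    n_starts: int
    seed: int
    category: dict = field(default_factory=dict)  # module id -> label, set downstream

    def module_members(self) -> dict[int, list[str]]:
        return {
            int(m): list(idx) for m, idx in self.assignment.groupby(self.assignment).groups.items()
        }


# ---------------------------------------------------------------------------
# Transform
# ---------------------------------------------------------------------------

def log_zscore(matrix, log: bool = True) -> TransformedMatrix:
    """Row-wise z-score of log2(x+1); constant rows map to all-zero.

    Sample standard deviation (n-1 denominator) is used. ``log=False`` skips
    the log step for inputs already on a suitable scale (e.g. methylation
    fractions or pre-normalized accessibility scores).
    """
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    x = values.to_numpy(dtype=float)
    if log:
        if (x < 0).any():
            raise ValueError("negative values are invalid in log mode")
        x = np.log2(x + 1.0)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    prov = "log2(x+1) + row z-score" if log else "row z-score"
    return TransformedMatrix(
        values=pd.DataFrame(z, index=values.index, columns=values.columns),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Gap statistic
# ---------------------------------------------------------------------------

def _within_dispersion(x: np.ndarray, k: int, n_starts: int, seed) -> float:
    """log of pooled within-cluster sum of squares for best-of-starts k-means."""
    if k == 1:
        w = float(((x - x.mean(axis=0)) ** 2).sum())
    else:
        km = KMeans(n_clusters=k, n_init=n_starts, max_iter=300, tol=1e-6, random_state=seed)
        km.fit(x)
        w = float(km.inertia_)
    return np.log(w) if w > 0 else -np.inf

def gap_select_k(
    matrix,
    k_grid=range(2, 21),
    B: int = 60,
    seed: int = 0,
    n_starts: int = 10,
) -> GapResult:
    """Gap statistic over ``k_grid`` with Tibshirani's SE selection rule.

    gap(k) = mean_b log W*_kb - log W_k, with W the pooled within-cluster
    dispersion and the B reference sets drawn uniformly over each variable's
    observed range. s_k = sd_b(log W*_kb) * sqrt(1 + 1/B). The chosen k is
    the smallest k with gap(k) >= gap(k+1) - s_{k+1}; if no k qualifies the
    largest grid value is returned.
    """
    values = matrix.values if isinstance(matrix, (TransformedMatrix, FeatureMatrix)) else matrix
    x = np.asarray(values, dtype=float)
    k_grid = sorted(int(k) for k in k_grid)
    if B < 10:
        raise ValueError("B must be at least 10")
    if k_grid[0] < 1 or k_grid[-1] > x.shape[0] - 1:
        raise ValueError("k_grid must lie within [1, n_features - 1]")

    if np.allclose(x, x[0]):
        warnings.warn("all rows identical; returning k = 1")
        nk = len(k_grid)
        return GapResult(k_grid, np.zeros(nk), np.zeros(nk), 1, B, np.zeros(nk))

    rng = np.random.default_rng(seed)
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    log_wk = np.array(
        [_within_dispersion(x, k, n_starts, int(rng.integers(2**31))) for k in k_grid]
    )
    log_wkb = np.empty((B, len(k_grid)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=x.shape)
        for j, k in enumerate(k_grid):
            log_wkb[b, j] = _within_dispersion(ref, k, n_starts, int(rng.integers(2**31)))

    gap = log_wkb.mean(axis=0) - log_wk
    se = log_wkb.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    chosen = k_grid[-1]
    for j in range(len(k_grid) - 1):
        if gap[j] >= gap[j + 1] - se[j + 1]:
            chosen = k_grid[j]
            break
    return GapResult(list(k_grid), gap, se, int(chosen), B, log_wk)


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def kmeans_fit(matrix, k: int, n_starts: int = 100, seed: int = 0) -> ClusterModel:
    """Best-of-``n_starts`` Lloyd k-means (k-means++ per start), seeded."""
    values = matrix.values if isinstance(matrix, (TransformedMatrix, FeatureMatrix)) else matrix
    x = values.to_numpy(dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.shape[0]:
        raise ValueError("k exceeds the number of features")
    km = KMeans(
        n_clusters=k, n_init=n_starts, init="k-means++",
        max_iter=300, tol=1e-6, random_state=seed,
    )
    labels = km.fit_predict(x)
    return ClusterModel(
        assignment=pd.Series(labels, index=values.index, name="module"),
        centroids=pd.DataFrame(km.cluster_centers_, columns=values.columns),
        inertia=float(km.inertia_),
        k=k,
        n_starts=n_starts,
        seed=seed,
    )


def merge_modules_by_correlation(model: ClusterModel, values: pd.DataFrame, threshold: float = 0.95) -> ClusterModel:
    """Collapse modules whose centroid Pearson correlation exceeds ``threshold``.

    Mirrors the manual "inspect and collapse similar clusters" step as an
    explicit, reproducible operation: iteratively merge the most-correlated
    centroid pair above the threshold, recomputing the merged centroid as the
    member mean.
    """
    centroids = {m: model.centroids.loc[m].to_numpy() for m in model.centroids.index}
    members = {m: list(ids) for m, ids in model.module_members().items()}
    x = values.loc[model.assignment.index].to_numpy(dtype=float)
    row_of = {f: i for i, f in enumerate(model.assignment.index)}

    def best_pair():
        pairs = sorted(centroids)
        top, top_r = None, threshold
        for i, a in enumerate(pairs):
            for b in pairs[i + 1:]:
                r = np.corrcoef(centroids[a], centroids[b])[0, 1]
                if r >= top_r:
                    top, top_r = (a, b), r
        return top

    while (pair := best_pair()) is not None:
        a, b = pair
        members[a].extend(members.pop(b))
        centroids.pop(b)
        rows = [row_of[f] for f in members[a]]
        centroids[a] = x[rows].mean(axis=0)

    relabel = {old: new for new, old in enumerate(sorted(members))}
    assignment = pd.Series(
        {f: relabel[m] for m, ids in members.items() for f in ids}, name="module"
    ).reindex(model.assignment.index)
    cents = pd.DataFrame(
        [centroids[m] for m in sorted(members)], columns=model.centroids.columns
    )
    inertia = float(
        sum(
            ((x[[row_of[f] for f in members[m]]] - centroids[m]) ** 2).sum()
            for m in members
        )
    )
    return ClusterModel(
        assignment=assignment, centroids=cents, inertia=inertia,
        k=len(members), n_starts=model.n_starts, seed=model.seed,
    )


# ---------------------------------------------------------------------------
# Pseudo-bulk
# ---------------------------------------------------------------------------

def pseudo_bulk(
    cell_values: pd.DataFrame,
    cell_clusters: pd.Series,
    max_cells: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Features x cluster mean profile, downsampling each cluster to ``max_cells``.

    ``cell_values`` is features x cells; ``cell_clusters`` maps cell -> cluster.
    Downsampling avoids cluster-size bias before averaging.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for cluster, cells in cell_clusters.groupby(cell_clusters).groups.items():
        cells = list(cells)
        if len(cells) > max_cells:
            cells = list(rng.choice(cells, size=max_cells, replace=False))
        out[cluster] = cell_values[cells].mean(axis=1)
    return pd.DataFrame(out)
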