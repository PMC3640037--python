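"""Temporal response profiles and k-means response clustering.

A gene's response over the treatment time course is summarized by the
median log2 fold change across samples at each timepoint (the f-profile,
anchored at 0 at time 0).  To cluster genes on the *dynamics* rather than
the overall intensity of response, clustering operates on the per-interval
change in log2 fold change (the delta-transform of f).  Each cluster is
summarized by its direction (Up/Down) and the timepoint at which the
reconstructed profile of its center peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


def median_profile(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint median log2 fold change across samples.

    ``panel`` is genes x (timepoint, sample).  Every timepoint must carry
    at least one sample.
    """
    timepoints = list(panel.columns.get_level_values("timepoint").unique())
    cols = {}
    for tp in timepoints:
        block = panel[tp]
        if block.shape[1] < 1:
            raise ValueError(f"timepoint {tp} has no samples")
        cols[tp] = block.median(axis=1)
    f = pd.DataFrame(cols)
    f.columns.name = "timepoint"
    return f


def delta_transform(f, timepoints: Sequence[float] | None = None) -> np.ndarray:
    """Change in log2 fold change per interval, anchored at 0 at time 0.

    ``df[0] = f[0]``; ``df[j] = f[j] - f[j-1]``.  Cumulative sums of the
    output reconstruct ``f`` exactly.
    """
    arr = np.asarray(f, dtype=float)
    return np.diff(arr, axis=-1, prepend=0.0)


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series        # gene -> cluster id (0..k-1)
    centers: pd.DataFrame         # k x timepoints (delta scale)
    inertia: float
    summary: pd.DataFrame         # cluster, direction, peak_time, size


def summarize_cluster(center, timepoints: Sequence[float]) -> tuple[str, float | None]:
    """Direction and peak time of a cluster center (delta scale).

    The center is cumulatively summed back to an f-profile; the peak time
    is the timepoint of maximal |f| (earliest on ties) and the direction
    is Up if f at the peak is positive, Down if negative.  An all-zero
    center is flagged ``flat`` with no peak time.
    """
    fstar = np.cumsum(np.asarray(center, dtype=float))
    if np.all(fstar == 0):
        return "flat", None
    idx = int(np.argmax(np.abs(fstar)))  # argmax takes the earliest tie
    direction = "Up" if fstar[idx] > 0 else "Down"
    return direction, float(timepoints[idx])


def kmeans_cluster(
    df_matrix: pd.DataFrame,
    k: int = 8,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
    timepoints: Sequence[float] | None = None,
) -> ClusterResult:
    """K-means on delta-profiles (Lloyd's algorithm, k-means++ seeding,
    best of ``n_init`` restarts; deterministic under ``seed``).

    Distances are Euclidean on the raw delta values, without scaling.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = np.asarray(df_matrix, dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct profiles")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(X)
    tps = (
        list(timepoints)
        if timepoints is not None
        else list(df_matrix.columns)
        if isinstance(df_matrix, pd.DataFrame)
        else list(range(X.shape[1]))
    )
    assignments = pd.Series(
        km.labels_,
        index=df_matrix.index if isinstance(df_matrix, pd.DataFrame) else None,
        name="cluster",
    )
    centers = pd.DataFrame(km.cluster_centers_, columns=tps)
    rows = []
    for c in range(k):
        direction, peak = summarize_cluster(centers.iloc[c].to_numpy(), tps)
        rows.append(
            {
                "cluster": c,
                "direction": direction,
                "peak_time": peak,
                "size": int((km.labels_ == c).sum()),
            }
        )
    summary = pd.DataFrame(rows)
    return ClusterResult(
        k=k,
        assignments=assignments,
        centers=centers,
        inertia=float(km.inertia_),
        summary=summary,
    )


def cluster_panel(
    panel: pd.DataFrame, k: int = 8, seed: int = 0, **kwargs
) -> tuple[ClusterResult, pd.DataFrame]:
    """Median profile -> delta transform -> k-means, returning the
    clustering and the delta matrix used."""
    f = median_profile(panel)
    df = pd.DataFrame(
        delta_transform(f.to_numpy()), index=f.index, columns=f.columns
    )
    return kmeans_cluster(df, k=k, seed=seed, **kwargs), df
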