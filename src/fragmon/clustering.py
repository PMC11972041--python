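"""Merge coincident neighboring pixel signals into clusters.

Charge sharing spreads one particle's energy deposit over adjacent pixels,
so pixel signals that are spatially adjacent and close in time are combined.
Two hits belong to the same cluster iff they are connected by a chain of
(adjacent AND |dt| <= time_window) pairs.  A cluster's timestamp is its
earliest pixel time of arrival, its energy the sum of the pixel energies,
and its 2D position the energy-weighted mean of the constituent pixel
positions (in pixel-center coordinates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

CLUSTER_COLUMNS = [
    "cluster_id",
    "layer",
    "t_ns",
    "energy_kev",
    "centroid_col",
    "centroid_row",
    "n_pixels",
]

# half neighborhoods; (0, 0) links repeated firings of the same pixel
_OFFSETS = {
    4: ((0, 0), (1, 0), (0, 1)),
    8: ((0, 0), (1, 0), (0, 1), (1, 1), (-1, 1)),
}


def cluster_hits(
    hits: pd.DataFrame, time_window_ns: float = 100.0, adjacency: int = 8
) -> tuple[pd.DataFrame, np.ndarray]:
    """Partition single-layer pixel hits into clusters.

    Returns ``(clusters, labels)`` where ``labels[i]`` is the cluster_id of
    input hit ``i`` (in the input row order).  Clusters are sorted by
    timestamp; the result is independent of the input ordering.  Empty input
    yields an empty table.
    """
    if time_window_ns <= 0:
        raise ValueError("time_window_ns must be positive")
    if adjacency not in _OFFSETS:
        raise ValueError("adjacency must be 4 or 8")
    n = len(hits)
    empty = pd.DataFrame(columns=CLUSTER_COLUMNS)
    if n == 0:
        return empty, np.array([], dtype=np.int64)
    layers = hits["layer"].unique()
    if len(layers) != 1:
        raise ValueError("cluster_hits expects hits from a single layer")

    toa = hits["toa_ns"].to_numpy(dtype=float)
    col = hits["col"].to_numpy(dtype=np.int64)
    row = hits["row"].to_numpy(dtype=np.int64)
    energy = hits["energy_kev"].to_numpy(dtype=float)

    # A cluster can never span a gap > window in its time-sorted hits (any
    # chain link across the gap would itself exceed the window), so bursts
    # separated by such gaps can be keyed independently.
    order = np.argsort(toa, kind="stable")
    burst = np.zeros(n, dtype=np.int64)
    burst[order[1:]] = np.cumsum(np.diff(toa[order]) > time_window_ns)

    left = pd.DataFrame({"burst": burst, "col": col, "row": row, "idx": np.arange(n)})
    edges_i, edges_j = [], []
    for dc, dr in _OFFSETS[adjacency]:
        right = left.copy()
        right["col"] = right["col"] + dc
        right["row"] = right["row"] + dr
        m = left.merge(right, on=["burst", "col", "row"], suffixes=("_a", "_b"))
        i = m["idx_a"].to_numpy()
        j = m["idx_b"].to_numpy()
        keep = (i != j) & (np.abs(toa[i] - toa[j]) <= time_window_ns)
        edges_i.append(i[keep])
        edges_j.append(j[keep])
    i = np.concatenate(edges_i)
    j = np.concatenate(edges_j)
    graph = coo_matrix((np.ones(len(i), dtype=np.int8), (i, j)), shape=(n, n))
    _, raw_labels = connected_components(graph, directed=False)

    n_clusters = raw_labels.max() + 1
    e_sum = np.bincount(raw_labels, weights=energy, minlength=n_clusters)
    c_col = np.bincount(raw_labels, weights=energy * col, minlength=n_clusters) / e_sum
    c_row = np.bincount(raw_labels, weights=energy * row, minlength=n_clusters) / e_sum
    n_pix = np.bincount(raw_labels, minlength=n_clusters)
    t_min = np.full(n_clusters, np.inf)
    np.minimum.at(t_min, raw_labels, toa)

    # canonical ordering: by timestamp, then centroid (tie-break only)
    rank = np.lexsort((c_row, c_col, t_min))
    remap = np.empty(n_clusters, dtype=np.int64)
    remap[rank] = np.arange(n_clusters)
    clusters = pd.DataFrame(
        {
            "cluster_id": np.arange(n_clusters),
            "layer": layers[0],
            "t_ns": t_min[rank],
            "energy_kev": e_sum[rank],
            "centroid_col": c_col[rank],
            "centroid_row": c_row[rank],
            "n_pixels": n_pix[rank],
        }
    )
    return clusters, remap[raw_labels]
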