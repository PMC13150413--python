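"""Per-frame DBSCAN clustering of selected atoms and cluster time series.

Clustering runs on the minimum-image distance matrix, so a clump straddling
a periodic boundary is one cluster. A core point has at least ``min_samples``
points (itself included) within ``eps``; clusters are connected components
of core points plus their border points; everything else is an outlier.

Two size conventions are always computed: the headline average excludes
outliers (an isolated atom is not a cluster), the inclusive variant counts
each outlier as a size-1 cluster. Cluster ids are assigned by ascending
minimal member index, so labels are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .errors import ParameterError, SelectionError
from .geometry import distance_matrix
from .parallel import map_frames
from .trajectory import CellGeometry, Frame, SelectionSpec, Trajectory, \
    resolve_selection

OUTLIER = -1


@dataclass
class ClusterParams:
    eps: float            # Å
    min_samples: int = 2

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ParameterError("eps must be positive")
        if self.min_samples < 1:
            raise ParameterError("min_samples must be >= 1")


@dataclass
class ClusterFrameStats:
    labels: np.ndarray               # per selected atom; OUTLIER = -1
    n_clusters: int
    avg_size_excl_outliers: float    # 0.0 when no clusters
    avg_size_incl_outliers: float    # outliers count as size-1 clusters
    n_outliers: int


@dataclass
class ClusterTimeSeries:
    per_frame: list[ClusterFrameStats]
    mean_n_clusters: float
    mean_size_excl: float
    mean_size_incl: float
    fragmented_frames: np.ndarray    # frames where n_clusters > modal value


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters by ascending minimal member index; outliers stay -1."""
    out = np.full_like(raw, OUTLIER)
    next_id = 0
    seen: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab == OUTLIER:
            continue
        if lab not in seen:
            seen[lab] = next_id
            next_id += 1
        out[i] = seen[lab]
    return out


def cluster_frame(frame: Frame, cell: CellGeometry, selection: SelectionSpec,
                  params: ClusterParams) -> ClusterFrameStats:
    """DBSCAN cluster statistics for one frame."""
    idx = resolve_selection(frame, selection)
    if idx.size == 0:
        raise SelectionError("cluster selection matched no atoms")
    pos = frame.positions[idx]
    dmat = distance_matrix(pos, pos, cell)
    raw = DBSCAN(eps=params.eps, min_samples=params.min_samples,
                 metric="precomputed").fit_predict(dmat)
    labels = _canonical_labels(raw)
    n_clusters = int(labels.max()) + 1 if np.any(labels != OUTLIER) else 0
    sizes = np.array([(labels == c).sum() for c in range(n_clusters)])
    n_outliers = int((labels == OUTLIER).sum())
    avg_excl = float(sizes.mean()) if n_clusters else 0.0
    all_sizes = np.concatenate([sizes, np.ones(n_outliers, dtype=int)]) \
        if (n_clusters or n_outliers) else np.array([0])
    avg_incl = float(all_sizes.mean())
    return ClusterFrameStats(labels=labels, n_clusters=n_clusters,
                             avg_size_excl_outliers=avg_excl,
                             avg_size_incl_outliers=avg_incl,
                             n_outliers=n_outliers)


def cluster_timeseries(traj: Trajectory, selection: SelectionSpec,
                       params: ClusterParams,
                       n_workers: int = 1) -> ClusterTimeSeries:
    """cluster_frame over every frame plus trajectory means.

    Frames whose cluster count exceeds the modal (most common) count are
    flagged as fragmentation events.
    """
    stats = map_frames(
        lambda k: cluster_frame(traj.frames[k], traj.cell_of(k), selection,
                                params),
        traj.n_frames, n_workers=n_workers)
    n_clusters = np.array([s.n_clusters for s in stats])
    vals, freq = np.unique(n_clusters, return_counts=True)
    modal = int(vals[np.argmax(freq)])
    return ClusterTimeSeries(
        per_frame=stats,
        mean_n_clusters=float(n_clusters.mean()),
        mean_size_excl=float(np.mean([s.avg_size_excl_outliers for s in stats])),
        mean_size_incl=float(np.mean([s.avg_size_incl_outliers for s in stats])),
        fragmented_frames=np.nonzero(n_clusters > modal)[0],
    )
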