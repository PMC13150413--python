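"""Descriptor-space farthest-point-sampling (FPS) of structure sets.

FPS greedily picks the structure farthest (max-min distance) from the
already-selected set, producing a diversity-ranked ordering: early picks
span the dataset, late picks fill in redundancy. The recorded distance of
each new pick to the selected set (the covering radius) decays as the pool
is exhausted; where it collapses, additional structures add little new
information — the basis for choosing a compact training subset.

The built-in descriptor is a histogram of all pair distances in a
structure, which is invariant under rigid translation, rotation, and atom
permutation. Richer descriptors (e.g. smooth-overlap atomic-environment
vectors from an external package) plug in through the same matrix contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .trajectory import Frame, Trajectory


@dataclass
class DescriptorMatrix:
    rows: np.ndarray        # (n_structures, dim)
    descriptor_id: str

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def dim(self) -> int:
        return self.rows.shape[1]


@dataclass
class FPSResult:
    order: np.ndarray            # ranked structure indices, length n
    min_dist_trace: np.ndarray   # distance of pick k to previous picks; inf at k=0
    start_index: int


def pair_distance_descriptor(frame: Frame, r_max: float = 6.0,
                             n_bins: int = 60) -> np.ndarray:
    """Pair-distance histogram of one structure, normalized per pair.

    Distances are raw Cartesian (no periodic images), keeping the descriptor
    exactly invariant under rigid motion. Single-atom structures have no
    pairs and give a zero vector (with a warning).
    """
    pos = frame.positions
    n = len(pos)
    if n < 2:
        warnings.warn("single-atom structure: pair descriptor is all-zero",
                      stacklevel=2)
        return np.zeros(n_bins)
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    vals = d[np.triu_indices(n, k=1)]
    hist, _ = np.histogram(vals, bins=n_bins, range=(0.0, r_max))
    return hist / vals.size


def compute_descriptors(structures, r_max: float = 6.0,
                        n_bins: int = 60) -> DescriptorMatrix:
    """One descriptor row per structure (Trajectory frames or Frame list)."""
    frames = structures.frames if isinstance(structures, Trajectory) else list(structures)
    if not frames:
        raise ParameterError("no structures to describe")
    rows = np.stack([pair_distance_descriptor(fr, r_max=r_max, n_bins=n_bins)
                     for fr in frames])
    return DescriptorMatrix(rows=rows,
                            descriptor_id=f"pairhist(r_max={r_max},n_bins={n_bins})")


def fps_rank(desc: DescriptorMatrix, n: int, start_index: int = 0,
             metric: str = "euclidean") -> FPSResult:
    """Greedy max-min FPS ordering of ``n`` structures.

    At each step the structure maximizing the minimal Euclidean distance to
    the selected set is chosen; exact ties break to the lowest index. The
    trace records that max-min distance at each pick (∞ for the seed pick).
    """
    if metric != "euclidean":
        raise ParameterError(f"unsupported metric {metric!r}")
    x = desc.rows
    total = x.shape[0]
    if not 1 <= n <= total:
        raise ParameterError(f"n must be in [1, {total}]")
    if not 0 <= start_index < total:
        raise ParameterError("start_index out of range")
    order = np.empty(n, dtype=int)
    trace = np.empty(n)
    order[0] = start_index
    trace[0] = np.inf
    min_d = np.linalg.norm(x - x[start_index], axis=1)
    min_d[start_index] = -np.inf
    for k in range(1, n):
        pick = int(np.argmax(min_d))  # argmax returns the first (lowest) index on ties
        order[k] = pick
        trace[k] = float(min_d[pick])
        d_new = np.linalg.norm(x - x[pick], axis=1)
        np.minimum(min_d, d_new, out=min_d)
        min_d[pick] = -np.inf
    return FPSResult(order=order, min_dist_trace=trace, start_index=start_index)


def diversity_curve(res: FPSResult, threshold_frac: float = 0.05):
    """Diversity-decay table and a convergence diagnostic.

    Returns ``(table, k_converged)``: table rows are ``(k, trace_k,
    normalized_trace_k)`` for k = 2..n (normalized to the first recorded
    distance), and ``k_converged`` is the smallest k whose trace falls to or
    below ``threshold_frac`` of the initial distance (None if it never does).
    """
    trace = res.min_dist_trace[1:]
    if trace.size == 0:
        raise ParameterError("FPS result holds a single pick; no curve")
    first = float(trace[0])
    normalized = trace / first if first > 0 else np.zeros_like(trace)
    ks = np.arange(2, res.order.size + 1)
    table = np.column_stack([ks, trace, normalized])
    below = np.nonzero(trace <= threshold_frac * first)[0]
    k_converged = int(ks[below[0]]) if below.size else None
    return table, k_converged
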