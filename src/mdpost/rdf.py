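"""Partial radial distribution functions and coordination numbers.

The partial RDF g_AB(r) is the density-normalized probability of finding an
atom of selection B at distance r from an atom of selection A: every frame's
minimum-image A–B distances are histogrammed and each bin divided by the
ideal-gas expectation N_A ρ_B V_shell, so an uncorrelated system gives
g ≡ 1. Selections are arbitrary (element- or index-based); when they share
atoms the cross density uses N_B − 1 (an atom is never its own neighbor).

Coordination numbers count neighbors within a cutoff sphere, where the
cutoff is fixed, taken dynamically from the first minimum of the pair RDF,
or derived per element pair from van der Waals radii.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .elements import vdw_radius
from .errors import NoMinimumError, ParameterError, SelectionError
from .geometry import distance_matrix
from .parallel import map_frames
from .trajectory import SelectionSpec, Trajectory, resolve_selection


@dataclass
class RDFResult:
    bin_edges: np.ndarray            # Å, uniform
    g: np.ndarray                    # trajectory-averaged
    pair: tuple[str, str]
    n_frames: int
    g_per_frame: np.ndarray | None = None  # (n_frames, n_bins)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class CoordinationResult:
    mean_cn: float
    per_frame_cn: np.ndarray
    cutoff_used: float               # Å (vdw mode: the mean per-pair cutoff)
    cutoff_mode: str                 # {"fixed", "dynamic", "vdw"}


def _frame_pair_histogram(traj, k, idx_a, idx_b, edges):
    """Histogram of ordered A-B min-image distances for frame k, plus the
    per-frame normalization prefactor pieces (volume)."""
    cell = traj.cell_of(k)
    pos = traj.frames[k].positions
    d = distance_matrix(pos[idx_a], pos[idx_b], cell)
    self_mask = idx_a[:, None] == idx_b[None, :]
    vals = d[~self_mask]
    counts, _ = np.histogram(vals, bins=edges)
    return counts, cell.volume


def prdf(traj: Trajectory, sel_a: SelectionSpec, sel_b: SelectionSpec,
         r_max: float = 6.0, n_bins: int | None = None,
         bin_width: float = 0.05, keep_frames: bool = False,
         n_workers: int = 1) -> RDFResult:
    """Trajectory-averaged partial RDF between selections A and B.

    Bins are uniform on [0, r_max]; by default the bin width is 0.05 Å
    (``n_bins`` overrides it). Per-frame normalization uses that frame's
    cell volume, so constant-pressure trajectories are handled correctly.
    A warning is issued when r_max exceeds half the smallest periodic cell
    height (the minimum-image count then misses farther periodic copies).
    """
    if r_max <= 0:
        raise ParameterError("r_max must be positive")
    if n_bins is None:
        n_bins = int(round(r_max / bin_width))
    if n_bins < 10:
        raise ParameterError("n_bins must be >= 10")
    idx_a = resolve_selection(traj, sel_a)
    idx_b = resolve_selection(traj, sel_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise SelectionError("RDF selection matched no atoms")
    overlap = np.intersect1d(idx_a, idx_b).size
    n_a, n_b = idx_a.size, idx_b.size
    n_b_eff = n_b - 1 if overlap else n_b
    if n_a * n_b - overlap == 0 or n_b_eff == 0:
        raise SelectionError("selections admit no cross pairs")
    cell0 = traj.cell_of(0)
    if cell0.any_periodic and r_max > 0.5 * cell0.min_height():
        warnings.warn(
            f"r_max {r_max:.3g} Å exceeds half the minimal cell height; "
            "g(r) beyond that radius undercounts periodic copies", stacklevel=2)

    edges = np.linspace(0.0, r_max, n_bins + 1)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    results = map_frames(
        lambda k: _frame_pair_histogram(traj, k, idx_a, idx_b, edges),
        traj.n_frames, n_workers=n_workers)
    per_frame = np.empty((traj.n_frames, n_bins))
    for k, (counts, volume) in enumerate(results):
        rho_b = n_b_eff / volume
        per_frame[k] = counts / (n_a * rho_b * shell)
    g = per_frame.mean(axis=0)
    return RDFResult(bin_edges=edges, g=g,
                     pair=(_sel_label(sel_a), _sel_label(sel_b)),
                     n_frames=traj.n_frames,
                     g_per_frame=per_frame if keep_frames else None)


def _sel_label(spec: SelectionSpec) -> str:
    if spec.mode == "elements":
        return "+".join(sorted(spec.elements))
    if spec.mode == "indices":
        return f"indices[{len(spec.indices)}]"
    return "all"


def first_minimum(rdf: RDFResult, search_from: float = 2.0,
                  smooth_bins: int = 5, min_depth_frac: float = 0.01) -> float:
    """Bin center of the first local minimum of g(r) after its first peak.

    g is smoothed with a ``smooth_bins``-point moving average before
    extremum detection, and the minimum must lie at least
    ``min_depth_frac`` of the first-peak height below the peak (rejects
    noise plateaus). Raises NoMinimumError when g is monotone in range.
    """
    centers = rdf.bin_centers
    kernel = np.ones(smooth_bins) / smooth_bins
    # edge-corrected moving average (same length, no boundary damping)
    s = np.convolve(rdf.g, kernel, mode="same")
    norm = np.convolve(np.ones_like(rdf.g), kernel, mode="same")
    s = s / norm

    start = int(np.searchsorted(centers, search_from))
    peak = None
    for i in range(max(start, 1), len(s) - 1):
        if s[i] >= s[i - 1] and s[i] > s[i + 1]:
            peak = i
            break
    if peak is None:
        raise NoMinimumError("g(r) has no maximum beyond search_from")
    for i in range(peak + 1, len(s) - 1):
        if s[i] <= s[i - 1] and s[i] < s[i + 1]:
            if (s[peak] - s[i]) > min_depth_frac * s[peak]:
                return float(centers[i])
    raise NoMinimumError("g(r) is monotone after its first peak; no minimum")


def _frame_cn(traj, k, idx_c, idx_n, cutoffs):
    """Mean neighbor count over centers for frame k; ``cutoffs`` is either a
    scalar or a per-(center, neighbor) matrix. Closed interval: d == cutoff
    counts as coordinated."""
    cell = traj.cell_of(k)
    pos = traj.frames[k].positions
    d = distance_matrix(pos[idx_c], pos[idx_n], cell)
    within = d <= cutoffs
    within[idx_c[:, None] == idx_n[None, :]] = False
    return float(within.sum(axis=1).mean())


def coordination_number(traj: Trajectory, centers: SelectionSpec,
                        neighbors: SelectionSpec, mode: str = "fixed",
                        cutoff: float | None = None, vdw_scale: float = 1.0,
                        vdw_overrides: dict[str, float] | None = None,
                        r_max: float = 6.0, bin_width: float = 0.05,
                        n_workers: int = 1) -> CoordinationResult:
    """Per-frame and trajectory-mean coordination number.

    modes:
      fixed    — ``cutoff`` in Å, required;
      dynamic  — cutoff from the first minimum of the centers–neighbors RDF
                 (computed once for the whole trajectory);
      vdw      — per element pair, (r_vdW(A) + r_vdW(B)) · vdw_scale.
    """
    idx_c = resolve_selection(traj, centers)
    idx_n = resolve_selection(traj, neighbors)
    if idx_c.size == 0 or idx_n.size == 0:
        raise SelectionError("coordination selection matched no atoms")

    if mode == "fixed":
        if cutoff is None or cutoff <= 0:
            raise ParameterError("fixed mode needs cutoff > 0")
        cut: float | np.ndarray = float(cutoff)
        cutoff_used = float(cutoff)
    elif mode == "dynamic":
        rdf = prdf(traj, centers, neighbors, r_max=r_max, bin_width=bin_width,
                   n_workers=n_workers)
        cutoff_used = first_minimum(rdf)
        cut = cutoff_used
    elif mode == "vdw":
        syms = traj.elements
        r_c = np.array([vdw_radius(syms[i], vdw_overrides) for i in idx_c])
        r_n = np.array([vdw_radius(syms[j], vdw_overrides) for j in idx_n])
        cut = (r_c[:, None] + r_n[None, :]) * vdw_scale
        cutoff_used = float(cut.mean())
    else:
        raise ParameterError(f"unknown coordination mode {mode!r}")

    per_frame = np.array(map_frames(
        lambda k: _frame_cn(traj, k, idx_c, idx_n, cut),
        traj.n_frames, n_workers=n_workers))
    return CoordinationResult(mean_cn=float(per_frame.mean()),
                              per_frame_cn=per_frame,
                              cutoff_used=cutoff_used, cutoff_mode=mode)
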