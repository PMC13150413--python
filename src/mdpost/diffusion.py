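"""Windowed mean-square displacement and Einstein-relation diffusion.

For diffusive motion in d dimensions the time-origin-averaged MSD grows as
``M(t) ≈ 2 d D t + b``; the self-diffusion coefficient D follows from the
slope of the linear regime. The fit splits the chosen lag interval into
contiguous sub-windows, fits a line independently in each, and reports the
mean D with its standard error across sub-windows — a single global fit is
the special case ``n_subwindows=1`` (then the SEM is undefined and reported
as 0 with ``sem_defined=False``).

Lags enter in fs and MSD in Å²; D is reported in Å²/ps (1 Å²/fs = 1000 Å²/ps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, SelectionError, UnwrapError
from .geometry import min_image_displacement
from .trajectory import SelectionSpec, Trajectory, resolve_selection

FS_PER_PS = 1000.0


@dataclass
class MSDCurve:
    lags: np.ndarray        # fs, strictly increasing, starts at 0
    msd: np.ndarray         # Å²
    n_origins: np.ndarray   # time origins averaged per lag
    mode: str = "windowed"  # {"windowed", "single_origin"}


@dataclass
class DiffusionFit:
    D: float                # Å²/ps
    sem_D: float            # Å²/ps
    intercept: float        # Å²
    dimension: int
    fit_range: tuple[float, float]  # fs
    n_subwindows: int
    sem_defined: bool = True


def unwrap(traj: Trajectory, indices) -> np.ndarray:
    """Unwrap periodic paths into continuous Cartesian trajectories.

    Returns an (n_frames, n_atoms_selected, 3) array whose frame-to-frame
    displacements equal the minimum-image displacements of the wrapped
    input. Requires every per-frame displacement to stay below half the
    smallest periodic cell height, otherwise the image choice is ambiguous.
    """
    indices = np.asarray(indices, dtype=int)
    pos = traj.positions()[:, indices, :]
    out = np.empty_like(pos)
    out[0] = pos[0]
    for k in range(1, traj.n_frames):
        cell = traj.cell_of(k)
        step = min_image_displacement(pos[k] - pos[k - 1], cell)
        if cell.any_periodic:
            limit = 0.5 * cell.min_height()
            too_far = np.linalg.norm(step, axis=1) > limit
            if np.any(too_far):
                raise UnwrapError(
                    f"frame {k}: {int(too_far.sum())} atom(s) moved farther "
                    f"than half the cell height ({limit:.3g} Å) in one stored "
                    "frame; re-read the trajectory with a smaller frame_skip")
        out[k] = out[k - 1] + step
    return out


def msd_windowed(traj: Trajectory, selection: SelectionSpec,
                 max_lag: int | None = None, origin_stride: int = 1,
                 mode: str = "windowed") -> MSDCurve:
    """Multiple-time-origin MSD of the selected atoms on unwrapped paths.

    ``M(τ)`` averages ``|r(t0+τ) − r(t0)|²`` over all origins ``t0`` (stride
    ``origin_stride``) and all selected atoms; ``mode="single_origin"``
    uses only t0 = 0. Lag 0 is included with value 0.
    """
    idx = resolve_selection(traj, selection)
    if idx.size == 0:
        raise SelectionError("MSD selection matched no atoms")
    n = traj.n_frames
    if max_lag is None:
        max_lag = n - 1
    if not 1 <= max_lag < n:
        raise ParameterError(f"max_lag must be in [1, {n - 1}]")
    paths = unwrap(traj, idx)  # (n, m, 3)

    lags = np.arange(max_lag + 1)
    msd = np.zeros(max_lag + 1)
    n_origins = np.ones(max_lag + 1, dtype=int)
    for tau in range(1, max_lag + 1):
        if mode == "single_origin":
            disp = paths[tau] - paths[0]
            msd[tau] = float(np.mean(np.sum(disp * disp, axis=-1)))
            n_origins[tau] = 1
        else:
            disp = paths[tau:] - paths[:-tau]  # (n - tau, m, 3)
            disp = disp[::origin_stride]
            msd[tau] = float(np.mean(np.sum(disp * disp, axis=-1)))
            n_origins[tau] = disp.shape[0]
    return MSDCurve(lags=lags * traj.timestep, msd=msd,
                    n_origins=n_origins, mode=mode)


def fit_diffusion(msd: MSDCurve, d: int = 3,
                  fit_range: tuple[float, float] | None = None,
                  n_subwindows: int = 5) -> DiffusionFit:
    """Einstein-relation fit M ≈ 2 d D t + b over ``fit_range`` (fs).

    The interval is split into ``n_subwindows`` contiguous equal spans of
    lag points; each gets an independent least-squares line. D is the mean
    of the sub-window slopes over 2d (converted to Å²/ps), sem_D the standard
    error of those estimates. The default range uses all available lags.
    """
    if d not in (1, 2, 3):
        raise ParameterError("dimension d must be 1, 2 or 3")
    if n_subwindows < 1:
        raise ParameterError("n_subwindows must be >= 1")
    if fit_range is None:
        fit_range = (float(msd.lags[1]), float(msd.lags[-1]))
    lo, hi = fit_range
    mask = (msd.lags >= lo) & (msd.lags <= hi)
    t = msd.lags[mask]
    y = msd.msd[mask]
    if t.size < 2 * n_subwindows:
        raise ParameterError(
            f"fit range holds {t.size} lag points; need >= {2 * n_subwindows}")

    bounds = np.linspace(0, t.size, n_subwindows + 1).astype(int)
    slopes = np.empty(n_subwindows)
    intercepts = np.empty(n_subwindows)
    for w in range(n_subwindows):
        sl = slice(bounds[w], bounds[w + 1])
        tw, yw = t[sl], y[sl]
        if tw.size < 2 or np.ptp(tw) == 0:
            raise ParameterError(f"degenerate sub-window {w} (constant lag)")
        slopes[w], intercepts[w] = np.polyfit(tw, yw, 1)

    d_estimates = slopes / (2.0 * d) * FS_PER_PS  # Å²/fs -> Å²/ps
    D = float(np.mean(d_estimates))
    if n_subwindows == 1:
        sem, defined = 0.0, False
    else:
        sem = float(np.std(d_estimates, ddof=1) / np.sqrt(n_subwindows))
        defined = True
    return DiffusionFit(D=D, sem_D=sem, intercept=float(np.mean(intercepts)),
                        dimension=d, fit_range=(float(lo), float(hi)),
                        n_subwindows=n_subwindows, sem_defined=defined)


def per_atom_msd(traj: Trajectory, selection: SelectionSpec,
                 max_lag: int | None = None) -> np.ndarray:
    """(max_lag+1, n_selected) windowed MSD per atom (Å²)."""
    idx = resolve_selection(traj, selection)
    if idx.size == 0:
        raise SelectionError("MSD selection matched no atoms")
    n = traj.n_frames
    if max_lag is None:
        max_lag = n - 1
    paths = unwrap(traj, idx)
    out = np.zeros((max_lag + 1, idx.size))
    for tau in range(1, max_lag + 1):
        disp = paths[tau:] - paths[:-tau]
        out[tau] = np.mean(np.sum(disp * disp, axis=-1), axis=0)
    return out
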