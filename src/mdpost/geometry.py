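"""Periodic-boundary geometry: minimum-image displacements and cutoff
neighbor searches.

The minimum-image convention maps a raw displacement onto its nearest
periodic image. For orthorhombic (and near-orthorhombic) cells rounding the
fractional coordinates is exact; for skewed (triclinic) cells the rounded
image is refined by an exhaustive search over the 27 neighboring images,
which is exact whenever the relevant distances stay below half the smallest
perpendicular cell height.
"""

from __future__ import annotations

import warnings

import numpy as np

from .trajectory import CellGeometry, Frame


def _image_shifts(periodic: tuple[bool, bool, bool]) -> np.ndarray:
    """Integer fractional shifts over {-1,0,1} on periodic axes only."""
    axes = [(-1, 0, 1) if p else (0,) for p in periodic]
    grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    return grid.astype(float)


def min_image_displacement(disp, cell: CellGeometry) -> np.ndarray:
    """Map displacement vectors (…, 3) onto their minimum periodic image.

    Non-periodic axes are left untouched. Accepts a single vector or any
    array with trailing dimension 3; the shape is preserved.
    """
    d = np.asarray(disp, dtype=float)
    single = d.ndim == 1
    d = np.atleast_2d(d)
    if not cell.any_periodic:
        return d[0] if single else d

    inv = cell.inverse()
    frac = d @ inv
    mask = np.array(cell.periodic)
    frac[..., mask] -= np.round(frac[..., mask])
    out = frac @ cell.vectors

    if not cell.is_orthorhombic:
        shifts = _image_shifts(cell.periodic) @ cell.vectors  # (m, 3)
        cand = out[..., None, :] + shifts  # (..., m, 3)
        norms = np.einsum("...mi,...mi->...m", cand, cand)
        best = np.argmin(norms, axis=-1)
        out = np.take_along_axis(cand, best[..., None, None], axis=-2)[..., 0, :]
    return out[0] if single else out


def displacement(p, q, cell: CellGeometry) -> np.ndarray:
    """Minimum-image displacement q - p (Å)."""
    return min_image_displacement(np.asarray(q, float) - np.asarray(p, float), cell)


def distance(p, q, cell: CellGeometry) -> float:
    return float(np.linalg.norm(displacement(p, q, cell)))


def pairwise_displacements(pos_a: np.ndarray, pos_b: np.ndarray,
                           cell: CellGeometry) -> np.ndarray:
    """(len(a), len(b), 3) matrix of min-image displacements b - a."""
    raw = pos_b[None, :, :] - pos_a[:, None, :]
    return min_image_displacement(raw, cell)


def distance_matrix(pos_a: np.ndarray, pos_b: np.ndarray,
                    cell: CellGeometry) -> np.ndarray:
    """(len(a), len(b)) min-image distance matrix (Å)."""
    disp = pairwise_displacements(pos_a, pos_b, cell)
    return np.sqrt(np.einsum("ijk,ijk->ij", disp, disp))


def neighbor_pairs(frame: Frame, cell: CellGeometry, idx_a, idx_b,
                   cutoff: float) -> list[tuple[int, int, float]]:
    """All pairs (i in idx_a, j in idx_b, i != j) with min-image distance
    <= cutoff (Å, closed interval), each unordered pair reported once when
    the selections overlap, sorted by (i, j).

    A cutoff beyond half the smallest periodic cell height makes the nearest
    image ambiguous; a warning is issued and distances are still computed
    over the neighboring-image search.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    if cell.any_periodic and cutoff > 0.5 * cell.min_height():
        warnings.warn(
            f"cutoff {cutoff:.3g} Å exceeds half the minimal cell height "
            f"({0.5 * cell.min_height():.3g} Å); nearest-image distances may "
            "miss farther periodic copies", stacklevel=2)
    dmat = distance_matrix(frame.positions[idx_a], frame.positions[idx_b], cell)
    set_a, set_b = set(idx_a.tolist()), set(idx_b.tolist())
    pairs: list[tuple[int, int, float]] = []
    for ai, i in enumerate(idx_a):
        for bj, j in enumerate(idx_b):
            if i == j or dmat[ai, bj] > cutoff:
                continue
            # both orientations representable -> keep only i < j
            if j in set_a and i in set_b and i > j:
                continue
            pairs.append((int(i), int(j), float(dmat[ai, bj])))
    pairs.sort(key=lambda t: (t[0], t[1]))
    return pairs


def wrap_positions(positions: np.ndarray, cell: CellGeometry) -> np.ndarray:
    """Wrap Cartesian positions into the primary cell along periodic axes
    (fractional coordinates mapped to [0, 1) by flooring)."""
    if not cell.any_periodic:
        return np.array(positions, dtype=float)
    frac = np.asarray(positions, float) @ cell.inverse()
    mask = np.array(cell.periodic)
    frac[..., mask] -= np.floor(frac[..., mask])
    return frac @ cell.vectors
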