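"""Volumetric occupancy / probability density of selected atoms.

Every selected atom in every frame is wrapped into the cell by fractional
coordinate and binned on an (nx, ny, nz) grid with half-open [0, 1) voxels
(an atom exactly on a voxel boundary lands in the higher-index voxel).
``density = counts / (n_samples · voxel_volume)`` integrates to 1 over the
cell; axis-plane projections integrate to 1 over their plane.

Output formats: long-form CSV and Gaussian cube (for standard volumetric
viewers). For non-periodic structures the grid spans the axis-aligned
bounding box of the selected atoms over the whole trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import atomic_number
from .errors import GeometryError, SelectionError
from .trajectory import CellGeometry, SelectionSpec, Trajectory, resolve_selection

_PLANES = {"XY": 2, "XZ": 1, "YZ": 0}
BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


@dataclass
class DensityGrid:
    counts: np.ndarray       # (nx, ny, nz) occupancy
    density: np.ndarray      # probability per Å³
    cell: CellGeometry
    n_samples: int

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.counts.shape)  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / np.prod(self.grid_shape)


def density_grid(traj: Trajectory, selection: SelectionSpec,
                 grid_shape=(50, 50, 50)) -> DensityGrid:
    """3D occupancy histogram of the selected atoms over the whole trajectory."""
    shape = tuple(int(g) for g in grid_shape)
    if len(shape) != 3 or any(g < 2 for g in shape):
        raise GeometryError("grid needs three dimensions of size >= 2")
    idx = resolve_selection(traj, selection)
    if idx.size == 0:
        raise SelectionError("density selection matched no atoms")

    cell = traj.cell
    if not all(cell.periodic):
        pts = traj.positions()[:, idx, :].reshape(-1, 3)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        # pad so boundary atoms bin inside the half-open grid
        span = span * (1.0 + 1e-9)
        cell = CellGeometry(np.diag(span), (True, True, True))
        origin = lo
    else:
        origin = np.zeros(3)

    inv = cell.inverse()
    counts = np.zeros(shape, dtype=np.int64)
    nvec = np.array(shape)
    for k in range(traj.n_frames):
        frac = (traj.frames[k].positions[idx] - origin) @ inv
        frac -= np.floor(frac)
        vox = np.floor(frac * nvec).astype(int)
        vox = np.clip(vox, 0, nvec - 1)  # guards frac == 1.0 after rounding
        np.add.at(counts, (vox[:, 0], vox[:, 1], vox[:, 2]), 1)
    n_samples = int(counts.sum())
    voxel_vol = cell.volume / np.prod(shape)
    density = counts / (n_samples * voxel_vol)
    grid = DensityGrid(counts=counts, density=density, cell=cell,
                       n_samples=n_samples)
    grid.origin = origin  # type: ignore[attr-defined]
    return grid


def project_density(grid: DensityGrid, plane: str = "XY") -> np.ndarray:
    """2D marginal density onto an axis plane (probability per Å²).

    Summing over the orthogonal axis weighted by the voxel extent along it
    turns the volume density into a plane density that integrates to 1.
    """
    plane = plane.upper()
    if plane not in _PLANES:
        raise GeometryError(f"plane must be one of {sorted(_PLANES)}")
    axis = _PLANES[plane]
    extent = np.linalg.norm(grid.cell.vectors[axis]) / grid.grid_shape[axis]
    return grid.density.sum(axis=axis) * extent


def write_cube(path, grid: DensityGrid, frame=None) -> None:
    """Write the density as a Gaussian cube file (values in Å⁻³ on a grid
    whose axes are the cell vectors; positions converted to Bohr as the
    format requires). ``frame`` optionally supplies atoms to embed."""
    shape = grid.grid_shape
    steps = grid.cell.vectors / np.array(shape)[:, None] * BOHR_PER_ANGSTROM
    origin = getattr(grid, "origin", np.zeros(3)) * BOHR_PER_ANGSTROM
    atoms = [] if frame is None else list(zip(frame.elements, frame.positions))
    with open(path, "w") as fh:
        fh.write("mdpost volumetric density\nprobability density (1/A^3)\n")
        fh.write(f"{len(atoms):5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}\n")
        for ax in range(3):
            fh.write(f"{shape[ax]:5d} {steps[ax,0]:12.6f} {steps[ax,1]:12.6f} "
                     f"{steps[ax,2]:12.6f}\n")
        for sym, pos in atoms:
            z = atomic_number(sym)
            pb = np.asarray(pos) * BOHR_PER_ANGSTROM
            fh.write(f"{z:5d} {float(z):12.6f} {pb[0]:12.6f} {pb[1]:12.6f} {pb[2]:12.6f}\n")
        flat = grid.density.reshape(shape[0] * shape[1], shape[2])
        for row in flat:
            for start in range(0, row.size, 6):
                fh.write(" ".join(f"{v:13.5E}" for v in row[start:start + 6]) + "\n")
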