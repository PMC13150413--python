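"""Trajectory data model: simulation cell, frames, trajectories, atom selections.

Units follow the package-wide convention: distances in angstrom (Å), times in
femtoseconds (fs). Atom indices are 0-based everywhere. Coordinates are
Cartesian; fractional coordinates appear only inside geometry routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, SelectionError, StructuralError


@dataclass(frozen=True)
class CellGeometry:
    """Simulation cell: a 3x3 lattice matrix (rows are cell vectors, Å) plus
    per-axis periodicity flags.

    A fully non-periodic cell may carry a zero matrix; any periodic axis must
    have a cell vector of nonzero length, and a fully periodic cell must have
    positive volume.
    """

    vectors: np.ndarray
    periodic: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float).reshape(3, 3)
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "periodic", tuple(bool(p) for p in self.periodic))
        for ax, p in enumerate(self.periodic):
            if p and np.linalg.norm(v[ax]) == 0.0:
                raise GeometryError(f"periodic axis {ax} has a zero cell vector")
        if all(self.periodic) and abs(np.linalg.det(v)) <= 0.0:
            raise GeometryError("fully periodic cell has zero volume")

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.vectors)))

    @property
    def any_periodic(self) -> bool:
        return any(self.periodic)

    @property
    def is_orthorhombic(self) -> bool:
        off = self.vectors - np.diag(np.diag(self.vectors))
        return bool(np.all(np.abs(off) < 1e-10))

    def heights(self) -> np.ndarray:
        """Perpendicular cell heights (Å) along the three axes.

        Height i is the distance between the two cell faces spanned by the
        other two vectors: V / |a_j x a_k|. Infinite along non-periodic axes.
        """
        v = self.vectors
        h = np.full(3, np.inf)
        for i in range(3):
            if not self.periodic[i]:
                continue
            j, k = (i + 1) % 3, (i + 2) % 3
            cross = np.cross(v[j], v[k])
            area = np.linalg.norm(cross)
            if area == 0.0:
                # degenerate companion vectors (e.g. partially periodic cell):
                # fall back to the vector length itself
                h[i] = np.linalg.norm(v[i])
            else:
                h[i] = abs(float(np.dot(v[i], cross))) / area
        return h

    def min_height(self) -> float:
        """Smallest perpendicular height over the periodic axes (Å)."""
        return float(np.min(self.heights()))

    def inverse(self) -> np.ndarray:
        try:
            return np.linalg.inv(self.vectors)
        except np.linalg.LinAlgError as exc:
            raise GeometryError("singular cell matrix with periodic flags") from exc

    @classmethod
    def cubic(cls, length: float, periodic: bool = True) -> "CellGeometry":
        return cls(np.eye(3) * float(length), (periodic,) * 3)

    @classmethod
    def nonperiodic(cls) -> "CellGeometry":
        return cls(np.zeros((3, 3)), (False, False, False))


@dataclass
class Frame:
    """One snapshot: N x 3 Cartesian positions (Å), N element symbols, and an
    optional timestamp (fs)."""

    positions: np.ndarray
    elements: list[str]
    time: float | None = None
    cell: CellGeometry | None = None  # per-frame cell (NPT); else trajectory cell

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.positions)):
            raise StructuralError("non-finite coordinates in frame")
        if len(self.elements) != len(self.positions):
            raise StructuralError(
                f"{len(self.elements)} element symbols for {len(self.positions)} positions"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


@dataclass
class Trajectory:
    """Ordered frames with identical atom count/element ordering, a shared
    cell (individual frames may override it), and the time step between
    *stored* frames in fs."""

    frames: list[Frame]
    cell: CellGeometry
    timestep: float = 1.0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise StructuralError("timestep must be positive")
        if not self.frames:
            raise StructuralError("trajectory has no frames")
        ref = self.frames[0]
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != ref.n_atoms:
                raise StructuralError(
                    f"frame {k} has {fr.n_atoms} atoms, frame 0 has {ref.n_atoms}"
                )
            if fr.elements != ref.elements:
                raise StructuralError(f"frame {k} changes the element ordering")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def elements(self) -> list[str]:
        return self.frames[0].elements

    def cell_of(self, frame_index: int) -> CellGeometry:
        fr = self.frames[frame_index]
        return fr.cell if fr.cell is not None else self.cell

    def positions(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) position array."""
        return np.stack([fr.positions for fr in self.frames])

    def times(self) -> np.ndarray:
        """Frame timestamps in fs; index * timestep where not stored."""
        return np.array(
            [fr.time if fr.time is not None else k * self.timestep
             for k, fr in enumerate(self.frames)]
        )


@dataclass
class SelectionSpec:
    """Atom selection: by element symbols, by explicit 0-based indices, or all."""

    mode: str = "all"  # {"all", "elements", "indices"}
    elements: frozenset[str] = field(default_factory=frozenset)
    indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("all", "elements", "indices"):
            raise SelectionError(f"unknown selection mode {self.mode!r}")
        self.elements = frozenset(self.elements)
        self.indices = tuple(int(i) for i in self.indices)
        if self.mode == "elements" and not self.elements:
            raise SelectionError("element selection with empty symbol set")

    @classmethod
    def of_elements(cls, *symbols: str) -> "SelectionSpec":
        return cls(mode="elements", elements=frozenset(symbols))

    @classmethod
    def of_indices(cls, indices) -> "SelectionSpec":
        return cls(mode="indices", indices=tuple(indices))

    @classmethod
    def everything(cls) -> "SelectionSpec":
        return cls(mode="all")


def resolve_selection(traj: Trajectory | Frame, spec: SelectionSpec) -> np.ndarray:
    """Resolve a SelectionSpec against a trajectory (or single frame) into a
    sorted, deduplicated array of 0-based atom indices.

    An element selection matching zero atoms yields an empty array (callers
    that need atoms raise SelectionError); an explicit index >= N is an error.
    """
    elements = traj.elements
    n = len(elements)
    if spec.mode == "all":
        return np.arange(n)
    if spec.mode == "elements":
        return np.array(
            [i for i, sym in enumerate(elements) if sym in spec.elements], dtype=int
        )
    idx = np.unique(np.asarray(spec.indices, dtype=int))
    if idx.size and (idx[0] < 0 or idx[-1] >= n):
        raise SelectionError(f"selection index out of range for {n} atoms")
    return idx
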