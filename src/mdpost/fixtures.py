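"""Seeded synthetic-input generators with analytic ground truth.

Each generator emulates one input class the analyses consume and records the
truth the analysis should recover:

* AR(1) series — known autocorrelation φ^k and statistical inefficiency
  (1+φ)/(1−φ), ground truth for the error estimators;
* periodic Brownian walkers — known diffusion coefficient D, ground truth
  for windowed MSD and the Einstein fit (the raw unwrapped paths are kept so
  the wrap/unwrap round trip is checkable exactly);
* simple-cubic lattices — known nearest-neighbor shell (6 at spacing a);
* constructed water dimers/chains — exact H-bond geometry by parameter;
* Gaussian clumps — known cluster memberships;
* uniform ideal gas — g(r) ≡ 1 and flat densities.

All generators take an integer seed and are bit-reproducible for a fixed
seed (numpy PCG64 streams, one per call).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .convergence import TimeSeries
from .errors import ParameterError
from .geometry import wrap_positions
from .trajectory import CellGeometry, Frame, Trajectory

FS_PER_PS = 1000.0


def make_ar1(n: int, phi: float, sigma: float = 1.0,
             seed: int = 0, dt: float = 1.0) -> TimeSeries:
    """Stationary AR(1) series x_{t+1} = φ x_t + ε, ε ~ N(0, σ²).

    Analytic truths: ACF(k) = φ^k, statistical inefficiency
    g = (1+φ)/(1−φ), stationary variance σ²/(1−φ²).
    """
    if not abs(phi) < 1:
        raise ParameterError("AR(1) needs |phi| < 1 for stationarity")
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma / np.sqrt(1.0 - phi * phi))
    eps = rng.normal(0.0, sigma, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return TimeSeries(x, dt=dt, label=f"ar1(phi={phi})")


@dataclass
class BrownianFixture:
    trajectory: Trajectory       # wrapped into the periodic box
    paths: np.ndarray            # raw unwrapped paths (n_frames, n_atoms, 3)
    D: float                     # true diffusion coefficient, Å²/ps


def make_brownian(n_atoms: int = 64, n_frames: int = 500, D: float = 0.23,
                  dt: float = 1.0, box: float = 10.0, seed: int = 0,
                  element: str = "O") -> BrownianFixture:
    """Independent Brownian walkers in a periodic cubic box.

    Per-axis step variance is 2 D Δt (D in Å²/ps, dt in fs), so the
    ensemble MSD is 6 D τ in three dimensions. Steps must stay below a
    quarter box so unwrapping is unambiguous.
    """
    step_std = np.sqrt(2.0 * D * dt / FS_PER_PS)
    if D > 0 and step_std >= box / 4.0:
        raise ParameterError(
            f"step std {step_std:.3g} Å too large for box {box:g} Å; "
            "lower D·dt or enlarge the box")
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, box, size=(n_atoms, 3))
    steps = rng.normal(0.0, step_std, size=(n_frames - 1, n_atoms, 3))
    paths = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    cell = CellGeometry.cubic(box)
    frames = [Frame(wrap_positions(p, cell), [element] * n_atoms,
                    time=k * dt) for k, p in enumerate(paths)]
    return BrownianFixture(Trajectory(frames, cell, timestep=dt), paths, D)


def make_lattice(a: float = 3.0, n: int = 3, element: str = "Pt",
                 periodic: bool = True) -> tuple[Frame, CellGeometry]:
    """n×n×n simple-cubic lattice with spacing a (Å) in an (n·a)³ box.

    Under periodic boundaries every atom has exactly 6 nearest neighbors at
    distance a.
    """
    grid = np.arange(n) * a
    pos = np.array(np.meshgrid(grid, grid, grid, indexing="ij")).reshape(3, -1).T
    cell = CellGeometry.cubic(n * a, periodic=periodic)
    return Frame(pos, [element] * len(pos)), cell


_WATER_HOH_DEG = 104.5
_WATER_OH = 0.96


def _acceptor_hydrogens(o_pos, away_dir):
    """Two H at 0.96 Å fanned ±52.25° off ``away_dir`` (unit vector), in the
    plane spanned by away_dir and a perpendicular axis — they point away from
    whatever lies opposite ``away_dir``, so they cannot donate back."""
    away = np.asarray(away_dir, float)
    away = away / np.linalg.norm(away)
    perp = np.cross(away, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(away, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    half = np.radians(_WATER_HOH_DEG / 2.0)
    h1 = o_pos + _WATER_OH * (np.cos(half) * away + np.sin(half) * perp)
    h2 = o_pos + _WATER_OH * (np.cos(half) * away - np.sin(half) * perp)
    return h1, h2


def make_water_dimer(d_ha: float = 1.85, angle: float = 180.0,
                     box: float = 20.0) -> tuple[Frame, CellGeometry]:
    """Two waters with one D–H···A contact of exact geometry.

    The donor O sits at the box center with its donating H at 0.96 Å along
    +x; the acceptor O is placed so the H···A distance is ``d_ha`` (Å) and
    the internal D–H···A angle is ``angle`` (degrees, 180 = linear). The
    remaining hydrogens point away and form no bonds.
    """
    th = np.radians(angle)
    center = np.full(3, box / 2.0)
    o_d = center
    h_d = o_d + np.array([_WATER_OH, 0.0, 0.0])
    # direction from H making the requested angle with H->donor (-x)
    dir_a = np.array([-np.cos(th), np.sin(th), 0.0])
    o_a = h_d + d_ha * dir_a
    h2_d = o_d + _WATER_OH * np.array([np.cos(np.radians(_WATER_HOH_DEG)),
                                       np.sin(np.radians(_WATER_HOH_DEG)), 0.0]) * -1.0
    away = (o_a - o_d) / np.linalg.norm(o_a - o_d)
    h1_a, h2_a = _acceptor_hydrogens(o_a, away)
    pos = np.array([o_d, h_d, h2_d, o_a, h1_a, h2_a])
    elements = ["O", "H", "H", "O", "H", "H"]
    return Frame(pos, elements), CellGeometry.cubic(box)


def make_water_chain(n_molecules: int = 4, r_oo: float = 2.8,
                     box: float | None = None) -> tuple[Frame, CellGeometry]:
    """Linear chain A→B→…: each molecule donates one H-bond to the next.

    Molecule i's oxygen sits at (i·r_oo, 0, 0) with one H at 0.96 Å toward
    the next oxygen (perfectly linear bond, H···O distance r_oo − 0.96);
    the second H points off-axis and bonds to nothing. A chain of k
    molecules therefore has exactly k−1 hydrogen bonds.
    """
    if box is None:
        box = n_molecules * r_oo + 10.0
    off = np.full(3, 5.0)
    positions = []
    elements = []
    tilt = np.radians(_WATER_HOH_DEG)
    for i in range(n_molecules):
        o = off + np.array([i * r_oo, 0.0, 0.0])
        h_don = o + np.array([_WATER_OH, 0.0, 0.0])
        h_other = o + _WATER_OH * np.array([np.cos(tilt), np.sin(tilt), 0.0])
        positions += [o, h_don, h_other]
        elements += ["O", "H", "H"]
    return Frame(np.array(positions), elements), CellGeometry.cubic(box)


def make_water_box(n_molecules: int = 64, box: float = 12.5, seed: int = 0,
                   min_oo: float = 2.4) -> tuple[Frame, CellGeometry]:
    """Random rigid waters in a periodic cube (geometry, not physics).

    Oxygen positions are rejection-sampled to keep all min-image O–O
    distances above ``min_oo``; each molecule gets a random rigid
    orientation with the gas-phase 0.96 Å / 104.5° internal geometry.
    """
    rng = np.random.default_rng(seed)
    cell = CellGeometry.cubic(box)
    oxygens: list[np.ndarray] = []
    attempts = 0
    while len(oxygens) < n_molecules:
        cand = rng.uniform(0.0, box, size=3)
        ok = True
        for o in oxygens:
            d = cand - o
            d -= box * np.round(d / box)
            if np.linalg.norm(d) < min_oo:
                ok = False
                break
        if ok:
            oxygens.append(cand)
        attempts += 1
        if attempts > 200000:
            raise ParameterError("cannot place molecules; box too dense")
    positions = []
    elements = []
    half = np.radians(_WATER_HOH_DEG / 2.0)
    for o in oxygens:
        # random orthonormal pair via QR of a Gaussian matrix
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        u, v = q[:, 0], q[:, 1]
        h1 = o + _WATER_OH * (np.cos(half) * u + np.sin(half) * v)
        h2 = o + _WATER_OH * (np.cos(half) * u - np.sin(half) * v)
        positions += [o, h1, h2]
        elements += ["O", "H", "H"]
    return Frame(np.array(positions), elements), cell


def make_clustered_points(k: int = 3, n_per: int = 10, spread: float = 0.3,
                          sep: float = 6.0, seed: int = 0,
                          element: str = "Pt", box: float | None = None):
    """k isotropic Gaussian clumps of n_per atoms with known memberships.

    Clump centers are sep apart along the box diagonal. Returns
    (Frame, CellGeometry, true_labels). Well-separated clusters need
    sep > spread by a wide margin; sep < 4·spread draws a warning.
    """
    import warnings

    if sep < 4.0 * spread:
        warnings.warn("clumps overlap (sep < 4·spread); memberships are "
                      "not clean ground truth", stacklevel=2)
    if box is None:
        box = (k + 1) * sep
    rng = np.random.default_rng(seed)
    positions = []
    labels = []
    for c in range(k):
        center = np.full(3, (c + 0.5) * sep)
        positions.append(center + rng.normal(0.0, spread, size=(n_per, 3)))
        labels += [c] * n_per
    pos = np.concatenate(positions)
    cell = CellGeometry.cubic(box)
    return Frame(pos, [element] * len(pos)), cell, np.array(labels)


def make_uniform_gas(n_atoms: int = 500, n_frames: int = 50,
                     box: float = 15.0, seed: int = 0,
                     element: str = "Ar") -> Trajectory:
    """Ideal-gas trajectory: fresh uniform positions every frame (g(r) ≡ 1)."""
    rng = np.random.default_rng(seed)
    cell = CellGeometry.cubic(box)
    frames = [Frame(rng.uniform(0.0, box, size=(n_atoms, 3)),
                    [element] * n_atoms) for _ in range(n_frames)]
    return Trajectory(frames, cell, timestep=1.0)


def as_trajectory(frame: Frame, cell: CellGeometry, n_frames: int = 1,
                  timestep: float = 1.0) -> Trajectory:
    """Repeat a static frame into a trajectory (frames share the geometry)."""
    frames = [Frame(frame.positions.copy(), list(frame.elements),
                    time=k * timestep) for k in range(n_frames)]
    return Trajectory(frames, cell, timestep=timestep)
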