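"""Geometric hydrogen-bond detection and graph-based network statistics.

A hydrogen bond D–H···A is assigned when the hydrogen sits covalently on a
donor (nearest donor within ``dh_cut``), the minimum-image H···A distance is
at most ``d_ha_cut``, and the internal D–H···A angle (180° = linear) is at
least ``angle_cut``. Defaults (d_HA ≤ 2.5 Å, angle ≥ 130°, D–H ≤ 1.2 Å) are
a standard water criterion; all three are parameters.

Per-frame bond lists feed a molecule-level graph (heavy atoms as vertices,
bonds as edges) whose connected components describe the network. The
headline per-molecule average counts each bond for both partner molecules
(donated + accepted), the convention under which bulk water averages ≈ 3.8;
``per_molecule="donated"`` counts donations only.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import SelectionError
from .geometry import distance_matrix, min_image_displacement
from .parallel import map_frames
from .trajectory import (CellGeometry, Frame, SelectionSpec, Trajectory,
                         resolve_selection)


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    d_ha: float       # Å
    angle_dha: float  # degrees, 180 = linear


@dataclass
class HBondStats:
    per_frame_counts: np.ndarray
    avg_per_molecule: float
    std_per_molecule: float          # across frames
    components_per_frame: np.ndarray
    n_molecules: int
    bonds_per_frame: list[list[HBond]]


def assign_covalent_hydrogens(frame: Frame, cell: CellGeometry,
                              donors: SelectionSpec, dh_cut: float = 1.2,
                              hydrogen_symbol: str = "H") -> dict[int, list[int]]:
    """Map each donor atom to its covalently bound hydrogens.

    Every hydrogen attaches to its *nearest* donor candidate within
    ``dh_cut`` (Å); equidistant ties break deterministically to the lower
    donor index. Hydrogens with no donor in range stay unassigned.
    """
    donor_idx = resolve_selection(frame, donors)
    h_idx = np.array([i for i, s in enumerate(frame.elements)
                      if s == hydrogen_symbol], dtype=int)
    mapping: dict[int, list[int]] = {int(d): [] for d in donor_idx}
    if donor_idx.size == 0 or h_idx.size == 0:
        return mapping
    d = distance_matrix(frame.positions[h_idx], frame.positions[donor_idx], cell)
    for hi, h in enumerate(h_idx):
        row = d[hi]
        best = float(row.min())
        if best > dh_cut:
            continue
        nearest = int(donor_idx[np.nonzero(row == best)[0][0]])  # lowest index tie-break
        mapping[nearest].append(int(h))
    return mapping


def find_hbonds(frame: Frame, cell: CellGeometry, donors: SelectionSpec,
                acceptors: SelectionSpec, d_ha_cut: float = 2.5,
                angle_cut: float = 130.0, dh_cut: float = 1.2) -> list[HBond]:
    """All hydrogen bonds in one frame, sorted by (donor, hydrogen, acceptor).

    Geometry is minimum-image throughout, so bonds across periodic
    boundaries are found. An acceptor never bonds to its own hydrogen's
    donor (donor != acceptor).
    """
    donor_idx = resolve_selection(frame, donors)
    acceptor_idx = resolve_selection(frame, acceptors)
    if donor_idx.size == 0 or acceptor_idx.size == 0:
        raise SelectionError("empty donor or acceptor selection")
    dh_map = assign_covalent_hydrogens(frame, cell, donors, dh_cut=dh_cut)
    pos = frame.positions
    bonds: list[HBond] = []
    for d_atom, hydrogens in dh_map.items():
        for h in hydrogens:
            v_d = min_image_displacement(pos[d_atom] - pos[h], cell)
            n_d = np.linalg.norm(v_d)
            v_a = min_image_displacement(pos[acceptor_idx] - pos[h], cell)
            dist = np.linalg.norm(v_a, axis=1)
            for ai, a_atom in enumerate(acceptor_idx):
                if a_atom == d_atom or dist[ai] > d_ha_cut:
                    continue
                cosang = float(np.dot(v_d, v_a[ai]) / (n_d * dist[ai]))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle >= angle_cut:
                    bonds.append(HBond(int(d_atom), int(h), int(a_atom),
                                       float(dist[ai]), angle))
    bonds.sort(key=lambda b: (b.donor, b.hydrogen, b.acceptor))
    return bonds


def hbond_stats(traj: Trajectory, donors: SelectionSpec,
                acceptors: SelectionSpec, d_ha_cut: float = 2.5,
                angle_cut: float = 130.0, dh_cut: float = 1.2,
                per_molecule: str = "both", n_workers: int = 1) -> HBondStats:
    """Per-frame bond counts, per-molecule averages, and network components.

    Molecules are identified with their heavy atoms (union of the donor and
    acceptor selections). ``per_molecule="both"`` counts each bond for donor
    and acceptor molecule (2·bonds/n_molecules per frame); ``"donated"``
    counts each bond once.
    """
    donor_idx = resolve_selection(traj, donors)
    acceptor_idx = resolve_selection(traj, acceptors)
    molecules = sorted(set(donor_idx.tolist()) | set(acceptor_idx.tolist()))
    if not molecules:
        raise SelectionError("no molecules in donor/acceptor selections")
    factor = 2.0 if per_molecule == "both" else 1.0

    def one_frame(k: int):
        frame = traj.frames[k]
        cell = traj.cell_of(k)
        bonds = find_hbonds(frame, cell, donors, acceptors,
                            d_ha_cut=d_ha_cut, angle_cut=angle_cut,
                            dh_cut=dh_cut)
        graph = nx.Graph()
        graph.add_nodes_from(molecules)
        graph.add_edges_from((b.donor, b.acceptor) for b in bonds)
        return bonds, nx.number_connected_components(graph)

    results = map_frames(one_frame, traj.n_frames, n_workers=n_workers)
    bonds_per_frame = [r[0] for r in results]
    counts = np.array([len(b) for b in bonds_per_frame], dtype=float)
    comps = np.array([r[1] for r in results], dtype=int)
    per_mol = factor * counts / len(molecules)
    return HBondStats(
        per_frame_counts=counts.astype(int),
        avg_per_molecule=float(per_mol.mean()),
        std_per_molecule=float(per_mol.std(ddof=0)),
        components_per_frame=comps,
        n_molecules=len(molecules),
        bonds_per_frame=bonds_per_frame,
    )
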