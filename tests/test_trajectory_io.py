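"""Trajectory model, extended-XYZ I/O, selections, and periodic geometry."""

import numpy as np
import pytest

import mdpost
from mdpost import CellGeometry, Frame, SelectionSpec, Trajectory
from mdpost.errors import ParseError, SelectionError, StructuralError
from mdpost.geometry import distance_matrix, min_image_displacement, \
    neighbor_pairs
from mdpost.io_xyz import read_trajectory, write_trajectory


def brute_min_image(disp, cell):
    """Exhaustive 27-image oracle for the minimum-image displacement."""
    best = None
    shifts = [(-1, 0, 1) if p else (0,) for p in cell.periodic]
    # map into the rounded central image first so the 27-image scan suffices
    inv = np.linalg.inv(cell.vectors)
    frac = np.asarray(disp, float) @ inv
    mask = np.array(cell.periodic)
    frac[mask] -= np.round(frac[mask])
    base = frac @ cell.vectors
    for i in shifts[0]:
        for j in shifts[1]:
            for k in shifts[2]:
                cand = base + np.array([i, j, k], float) @ cell.vectors
                if best is None or np.linalg.norm(cand) < np.linalg.norm(best):
                    best = cand
    return best


def write_frames(path, blocks):
    path.write_text("".join(blocks))
    return path


EXT_FRAME = (
    "2\n"
    'Lattice="10 0 0 0 10 0 0 0 10" Properties=species:S:1:pos:R:3 pbc="T T T"\n'
    "O 1.0 1.0 1.0\nH 2.0 1.0 1.0\n"
)


class TestReadWrite:
    def test_frame_skip_keeps_every_kth_frame(self, tmp_path):
        path = write_frames(tmp_path / "t.extxyz", [EXT_FRAME] * 5)
        traj = read_trajectory(path, frame_skip=2)
        assert traj.n_frames == 3
        assert traj.timestep == 2.0  # file timestep 1 fs x skip

    def test_lattice_and_pbc_parsed(self, tmp_path):
        path = write_frames(tmp_path / "t.extxyz", [EXT_FRAME])
        traj = read_trajectory(path)
        assert np.allclose(traj.cell.vectors, np.eye(3) * 10)
        assert traj.cell.periodic == (True, True, True)
        assert traj.elements == ["O", "H"]

    def test_plain_xyz_is_nonperiodic(self, tmp_path):
        path = write_frames(tmp_path / "t.xyz",
                            ["2\ncomment\nO 0 0 0\nH 1 0 0\n"])
        traj = read_trajectory(path)
        assert traj.cell.periodic == (False, False, False)

    def test_declared_atom_count_mismatch_names_frame(self, tmp_path):
        bad = "4\ncomment\nO 0 0 0\nH 1 0 0\nH 2 0 0\n"
        path = write_frames(tmp_path / "t.xyz", [EXT_FRAME, EXT_FRAME, bad])
        with pytest.raises(ParseError, match="frame 2"):
            read_trajectory(path)

    def test_inconsistent_atom_count_across_frames(self, tmp_path):
        other = "1\ncomment\nO 0 0 0\n"
        path = write_frames(tmp_path / "t.xyz", [EXT_FRAME, other])
        with pytest.raises(StructuralError):
            read_trajectory(path)

    def test_round_trip_preserves_positions_and_symbols(self, tmp_path):
        rng = np.random.default_rng(11)
        cell = CellGeometry.cubic(8.0)
        frames = [Frame(rng.uniform(0, 8, (7, 3)),
                        ["Si", "O", "O", "H", "H", "Al", "Na"])
                  for _ in range(4)]
        traj = Trajectory(frames, cell, timestep=0.5)
        path = tmp_path / "rt.extxyz"
        write_trajectory(path, traj)
        back = read_trajectory(path, timestep=0.5)
        assert back.elements == traj.elements
        assert back.cell.periodic == cell.periodic
        for a, b in zip(traj.frames, back.frames):
            assert np.max(np.abs(a.positions - b.positions)) <= 1e-6


class TestSelections:
    def water_trimer(self):
        pos = np.zeros((9, 3))
        return Trajectory([Frame(pos, ["O", "H", "H"] * 3)],
                          CellGeometry.nonperiodic())

    def test_element_selection(self):
        traj = self.water_trimer()
        idx = mdpost.resolve_selection(traj, SelectionSpec.of_elements("O"))
        assert idx.tolist() == [0, 3, 6]

    def test_indices_deduplicated_and_sorted(self):
        traj = self.water_trimer()
        idx = mdpost.resolve_selection(traj, SelectionSpec.of_indices([2, 2, 1]))
        assert idx.tolist() == [1, 2]

    def test_all_mode(self):
        traj = self.water_trimer()
        idx = mdpost.resolve_selection(traj, SelectionSpec.everything())
        assert idx.tolist() == list(range(9))

    def test_out_of_range_index_raises(self):
        traj = self.water_trimer()
        with pytest.raises(SelectionError):
            mdpost.resolve_selection(traj, SelectionSpec.of_indices([9]))

    def test_unmatched_element_gives_empty_selection(self):
        traj = self.water_trimer()
        idx = mdpost.resolve_selection(traj, SelectionSpec.of_elements("Pt"))
        assert idx.size == 0


class TestMinImage:
    def test_cubic_boundary_crossing(self):
        cell = CellGeometry.cubic(10.0)
        d = mdpost.distance((1, 1, 1), (9, 1, 1), cell)
        assert d == pytest.approx(2.0)

    def test_identical_points_zero(self):
        cell = CellGeometry.cubic(10.0)
        assert np.allclose(mdpost.min_image_displacement(np.zeros(3), cell), 0)

    def test_triclinic_matches_27_image_oracle(self):
        rng = np.random.default_rng(5)
        vectors = np.array([[8.0, 0.0, 0.0], [1.5, 7.0, 0.0], [0.8, 1.1, 9.0]])
        cell = CellGeometry(vectors, (True, True, True))
        for _ in range(50):
            p = rng.uniform(-10, 10, 3)
            q = rng.uniform(-10, 10, 3)
            got = mdpost.min_image_displacement(q - p, cell)
            want = brute_min_image(q - p, cell)
            assert np.linalg.norm(got) == pytest.approx(np.linalg.norm(want),
                                                        abs=1e-10)

    def test_distance_symmetry(self):
        cell = CellGeometry.cubic(6.0)
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, 6, (30, 3))
        d = distance_matrix(pos, pos, cell)
        assert np.allclose(d, d.T)

    def test_translation_invariance(self):
        vectors = np.array([[8.0, 0.0, 0.0], [1.5, 7.0, 0.0], [0.8, 1.1, 9.0]])
        cell = CellGeometry(vectors, (True, True, True))
        rng = np.random.default_rng(9)
        pos = rng.uniform(0, 7, (20, 3))
        shift = rng.uniform(-30, 30, 3)
        d0 = distance_matrix(pos, pos, cell)
        d1 = distance_matrix(pos + shift, pos + shift, cell)
        assert np.allclose(d0, d1, atol=1e-9)


class TestNeighborPairs:
    def test_simple_cubic_center_has_six_neighbors(self):
        from mdpost.fixtures import make_lattice
        frame, cell = make_lattice(a=3.0, n=3)
        center = 13  # (1,1,1) in the 3x3x3 ordering
        pairs = neighbor_pairs(frame, cell, [center], list(range(27)), 3.6)
        assert len(pairs) == 6
        assert all(d == pytest.approx(3.0) for _, _, d in pairs)

    def test_vanishing_cutoff_empty(self):
        from mdpost.fixtures import make_lattice
        frame, cell = make_lattice(a=3.0, n=2)
        assert neighbor_pairs(frame, cell, [0], [1, 2, 3], 1e-9) == []

    def test_matches_quadratic_brute_force(self):
        rng = np.random.default_rng(21)
        cell = CellGeometry.cubic(9.0)
        pos = rng.uniform(0, 9, (100, 3))
        frame = Frame(pos, ["Ar"] * 100)
        idx = list(range(100))
        got = neighbor_pairs(frame, cell, idx, idx, 3.0)
        want = set()
        for i in range(100):
            for j in range(i + 1, 100):
                d = np.linalg.norm(brute_min_image(pos[j] - pos[i], cell))
                if d <= 3.0:
                    want.add((i, j))
        assert {(i, j) for i, j, _ in got} == want

    def test_large_cutoff_warns(self):
        from mdpost.fixtures import make_lattice
        frame, cell = make_lattice(a=3.0, n=2)  # box 6 A
        with pytest.warns(UserWarning, match="half the minimal cell height"):
            neighbor_pairs(frame, cell, [0], [1], 4.0)
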