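"""Partial RDFs, first-minimum detection, and coordination numbers."""

import numpy as np
import pytest

from mdpost import CellGeometry, Frame, SelectionSpec, Trajectory, \
    coordination_number, first_minimum, prdf
from mdpost.errors import NoMinimumError, SelectionError
from mdpost.fixtures import as_trajectory, make_lattice, make_uniform_gas, \
    make_water_dimer
from mdpost.rdf import RDFResult

ALL = SelectionSpec.everything()


@pytest.fixture(scope="module")
def gas():
    return make_uniform_gas(n_atoms=400, n_frames=20, box=15.0, seed=42)


class TestPrdf:
    def test_ideal_gas_is_uncorrelated(self, gas):
        r = prdf(gas, ALL, ALL, r_max=5.0)
        c = r.bin_centers
        window = (c >= 2.0) & (c <= 5.0)
        assert np.all(np.abs(r.g[window] - 1.0) < 0.05)
        assert 0.98 <= r.g[window].mean() <= 1.02

    def test_selection_symmetry(self, gas):
        """g_AB == g_BA bin-wise to machine precision (half/half split)."""
        a = SelectionSpec.of_indices(range(0, 200))
        b = SelectionSpec.of_indices(range(200, 400))
        ga = prdf(gas, a, b, r_max=5.0).g
        gb = prdf(gas, b, a, r_max=5.0).g
        assert np.array_equal(ga, gb)

    def test_index_subset_shares_normalization(self, gas):
        """A random half of the atoms still converges to g = 1."""
        rng = np.random.default_rng(0)
        half = rng.choice(400, size=200, replace=False)
        r = prdf(gas, SelectionSpec.of_indices(half),
                 SelectionSpec.of_indices(half), r_max=5.0)
        c = r.bin_centers
        window = (c >= 2.0) & (c <= 5.0)
        assert r.g[window].mean() == pytest.approx(1.0, abs=0.05)

    def test_lattice_first_shell_integrates_to_six(self):
        frame, cell = make_lattice(a=3.0, n=4)
        traj = as_trajectory(frame, cell)
        r = prdf(traj, ALL, ALL, r_max=4.0, bin_width=0.05)
        # coordination integral: sum over the first peak of rho * g * V_shell
        edges = r.bin_edges
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        rho = (frame.n_atoms - 1) / cell.volume
        peak = (r.bin_centers > 2.5) & (r.bin_centers < 3.5)
        cn = np.sum(r.g[peak] * shell[peak] * rho)
        assert cn == pytest.approx(6.0, rel=1e-9)
        first_nonzero = np.nonzero(r.g)[0][0]
        assert edges[first_nonzero] <= 3.0 <= edges[first_nonzero + 1]

    def test_two_atom_box_single_bin(self):
        cell = CellGeometry.cubic(10.0)
        frame = Frame([[1.0, 1, 1], [3.5, 1, 1]], ["Ar", "Ar"])
        r = prdf(as_trajectory(frame, cell), ALL, ALL, r_max=5.0,
                 bin_width=0.1)
        nz = np.nonzero(r.g)[0]
        assert len(nz) == 1
        assert r.bin_edges[nz[0]] <= 2.5 <= r.bin_edges[nz[0] + 1]

    def test_per_frame_stack(self, gas):
        r = prdf(gas, ALL, ALL, r_max=5.0, keep_frames=True)
        assert r.g_per_frame.shape == (gas.n_frames, len(r.g))
        assert np.allclose(r.g_per_frame.mean(axis=0), r.g)

    def test_empty_selection_raises(self, gas):
        with pytest.raises(SelectionError):
            prdf(gas, SelectionSpec.of_elements("Pt"), ALL, r_max=5.0)

    def test_large_rmax_warns(self, gas):
        with pytest.warns(UserWarning, match="half the minimal cell height"):
            prdf(gas, ALL, ALL, r_max=10.0)


def synthetic_rdf(bin_width=0.05, r_max=6.0):
    """g(r) = 1 + exp(-(r-2.8)^2/0.05) - 0.5 exp(-(r-3.4)^2/0.05)."""
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    c = 0.5 * (edges[:-1] + edges[1:])
    g = 1 + np.exp(-((c - 2.8) ** 2) / 0.05) - 0.5 * np.exp(-((c - 3.4) ** 2) / 0.05)
    return RDFResult(bin_edges=edges, g=g, pair=("A", "B"), n_frames=1)


class TestFirstMinimum:
    def test_synthetic_two_gaussian_curve(self):
        r = synthetic_rdf()
        # independent fine-grid scan of the analytic curve
        rr = np.linspace(2.8, 4.5, 200001)
        gg = 1 + np.exp(-((rr - 2.8) ** 2) / 0.05) - 0.5 * np.exp(-((rr - 3.4) ** 2) / 0.05)
        analytic_min = rr[np.argmin(gg)]
        assert first_minimum(r) == pytest.approx(analytic_min, abs=r.bin_width)

    def test_monotone_curve_raises(self):
        edges = np.arange(0.0, 5.0, 0.05)
        g = np.linspace(0.0, 2.0, edges.size - 1)
        r = RDFResult(bin_edges=edges, g=g, pair=("A", "B"), n_frames=1)
        with pytest.raises(NoMinimumError):
            first_minimum(r)

    def test_returns_interpeak_minimum_not_global(self):
        """Two peaks with the global minimum past the second peak: pick the
        minimum *between* peaks."""
        edges = np.arange(0.0, 8.0, 0.05)
        c = 0.5 * (edges[:-1] + edges[1:])
        g = (np.exp(-((c - 3.0) ** 2) / 0.1)
             + 0.8 * np.exp(-((c - 5.0) ** 2) / 0.1)) + 0.2
        r = RDFResult(bin_edges=edges, g=g, pair=("A", "B"), n_frames=1)
        got = first_minimum(r, search_from=2.0)
        assert 3.5 < got < 4.5  # between the peaks, not the far tail


class TestCoordinationNumber:
    def test_lattice_fixed_cutoff_exact(self):
        frame, cell = make_lattice(a=3.0, n=3)
        res = coordination_number(as_trajectory(frame, cell, 3), ALL, ALL,
                                  mode="fixed", cutoff=3.6)
        assert res.mean_cn == 6.0
        assert np.all(res.per_frame_cn == 6.0)

    def test_water_dimer_oo(self):
        frame, cell = make_water_dimer(d_ha=1.85)  # O-O = 2.81 A
        res = coordination_number(as_trajectory(frame, cell),
                                  SelectionSpec.of_elements("O"),
                                  SelectionSpec.of_elements("O"),
                                  mode="fixed", cutoff=3.5)
        assert res.mean_cn == 1.0

    def test_random_box_matches_quadratic_oracle(self):
        rng = np.random.default_rng(17)
        cell = CellGeometry.cubic(12.0)
        pos = rng.uniform(0, 12, (200, 3))
        frame = Frame(pos, ["Ar"] * 200)
        cutoff = 3.0
        res = coordination_number(as_trajectory(frame, cell), ALL, ALL,
                                  mode="fixed", cutoff=cutoff)
        count = 0
        for i in range(200):
            for j in range(200):
                if i == j:
                    continue
                d = pos[j] - pos[i]
                d -= 12.0 * np.round(d / 12.0)
                if np.linalg.norm(d) <= cutoff:
                    count += 1
        assert res.mean_cn == pytest.approx(count / 200, rel=1e-12)

    def test_cutoff_boundary_is_inclusive(self):
        cell = CellGeometry.cubic(10.0)
        frame = Frame([[0.0, 0, 0], [2.0, 0, 0]], ["Ar", "Ar"])
        res = coordination_number(as_trajectory(frame, cell), ALL, ALL,
                                  mode="fixed", cutoff=2.0)
        assert res.mean_cn == 1.0

    def test_dynamic_cutoff_from_first_minimum(self):
        """sc lattice: first g(r) minimum past the a=3 shell lies before the
        a*sqrt(2) shell, so the dynamic CN picks up exactly 6 neighbors."""
        frame, cell = make_lattice(a=3.0, n=4)
        res = coordination_number(as_trajectory(frame, cell), ALL, ALL,
                                  mode="dynamic", r_max=5.0)
        assert 3.0 < res.cutoff_used < 3.0 * np.sqrt(2)
        assert res.mean_cn == 6.0

    def test_vdw_mode_uses_radius_sums(self):
        # Pt-Pt vdW sum = 3.5 A; lattice spacing 3 -> coordinated at scale 1
        frame, cell = make_lattice(a=3.0, n=3, element="Pt")
        res = coordination_number(as_trajectory(frame, cell), ALL, ALL,
                                  mode="vdw", vdw_scale=1.0)
        assert res.mean_cn == 6.0
        assert res.cutoff_used == pytest.approx(3.5)
        tight = coordination_number(as_trajectory(frame, cell), ALL, ALL,
                                    mode="vdw", vdw_scale=0.5)
        assert tight.mean_cn == 0.0
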