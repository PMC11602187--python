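import numpy as np
import pytest

from pcpsim import (
    HexLattice,
    KineticParams,
    Sim1DConfig,
    Sim2DConfig,
    State1D,
    State2D,
    cell_polarity_2d,
    hex_neighbors,
    initial_state,
    initial_state_2d,
    rhs_1d,
    rhs_2d,
    simulate_1d,
    simulate_2d,
    tissue_polarity_2d,
    uniform_profile,
)
from pcpsim.lattice2d import EDGE_VECTORS, THETA
from pcpsim.io import read_state_2d, write_state_2d


def rotation(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


class TestNeighbors:
    def test_interior_cell_has_six_neighbors(self):
        lat = HexLattice(5, 5, boundary="open")
        center = lat.index(2, 2)
        assert all(n is not None for n, _, _ in hex_neighbors(lat, center))

    def test_open_corner_has_missing_neighbors(self):
        lat = HexLattice(5, 5, boundary="open")
        missing = sum(n is None for n, _, _ in hex_neighbors(lat, 0))
        assert missing >= 2

    @pytest.mark.parametrize("boundary", ["periodic", "open"])
    def test_reciprocity_exhaustive(self, boundary):
        """If B is A's neighbor across bin i, A is B's neighbor across bin
        (i+3) % 6 — checked for every pair of a 4x4 lattice."""
        lat = HexLattice(4, 4, boundary=boundary)
        for a in range(lat.n_cells):
            for b_cell, own, facing in hex_neighbors(lat, a):
                assert facing == (own + 3) % 6
                if b_cell is not None:
                    back = hex_neighbors(lat, b_cell)[facing]
                    assert back[0] == a

    def test_invalid_cell_rejected(self):
        with pytest.raises(IndexError):
            hex_neighbors(HexLattice(3, 3), 99)

    def test_neighbor_offsets_match_edge_angles(self):
        """The geometric direction to the neighbor across bin b is exactly
        theta_b."""
        lat = HexLattice(5, 5, boundary="open")
        c = lat.index(2, 2)
        for n, b, _ in hex_neighbors(lat, c):
            vec = lat.centers[n] - lat.centers[c]
            np.testing.assert_allclose(vec, EDGE_VECTORS[b], atol=1e-12)


class TestPolarity:
    def test_uniform_bins_zero_vector(self):
        st = State2D(np.full((4, 6), 0.5), np.full((4, 6), 0.2))
        pf, pd_ = cell_polarity_2d(st)
        np.testing.assert_allclose(pf, 0.0, atol=1e-12)
        np.testing.assert_allclose(tissue_polarity_2d(st), [0.0, 0.0], atol=1e-12)

    def test_single_bin_mass(self):
        f = np.zeros((1, 6))
        f[0, 0] = 0.7
        pf, _ = cell_polarity_2d(State2D(f, np.zeros((1, 6))))
        np.testing.assert_allclose(pf[0], [0.7, 0.0], atol=1e-12)

    def test_bin_rotation_rotates_polarity(self, rng):
        f = rng.random((3, 6))
        d = rng.random((3, 6))
        pf, pd_ = cell_polarity_2d(State2D(f, d))
        pf_rot, pd_rot = cell_polarity_2d(State2D(np.roll(f, 1, axis=1), np.roll(d, 1, axis=1)))
        R = rotation(np.pi / 3)
        np.testing.assert_allclose(pf_rot, pf @ R.T, atol=1e-12)
        np.testing.assert_allclose(pd_rot, pd_ @ R.T, atol=1e-12)

    def test_uniform_field_tissue_polarity(self):
        f = np.zeros((2, 6))
        f[:, 0] = 1.0  # pf = (a, 0) per cell
        d = np.zeros((2, 6))
        d[:, 3] = 1.0  # pd = (-a, 0)
        np.testing.assert_allclose(tissue_polarity_2d(State2D(f, d)), [2.0, 0.0], atol=1e-12)


class TestRhs:
    def test_empty_membrane_pure_binding(self, params):
        lat = HexLattice(3, 3)
        prof = uniform_profile(lat, 2.0)
        st = State2D(np.zeros((9, 6)), np.zeros((9, 6)))
        df, dd = rhs_2d(st, prof, params, lat)
        np.testing.assert_allclose(df, 2.0)
        np.testing.assert_allclose(dd, 2.0)

    def test_diffusion_zero_for_uniform_bins(self):
        lat = HexLattice(3, 3, boundary="periodic")
        prof = uniform_profile(lat, 3.0)
        st = State2D(np.full((9, 6), 0.4), np.full((9, 6), 0.4))
        df0, dd0 = rhs_2d(st, prof, KineticParams(d_theta=0.0), lat)
        df1, dd1 = rhs_2d(st, prof, KineticParams(d_theta=0.8), lat)
        np.testing.assert_allclose(df0, df1, atol=1e-12)
        np.testing.assert_allclose(dd0, dd1, atol=1e-12)

    def test_diffusion_conserves_membrane_protein(self, rng):
        """The angular diffusion term sums to zero over the six bins of any
        cell: membrane transport moves protein, it does not create it."""
        lat = HexLattice(4, 4, boundary="periodic")
        prof = uniform_profile(lat, 3.0)
        st = State2D(rng.random((16, 6)), rng.random((16, 6)))
        df0, dd0 = rhs_2d(st, prof, KineticParams(d_theta=0.0), lat)
        df1, dd1 = rhs_2d(st, prof, KineticParams(d_theta=1.3), lat)
        np.testing.assert_allclose((df1 - df0).sum(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose((dd1 - dd0).sum(axis=1), 0.0, atol=1e-12)

    def test_rotation_equivariance(self, rng):
        """Rotating the periodic lattice by pi/3 (axial (i,j) -> (-j, i+j))
        and advancing the bins by one permutes the right-hand side the same
        way: dynamics have the hexagonal symmetry."""
        n = 4
        lat = HexLattice(n, n, boundary="periodic")
        prof = uniform_profile(lat, 3.0)
        params = KineticParams(d_theta=0.2)
        f = rng.random((n * n, 6))
        d = rng.random((n * n, 6))

        def rotate_field(arr):
            out = np.empty_like(arr)
            for c in range(n * n):
                i, j = lat.axial(c)
                c2 = lat.index((-j) % n, (i + j) % n)
                out[c2] = np.roll(arr[c], 1)
            return out

        df, dd = rhs_2d(State2D(f, d), prof, params, lat)
        df_rot, dd_rot = rhs_2d(State2D(rotate_field(f), rotate_field(d)), prof, params, lat)
        np.testing.assert_allclose(df_rot, rotate_field(df), atol=1e-12)
        np.testing.assert_allclose(dd_rot, rotate_field(dd), atol=1e-12)


class TestEmbedding1D:
    """A 1 x N strip with only the left/right bins active reproduces the 1D
    model: bin 0 <-> right edge, bin 3 <-> left edge."""

    @staticmethod
    def embed(state1d):
        n = state1d.n_cells
        f = np.zeros((n, 6))
        d = np.zeros((n, 6))
        f[:, 0], f[:, 3] = state1d.fr, state1d.fl
        d[:, 0], d[:, 3] = state1d.dr, state1d.dl
        return State2D(f, d)

    def test_rhs_matches_elementwise(self, params, rng):
        n = 8
        prof1 = uniform_profile(n, 3.0)
        st1 = State1D(*(0.4 * rng.random(n) for _ in range(4)))
        lat = HexLattice(n, 1, boundary="open")
        prof2 = uniform_profile(lat, 3.0)
        active = np.array([True, False, False, True, False, False])
        df, dd = rhs_2d(self.embed(st1), prof2, params, lat, active_bins=active)
        d_fl, d_fr, d_dl, d_dr = rhs_1d(st1, prof1, params, "open")
        np.testing.assert_allclose(df[:, 0], d_fr, atol=1e-12)
        np.testing.assert_allclose(df[:, 3], d_fl, atol=1e-12)
        np.testing.assert_allclose(dd[:, 0], d_dr, atol=1e-12)
        np.testing.assert_allclose(dd[:, 3], d_dl, atol=1e-12)
        assert np.all(df[:, [1, 2, 4, 5]] == 0)

    def test_steady_state_matches_1d(self, params):
        n = 12
        prof1 = uniform_profile(n, 4.0)
        cfg1 = Sim1DConfig(n_cells=n, boundary="open")
        res1 = simulate_1d(initial_state(prof1, cfg1), prof1, params, cfg1)
        lat = HexLattice(n, 1, boundary="open")
        prof2 = uniform_profile(lat, 4.0)
        active = np.array([True, False, False, True, False, False])
        st0 = self.embed(initial_state(prof1, cfg1))
        res2 = simulate_2d(st0, prof2, params, lat, Sim2DConfig(dt=0.01), active_bins=active)
        assert res2.converged
        np.testing.assert_allclose(res2.state.f[:, 0], res1.state.fr, atol=1e-6)
        np.testing.assert_allclose(res2.state.f[:, 3], res1.state.fl, atol=1e-6)
        np.testing.assert_allclose(res2.state.d[:, 0], res1.state.dr, atol=1e-6)


class TestSimulate:
    def test_below_threshold_unpolarized(self, params):
        lat = HexLattice(6, 6, boundary="periodic")
        prof = uniform_profile(lat, 1.0)
        cfg = Sim2DConfig(dt=0.05)
        res = simulate_2d(initial_state_2d(prof, lat, cfg), prof, params, lat, cfg)
        assert res.converged
        assert np.linalg.norm(tissue_polarity_2d(res.state)) < 1e-6

    def test_above_threshold_polarizes(self, params):
        # the hexagonal lattice splits the membrane over six bins, so its
        # spontaneous threshold sits near 6 + 1/(2*alpha), above the 1D value
        lat = HexLattice(6, 6, boundary="periodic")
        prof = uniform_profile(lat, 8.0)
        cfg = Sim2DConfig(dt=0.05)
        res = simulate_2d(initial_state_2d(prof, lat, cfg), prof, params, lat, cfg)
        assert res.converged
        p = tissue_polarity_2d(res.state)
        assert np.linalg.norm(p) > 1.0
        assert p[0] > 0  # bin-0 seed points along +x

    def test_box_invariance_final_state(self, params):
        lat = HexLattice(5, 5, boundary="periodic")
        for rho in (1.0, 8.0):
            prof = uniform_profile(lat, rho)
            cfg = Sim2DConfig(dt=0.05)
            res = simulate_2d(initial_state_2d(prof, lat, cfg), prof, params, lat, cfg)
            assert np.all(res.state.fm <= prof.f_total + 1e-9)
            assert np.all(res.state.dm <= prof.d_total + 1e-9)
            assert np.all(res.state.f >= 0) and np.all(res.state.d >= 0)

    def test_initial_state_deterministic_random_bins(self, params):
        lat = HexLattice(5, 5)
        prof = uniform_profile(lat, 3.0)
        cfg = Sim2DConfig(init_direction="random", seed=4)
        a = initial_state_2d(prof, lat, cfg)
        b = initial_state_2d(prof, lat, cfg)
        np.testing.assert_array_equal(a.f, b.f)


def test_state_table_round_trip(tmp_path, rng):
    lat = HexLattice(3, 4)
    st = State2D(rng.random((12, 6)), rng.random((12, 6)))
    path = tmp_path / "state2d.tsv"
    write_state_2d(st, lat, path)
    back = read_state_2d(path)
    np.testing.assert_allclose(back.f, st.f)
    np.testing.assert_allclose(back.d, st.d)
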