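import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import solve_ivp

from pcpsim import (
    DynNoiseSpec,
    KineticParams,
    Sim1DConfig,
    State1D,
    cell_polarity_1d,
    initial_state,
    rhs_1d,
    simulate_1d,
    simulate_1d_langevin,
    tissue_polarity_1d,
    uniform_profile,
)
from pcpsim.lattice1d import _rhs_packed
from pcpsim.io import read_state_1d, write_state_1d


class TestInitialState:
    def test_zero_asymmetry_is_symmetric(self):
        prof = uniform_profile(10, 3.0)
        st = initial_state(prof, Sim1DConfig(n_cells=10, init_asymmetry=0.0))
        np.testing.assert_array_equal(st.fl, st.fr)
        np.testing.assert_array_equal(st.dl, st.dr)

    def test_fixed_direction_values(self):
        prof = uniform_profile(4, 3.0)
        st = initial_state(prof, Sim1DConfig(n_cells=4, init_asymmetry=0.01))
        np.testing.assert_allclose(st.fr, 0.03)
        np.testing.assert_allclose(st.fl, 0.0)
        np.testing.assert_allclose(st.dl, 0.03)
        np.testing.assert_allclose(st.dr, 0.0)

    def test_random_direction_deterministic(self):
        prof = uniform_profile(50, 3.0)
        cfg = Sim1DConfig(n_cells=50, init_direction="random", seed=9)
        a, b = initial_state(prof, cfg), initial_state(prof, cfg)
        np.testing.assert_array_equal(a.fl, b.fl)
        np.testing.assert_array_equal(a.fr, b.fr)

    def test_invalid_asymmetry(self):
        with pytest.raises(ValueError):
            Sim1DConfig(init_asymmetry=0.7)


class TestRhs:
    def test_symmetric_fixed_point_has_zero_derivative(self, params):
        """With rho = 2.5, alpha = 1 the uniform symmetric state with one unit
        per edge balances binding (0.5) against Hill-halved unbinding (0.5)."""
        n = 6
        prof = uniform_profile(n, 2.5)
        st = State1D(np.ones(n), np.ones(n), np.ones(n), np.ones(n))
        for d in rhs_1d(st, prof, params, "periodic"):
            np.testing.assert_allclose(d, 0.0, atol=1e-14)

    def test_empty_membrane_pure_binding(self, params):
        prof = uniform_profile(5, 3.0)
        st = State1D(*(np.zeros(5) for _ in range(4)))
        for d in rhs_1d(st, prof, params, "periodic"):
            np.testing.assert_allclose(d, 3.0)  # alpha * rho

    def test_open_boundary_edges_unbind_at_full_rate(self, params):
        n = 4
        prof = uniform_profile(n, 3.0)
        st = State1D(np.full(n, 0.5), np.full(n, 0.5), np.full(n, 0.5), np.full(n, 0.5))
        d_per = rhs_1d(st, prof, params, "periodic")
        d_open = rhs_1d(st, prof, params, "open")
        # interior cells identical, edge cells lose Hill stabilization
        assert d_open[0][0] < d_per[0][0]          # fl of cell 0: H2(0)=1
        np.testing.assert_allclose(d_open[0][1:], d_per[0][1:])

    def test_two_cell_ft_only_relaxation_rate(self, params):
        """With Ds absent the Ft dynamics are linear; total membrane Ft relaxes
        at rate 2*alpha + beta0 toward 2*alpha*fT/(2*alpha + beta0)."""
        n = 2
        rho = 3.0
        prof = uniform_profile(n, rho, 0.0)
        st0 = State1D(np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n))
        t_end = 1.3
        sol = solve_ivp(
            lambda t, y: _rhs_packed(y, prof, params, "periodic"),
            (0, t_end), st0.pack(), rtol=1e-10, atol=1e-12,
        )
        fm = sol.y[0, -1] + sol.y[n, -1]
        rate = 2 * params.alpha + params.beta0
        fm_exact = (2 * params.alpha * rho / rate) * (1 - np.exp(-rate * t_end))
        assert fm == pytest.approx(fm_exact, rel=1e-6)

    def test_nan_rejected(self, params):
        prof = uniform_profile(3, 1.0)
        st = State1D(np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3))
        st.fl[0] = np.nan
        with pytest.raises(FloatingPointError):
            rhs_1d(st, prof, params, "periodic")


class TestSimulate:
    def test_below_threshold_unpolarized(self, params):
        prof = uniform_profile(50, 1.0)
        cfg = Sim1DConfig(n_cells=50)
        res = simulate_1d(initial_state(prof, cfg), prof, params, cfg)
        assert res.converged
        assert abs(tissue_polarity_1d(res.state)) < 1e-6
        np.testing.assert_allclose(res.state.fl, res.state.fr, atol=1e-6)

    def test_above_threshold_polarizes_along_seed(self, params):
        prof = uniform_profile(50, 4.0)
        cfg = Sim1DConfig(n_cells=50)
        res = simulate_1d(initial_state(prof, cfg), prof, params, cfg)
        assert res.converged
        assert tissue_polarity_1d(res.state) > 1.0  # rightward seed -> p > 0

    def test_unlimited_pool_stays_symmetric(self, params):
        prof = replace(uniform_profile(50, 4.0), unlimited_pool=0.3)
        cfg = Sim1DConfig(n_cells=50)
        res = simulate_1d(initial_state(prof, cfg), prof, params, cfg)
        assert res.converged
        assert abs(tissue_polarity_1d(res.state)) < 1e-6

    def test_translation_invariance(self, params):
        prof = uniform_profile(64, 4.0)
        cfg = Sim1DConfig(n_cells=64)
        res = simulate_1d(initial_state(prof, cfg), prof, params, cfg)
        pf, pd_ = cell_polarity_1d(res.state)
        assert np.ptp(pf) < 1e-6 and np.ptp(pd_) < 1e-6

    def test_ft_ds_mirror_antisymmetry(self, params):
        """Equal uniform expression with the canonical antisymmetric seed gives
        pf(i) = -pd(i) at the converged state."""
        prof = uniform_profile(40, 3.5)
        cfg = Sim1DConfig(n_cells=40)
        res = simulate_1d(initial_state(prof, cfg), prof, params, cfg)
        pf, pd_ = cell_polarity_1d(res.state)
        np.testing.assert_allclose(pf, -pd_, atol=1e-7)

    def test_box_invariance_final_state(self, params):
        for rho in (1.0, 4.0):
            prof = uniform_profile(30, rho)
            cfg = Sim1DConfig(n_cells=30)
            res = simulate_1d(initial_state(prof, cfg), prof, params, cfg)
            assert np.all(res.state.fm <= prof.f_total + 1e-9)
            assert np.all(res.state.dm <= prof.d_total + 1e-9)
            assert np.all(res.state.fl >= 0) and np.all(res.state.dr >= 0)


class TestPolarity:
    def test_symmetric_state_zero(self):
        st = State1D(np.ones(5), np.ones(5), np.ones(5), np.ones(5))
        pf, pd_ = cell_polarity_1d(st)
        assert np.all(pf == 0) and np.all(pd_ == 0)
        assert tissue_polarity_1d(st) == 0.0

    def test_difference_definition(self):
        st = State1D([0.2], [1.0], [0.4], [0.1])
        pf, pd_ = cell_polarity_1d(st)
        assert pf[0] == pytest.approx(0.8)
        assert pd_[0] == pytest.approx(-0.3)

    def test_mirror_negates_polarity(self, rng):
        st = State1D(*(rng.random(7) for _ in range(4)))
        pf, pd_ = cell_polarity_1d(st)
        mpf, mpd = cell_polarity_1d(st.mirror())
        np.testing.assert_allclose(mpf, -pf[::-1])
        np.testing.assert_allclose(mpd, -pd_[::-1])

    def test_opposite_halves_cancel(self):
        fr = np.r_[np.ones(3), np.zeros(3)]
        fl = np.r_[np.zeros(3), np.ones(3)]
        st = State1D(fl, fr, fl, fr)
        assert tissue_polarity_1d(st) == pytest.approx(0.0)

    def test_uniform_antisymmetric_polarity(self):
        a = 0.7
        st = State1D(np.zeros(4), np.full(4, a), np.full(4, a), np.zeros(4))
        assert tissue_polarity_1d(st) == pytest.approx(2 * a)


class TestLangevin:
    def test_zero_noise_matches_deterministic(self, params):
        prof = uniform_profile(20, 4.0)
        cfg = Sim1DConfig(n_cells=20)
        det = simulate_1d(initial_state(prof, cfg), prof, params, cfg)
        sto = simulate_1d_langevin(
            initial_state(prof, cfg), prof, params, cfg, DynNoiseSpec(eta=0.0, seed=0)
        )
        assert abs(tissue_polarity_1d(sto.state) - tissue_polarity_1d(det.state)) < 5e-3

    def test_deterministic_under_seed(self, params):
        prof = uniform_profile(20, 4.0)
        cfg = Sim1DConfig(n_cells=20)
        spec = DynNoiseSpec(eta=1e-3, seed=5, duration=30.0)
        a = simulate_1d_langevin(initial_state(prof, cfg), prof, params, cfg, spec)
        b = simulate_1d_langevin(initial_state(prof, cfg), prof, params, cfg, spec)
        np.testing.assert_array_equal(a.state.fl, b.state.fl)

    def test_noise_error_decreases_with_eta(self, params):
        prof = uniform_profile(20, 4.0)
        cfg = Sim1DConfig(n_cells=20)
        det = simulate_1d(initial_state(prof, cfg), prof, params, cfg)
        errs = []
        for eta in (1e-2, 1e-3, 1e-4):
            sto = simulate_1d_langevin(
                initial_state(prof, cfg), prof, params, cfg,
                DynNoiseSpec(eta=eta, seed=11, duration=60.0),
            )
            errs.append(abs(tissue_polarity_1d(sto.state) - tissue_polarity_1d(det.state)))
        assert errs[0] > errs[1] > errs[2]

    def test_box_invariance_tail_state(self, params):
        prof = uniform_profile(20, 3.0)
        cfg = Sim1DConfig(n_cells=20)
        res = simulate_1d_langevin(
            initial_state(prof, cfg), prof, params, cfg,
            DynNoiseSpec(eta=1e-2, seed=2, duration=40.0),
        )
        assert np.all(res.state.fm <= prof.f_total + 0.1)
        assert np.all(res.state.fl >= 0)

    def test_negative_eta_rejected(self):
        with pytest.raises(ValueError):
            DynNoiseSpec(eta=-1.0)


def test_state_table_round_trip(tmp_path, rng):
    st = State1D(*(rng.random(9) for _ in range(4)))
    path = tmp_path / "state.tsv"
    write_state_1d(st, path)
    back = read_state_1d(path)
    np.testing.assert_allclose(back.fl, st.fl)
    np.testing.assert_allclose(back.dr, st.dr)
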