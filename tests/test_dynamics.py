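"""SCPW dynamics: closure factor, the four system forms, and integration."""

import numpy as np
import pytest

import scpw
from scpw.dynamics import SingularStateError

from .conftest import random_nondim_state


def _dimensional_from_nondim(u: scpw.NondimState, kmean: float, N: float = 10000.0):
    return scpw.DimensionalState(
        S=u.v * N, I=u.w * N, SI=u.x * kmean * N, SS=u.y * kmean * N,
        II=u.z * kmean * N, N=N, kmean=kmean,
    )


def q_closure_ns_form(state: scpw.DimensionalState, m: scpw.NetworkMoments) -> float:
    """Independent oracle: the closure written via the mean susceptible degree
    n_S = ([SI]+[SS])/[S] rather than via the alpha/beta constants."""
    n_s = (state.SI + state.SS) / state.S
    k1, k2, k3 = m.k1, m.k2, m.k3
    inner = (k2 * (k2 - k1 * n_s) + k3 * (n_s - k1)) / (n_s * (k2 - k1**2)) - 1.0
    return inner / (n_s * state.S)


class TestQClosure:
    def test_zero_when_alpha_beta_zero(self):
        # a moment triple with alpha = beta = 0: k2 = k1^2 + k1... not needed;
        # check directly that the formula is linear in (alpha, beta)
        state = scpw.DimensionalState(10000, 0, 0, 40000, 0, 10000, 4)
        m = scpw.NetworkMoments(4, 17, 76)
        q = scpw.q_closure(state, m)
        assert q == pytest.approx(8.125e-5, rel=1e-12)

    def test_matches_mean_susceptible_degree_form(self, rng, bimodal_moments):
        for _ in range(100):
            u = random_nondim_state(rng)
            state = _dimensional_from_nondim(u, bimodal_moments.k1)
            q = scpw.q_closure(state, bimodal_moments)
            oracle = q_closure_ns_form(state, bimodal_moments)
            assert q == pytest.approx(oracle, rel=1e-10)

    def test_singular_state_rejected(self, bimodal_moments):
        state = scpw.DimensionalState(1, 9999, 0, 0, 40000, 10000, 4)
        with pytest.raises(SingularStateError):
            scpw.q_closure(state, bimodal_moments)


class TestRhsDimensional:
    def test_dfe_is_fixed_point(self, bimodal_moments):
        N, k = 10000.0, bimodal_moments.k1
        dfe = scpw.DimensionalState(N, 0, 0, k * N, 0, N, k)
        rates = scpw.rhs_dimensional(dfe, scpw.EpiParams(0.5, 1.0), bimodal_moments)
        assert rates == pytest.approx(np.zeros(5), abs=1e-12)

    def test_conservation_of_rates(self, rng, bimodal_moments):
        p = scpw.EpiParams(tau=0.9, gamma=1.3)
        for _ in range(100):
            state = _dimensional_from_nondim(random_nondim_state(rng), bimodal_moments.k1)
            dS, dI, dSI, dSS, dII = scpw.rhs_dimensional(state, p, bimodal_moments)
            scale = max(1.0, abs(dS), abs(dSI))
            assert dS + dI == pytest.approx(0.0, abs=1e-9 * scale)
            assert 2 * dSI + dSS + dII == pytest.approx(0.0, abs=1e-9 * scale)

    def test_rescaling_matches_nondimensional(self, rng, bimodal_moments, bimodal_constants):
        # apply the variable/time scaling v=[S]/N ... T = gamma*t to the
        # dimensional rates and compare with the nondimensional field
        gamma, N, k = 1.7, 10000.0, bimodal_moments.k1
        delta = 0.8
        p = scpw.EpiParams(tau=delta * gamma, gamma=gamma)
        for _ in range(50):
            u = random_nondim_state(rng)
            dim = _dimensional_from_nondim(u, k, N)
            rates = scpw.rhs_dimensional(dim, p, bimodal_moments)
            scaled = np.array([
                rates[0] / (gamma * N), rates[1] / (gamma * N),
                rates[2] / (gamma * k * N), rates[3] / (gamma * k * N),
                rates[4] / (gamma * k * N),
            ])
            nondim = scpw.rhs_nondimensional(u, delta, bimodal_constants, k)
            assert scaled == pytest.approx(nondim, rel=1e-9, abs=1e-12)


class TestRhsNondimensional:
    def test_dfe_fixed_point(self, bimodal_constants):
        u = scpw.NondimState(1, 0, 0, 1, 0)
        rates = scpw.rhs_nondimensional(u, 0.7, bimodal_constants, 4.0)
        assert rates == pytest.approx(np.zeros(5), abs=1e-14)

    def test_x_zero_slice(self, bimodal_constants):
        # with x = 0 every closure term vanishes: dy = 0 and dx = z
        z = 0.3
        rates = scpw.rhs_nondimensional([1, 0, 0.0, 1 - z, z], 0.9, bimodal_constants, 4.0)
        assert rates[3] == 0.0
        assert rates[2] == pytest.approx(z)

    def test_conservation_on_randomized_states(self, rng):
        from .conftest import random_feasible_moments

        checked = 0
        while checked < 1000:
            m = random_feasible_moments(rng)
            if m.k2 - m.k1**2 <= 1e-8 * m.k1**2:
                continue
            c = scpw.derived_constants(m)
            u = random_nondim_state(rng)
            delta = rng.uniform(0.05, 5.0)
            dv, dw, dx, dy, dz = scpw.rhs_nondimensional(u, delta, c, m.k1)
            scale = max(1.0, abs(dx))
            assert dv + dw == pytest.approx(0.0, abs=1e-12 * scale)
            assert 2 * dx + dy + dz == pytest.approx(0.0, abs=1e-10 * scale)
            checked += 1


class TestReducedForms:
    def test_wxz_dfe(self, bimodal_constants):
        assert scpw.rhs_reduced_wxz([0, 0, 0], 0.5, bimodal_constants, 4.0) == pytest.approx(
            np.zeros(3), abs=1e-14
        )

    def test_vxy_dfe(self, bimodal_constants):
        assert scpw.rhs_reduced_vxy([1, 0, 1], 0.5, bimodal_constants) == pytest.approx(
            np.zeros(3), abs=1e-14
        )

    def test_w_equation_reads_off(self, rng, bimodal_constants):
        # dw = <k> delta x - w carries no closure terms
        for _ in range(20):
            w, x, z = rng.uniform(0.01, 0.3, size=3)
            delta = rng.uniform(0.1, 3.0)
            rates = scpw.rhs_reduced_wxz([w, x, z], delta, bimodal_constants, 4.0)
            assert rates[0] == pytest.approx(4.0 * delta * x - w, rel=1e-14)

    def test_agreement_with_full_system(self, rng, bimodal_constants):
        c, k = bimodal_constants, 4.0
        for _ in range(1000):
            u = random_nondim_state(rng)
            delta = rng.uniform(0.05, 4.0)
            full = scpw.rhs_nondimensional(u, delta, c, k)
            wxz = scpw.rhs_reduced_wxz([u.w, u.x, u.z], delta, c, k)
            vxy = scpw.rhs_reduced_vxy([u.v, u.x, u.y], delta, c)
            assert np.max(np.abs(wxz - full[[1, 2, 4]])) < 1e-12
            assert np.max(np.abs(vxy - full[[0, 2, 3]])) < 1e-12

    def test_sigma_delta_ratio_consistency(self, bimodal_constants, rng):
        # sigma * (delta/delta_c) = <k> * delta: the reparameterization is exact
        c = bimodal_constants
        for delta in rng.uniform(0.01, 5.0, size=20):
            assert c.sigma * delta / c.delta_c == pytest.approx(4.0 * delta, rel=1e-12)


class TestIntegrate:
    def test_dfe_stays_put(self, bimodal_constants):
        traj = scpw.integrate(
            "nondim", scpw.NondimState(1, 0, 0, 1, 0), 0.8, bimodal_constants,
            kmean=4.0, t_end=10.0,
        )
        assert np.allclose(traj.states, traj.states[0], atol=1e-9)

    def test_subthreshold_outbreak_dies(self, bimodal_constants):
        traj = scpw.integrate(
            "nondim", scpw.default_initial_state(0.01), 0.1, bimodal_constants,
            kmean=4.0,
        )
        assert traj.terminal.w < 1e-6

    def test_supercritical_matches_root_solver(self, bimodal_constants):
        c = bimodal_constants
        delta = 2 * c.delta_c
        traj = scpw.integrate("nondim", scpw.default_initial_state(0.01), delta, c, kmean=4.0)
        eq = scpw.solve_endemic(delta, c)
        term = traj.terminal
        assert term.w == pytest.approx(eq.w, abs=1e-6)
        assert term.x == pytest.approx(eq.x, abs=1e-6)
        assert term.y == pytest.approx(eq.y, abs=1e-6)

    def test_three_system_forms_agree(self, bimodal_constants):
        init = scpw.default_initial_state(0.05)
        kwargs = dict(delta=1.0, c=bimodal_constants, kmean=4.0, t_end=20.0,
                      rtol=1e-10, atol=1e-12, rate_norm_tol=0.0)
        finals = [
            scpw.integrate(system, init, **kwargs).states[-1]
            for system in ("nondim", "wxz", "vxy")
        ]
        for other in finals[1:]:
            assert np.max(np.abs(other - finals[0])) < 1e-8

    def test_positivity_and_conservation_along_trajectory(self, poisson_constants):
        traj = scpw.integrate(
            "nondim", scpw.default_initial_state(0.01), 0.3, poisson_constants,
            kmean=10.0,
        )
        assert np.all(traj.states >= -1e-9)
        assert np.all(traj.states <= 1 + 1e-9)
        assert np.max(np.abs(traj.states[:, 0] + traj.states[:, 1] - 1)) < 1e-6
        pair_sum = 2 * traj.states[:, 2] + traj.states[:, 3] + traj.states[:, 4]
        assert np.max(np.abs(pair_sum - 1)) < 1e-6

    def test_trajectory_csv_round_trip(self, bimodal_constants, tmp_path):
        import pandas as pd

        traj = scpw.integrate("vxy", scpw.default_initial_state(0.02), 0.7,
                              bimodal_constants, t_end=5.0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["T", "v", "w", "x", "y", "z"]
        assert df["w"].iloc[-1] == pytest.approx(traj.terminal.w, rel=1e-10)

    def test_invalid_inputs(self, bimodal_constants):
        with pytest.raises(ValueError, match="t_end"):
            scpw.integrate("nondim", scpw.default_initial_state(), 0.5,
                           bimodal_constants, kmean=4.0, t_end=-1.0)
        with pytest.raises(ValueError, match="unknown system"):
            scpw.integrate("full", scpw.default_initial_state(), 0.5,
                           bimodal_constants, kmean=4.0)
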