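"""Engine tests: hypothesis presets, initialization, the explicit step
against an independently hand-coded oracle, and the run-level wave
properties."""

import numpy as np
import pytest

from fairyring import (
    ModelParams,
    SimConfig,
    StabilityError,
    apply_hypothesis,
    fungus_free_equilibrium,
    run,
)
from fairyring.engine import (
    StateFields,
    Trajectory,
    aligned_profile_difference,
    front_position,
    front_speed,
    initialize,
    step,
)


class TestHypothesisModes:
    def test_hydrophobicity_disables_toxicity(self):
        p = apply_hypothesis(ModelParams(), "hydrophobicity")
        assert p.s_T == 0.0 and p.a == 2.0

    def test_phytotoxicity_disables_hydrophobicity(self):
        p = apply_hypothesis(ModelParams(), "phytotoxicity")
        assert p.a == 0.0 and p.s_T == pytest.approx(1.1)

    def test_combined_keeps_both(self):
        p = apply_hypothesis(ModelParams(), "combined")
        assert p.a == 2.0 and p.s_T == pytest.approx(0.3)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown hypothesis mode"):
            apply_hypothesis(ModelParams(), "nutrients")


class TestInitialize:
    def test_2d_central_inoculum(self):
        cfg = SimConfig(shape=(21, 21))
        st = initialize(cfg)
        assert st.F[10, 10] == 0.01
        assert st.F.sum() == pytest.approx(0.01)
        assert st.P.min() == st.P.max() == 1.0
        assert all(getattr(st, n).sum() == 0 for n in "ITSN")

    def test_1d_end_inoculum(self):
        st = initialize(SimConfig(shape=(50,)))
        assert st.F[0] == 0.01 and st.F[1:].sum() == 0

    def test_fungus_free_control_stays_fungus_free(self):
        traj = run(SimConfig(shape=(20,), n_steps=50, inoculum_amount=0.0))
        assert traj.final.F.sum() == 0.0

    def test_site_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside grid"):
            initialize(SimConfig(shape=(10,), inoculum_site=(12,)))

    def test_stability_check_refuses_coarse_step(self):
        cfg = SimConfig(dt=1.0, dx=0.1, substeps=1)  # D*dt/dx^2 = 1
        with pytest.raises(StabilityError):
            cfg.check_stability()


def _oracle_step(state, p, dt, dx):
    """Independent scalar re-implementation of one explicit update, written
    symbol-by-symbol from the governing equations (loops, no shared code)."""
    n = len(state.F)
    out = {k: np.zeros(n) for k in "FITSPN"}
    lap = {}
    for name, D in (("F", p.D_F), ("P", p.D_P)):
        f = getattr(state, name)
        l = np.zeros(n)
        for i in range(n):
            left = f[i - 1] if i > 0 else f[0]
            right = f[i + 1] if i < n - 1 else f[n - 1]
            l[i] = (left - 2 * f[i] + right) / dx**2
        lap[name] = l
    for i in range(n):
        F, I, T, S, Pl, N = (getattr(state, k)[i] for k in "FITSPN")
        wbar = 1 - p.b ** (p.a * F - p.W) if p.a * F < p.W else 0.0
        dF = p.g_F * F * (1 - p.s_I * I) * (p.W / (p.W + p.k_W)) - p.d_F * F**2 - p.s_F * F * I
        dI = p.c_I * (p.d_F * F**2 + p.s_F * F * I) - p.k_I * I - p.l_I * I * wbar
        dT = p.c_T * F - p.k_T * T - p.l_T * T * wbar
        dS = p.c_S * F - p.k_S * S
        dP = p.g_P * Pl * (wbar * (p.q_P + S + N) - Pl) - p.s_T * T * Pl
        dN = p.g_N * (p.g_P * Pl**2 + p.s_T * Pl * T) * wbar - p.u_N * (p.g_P * wbar * Pl * N) - p.l_N * N * wbar
        out["F"][i] = max(F + dt * (dF + p.D_F * lap["F"][i]), 0.0)
        out["I"][i] = max(I + dt * dI, 0.0)
        out["T"][i] = max(T + dt * dT, 0.0)
        out["S"][i] = max(S + dt * dS, 0.0)
        out["P"][i] = max(Pl + dt * (dP + p.D_P * lap["P"][i]), 0.0)
        out["N"][i] = max(N + dt * dN, 0.0)
    return out


class TestStep:
    def test_zero_state_fixed(self, default_params):
        z = StateFields(*(np.zeros(10) for _ in range(6)))
        nxt = step(z, default_params, 1.0)
        assert all(getattr(nxt, k).sum() == 0 for k in "FITSPN")

    def test_matches_independent_oracle(self, default_params, rng):
        """Two chained steps from a random positive state agree with the
        loop-based symbol-by-symbol oracle at every cell."""
        st = StateFields(*(rng.uniform(0, 1.5, 9) for _ in range(6)))
        p = default_params
        expect = _oracle_step(st, p, 0.5, 1.0)
        got = step(st, p, 0.5)
        for k in "FITSPN":
            np.testing.assert_allclose(getattr(got, k), expect[k], rtol=1e-13)
        expect2 = _oracle_step(got, p, 0.5, 1.0)
        got2 = step(got, p, 0.5)
        for k in "FITSPN":
            np.testing.assert_allclose(getattr(got2, k), expect2[k], rtol=1e-13)

    def test_fields_stay_nonnegative(self, default_params, rng):
        st = StateFields(*(rng.uniform(0, 5, 30) for _ in range(6)))
        for _ in range(20):
            st = step(st, default_params, 1.0)
            assert all(getattr(st, k).min() >= 0 for k in "FITSPN")

    def test_diffusion_conserves_biomass(self, default_params):
        """With reactions switched off, the diffusive update preserves the
        domain totals of F and P exactly (zero-flux boundaries)."""
        p = ModelParams(
            g_F=0, d_F=0, s_F=0, c_I=0, k_I=0, l_I=0, c_T=0, k_T=0, l_T=0,
            c_S=0, k_S=0, g_P=0, s_T=0, g_N=0, u_N=0, l_N=0,
        )
        rng = np.random.default_rng(7)
        st = StateFields(*(rng.uniform(0, 2, 40) for _ in range(6)))
        tot_F, tot_P = st.F.sum(), st.P.sum()
        for _ in range(50):
            st = step(st, p, 1.0)
        assert st.F.sum() == pytest.approx(tot_F, rel=1e-12)
        assert st.P.sum() == pytest.approx(tot_P, rel=1e-12)


class TestRun:
    def test_deterministic(self):
        cfg = SimConfig(shape=(60,), n_steps=200)
        a, b = run(cfg), run(cfg)
        for k in "FITSPN":
            np.testing.assert_array_equal(getattr(a.final, k), getattr(b.final, k))

    def test_fungus_free_run_reaches_coupled_equilibrium(self, default_params):
        """Without an inoculum the vegetation relaxes to the closed-form
        plant/nutrient equilibrium everywhere (within 1e-6 by 2000 d)."""
        traj = run(SimConfig(shape=(20,), inoculum_amount=0.0))
        P_star, N_star = fungus_free_equilibrium(default_params)
        assert np.abs(traj.final.P - P_star).max() < 1e-6
        assert np.abs(traj.final.N - N_star).max() < 1e-6

    def test_uniform_no_fungus_monotone_relaxation(self):
        """With nutrient recycling off the plant field relaxes monotonically
        toward the water-limited logistic level W_bar*q_P."""
        p = ModelParams(g_N=0.0)
        cfg = SimConfig(params=p, shape=(10,), inoculum_amount=0.0, n_steps=300, snapshot_stride=1)
        traj = run(cfg)
        series = np.array([s.P[5] for s in traj.snapshots])
        target = (1 - 9.0**-1) * p.q_P
        assert np.all(np.diff(series) <= 1e-12)  # P starts above capacity
        assert series[-1] == pytest.approx(target, abs=1e-6)

    def test_ring_profile_emerges_at_defaults(self, default_run):
        """Self-inhibition hollows the colony: a single interior mycelium
        maximum with near-zero fungus at the inoculum end."""
        x, F, _ = default_run.final_transect()
        assert 0 < np.argmax(F) < len(F) - 1
        assert F[0] < 0.1 * F.max()

    def test_times_strictly_increasing_and_shapes_constant(self, default_run):
        assert np.all(np.diff(default_run.times) > 0)
        assert len({s.shape for s in default_run.snapshots}) == 1

    def test_2d_rotation_symmetry(self):
        """A central inoculum on a square lattice keeps the fields invariant
        under 90-degree rotation (no directional bias in the operator)."""
        traj = run(SimConfig(shape=(41, 41), n_steps=200, snapshot_stride=100))
        for k in "FP":
            f = getattr(traj.final, k)
            assert np.abs(f - np.rot90(f)).max() < 1e-12

    def test_dt_refinement_consistency(self):
        """Doubling the temporal resolution leaves the 2000-day transect
        essentially unchanged once profiles are aligned for the (sub-cell)
        front displacement; measured at dx=0.5 so discretization of the
        narrow mycelium band does not mask the comparison."""
        base = SimConfig(dx=0.5, shape=(800,))
        t1, t2 = run(base), run(base.replace(substeps=10))
        dF = aligned_profile_difference(t1.final.F, t2.final.F)
        dP = aligned_profile_difference(t1.final.P, t2.final.P)
        assert dF < 0.05 * t1.final.F.max()
        assert dP < 0.05 * t1.final.P.max()


class TestFrontSpeed:
    def _synthetic(self, speed):
        times = np.arange(0, 500, 10.0)
        cfg = SimConfig(shape=(400,), n_steps=490)
        snaps = [StateFields(*(np.zeros(400) for _ in range(6)))] * len(times)
        return Trajectory(times=times, snapshots=snaps,
                          front_positions=speed * times, config=cfg)

    def test_exact_linear_input(self):
        fit = front_speed(self._synthetic(0.3), (0, 400))
        assert fit.speed == pytest.approx(0.3, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.residual == pytest.approx(0.0, abs=1e-9)

    def test_too_few_snapshots_rejected(self):
        with pytest.raises(ValueError, match=">= 3 snapshots"):
            front_speed(self._synthetic(0.3), (0, 15))

    def test_boundary_contamination_rejected(self):
        traj = self._synthetic(1.0)  # reaches 490 dm on a 400-cell grid
        with pytest.raises(ValueError, match="boundary"):
            front_speed(traj, (0, 400))

    def test_speed_increases_with_fungal_growth(self):
        """A faster-growing fungus pushes a faster front."""
        speeds = []
        for g_F in (0.025, 0.05):
            traj = run(SimConfig(params=ModelParams(g_F=g_F)))
            speeds.append(front_speed(traj, (1000, 1800)).speed)
        assert speeds[1] > speeds[0]
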