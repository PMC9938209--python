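"""Right-hand-side assembly and the stabilized time-stepping schemes."""

import numpy as np
import pytest

import phasecell as pc
from phasecell.dynamics import _assemble_all
from phasecell.errors import ConfigurationError, InstabilityError

from conftest import single_cell_state, two_cell_state


class TestDoubleWellPrime:
    @pytest.mark.parametrize(
        "phi,expected",
        [(0.0, 0.0), (1.0, 0.0), (0.5, 0.0), (0.25, 0.1875)],
    )
    def test_values(self, phi, expected):
        assert pc.double_well_prime(np.float64(phi)) == pytest.approx(
            expected, abs=1e-15
        )

    def test_matches_polynomial(self, rng):
        phi = rng.uniform(-0.2, 1.2, size=100)
        direct = 4 * phi**3 - 6 * phi**2 + 2 * phi
        assert np.allclose(pc.double_well_prime(phi), direct, atol=1e-14)


class TestAssembleRhs:
    def test_isolated_cell_at_target_volume_reduces_to_double_well(
        self, grid32
    ):
        state = single_cell_state(grid32, radius=4.0)
        state.cells[0].target_volume = pc.integrate(grid32, state.phi[0])
        params = pc.ModelParams()
        F = pc.assemble_rhs(state, params, 0)
        expected = -params.gamma * params.c * pc.double_well_prime(
            state.phi[0]
        )
        assert np.max(np.abs(F - expected)) < 1e-12

    def test_empty_field_gives_zero_rhs(self, grid32):
        state = single_cell_state(grid32, radius=4.0)
        state.phi[0] = np.zeros(grid32.shape)
        state.cells[0].target_volume = 100.0
        F = pc.assemble_rhs(state, pc.ModelParams(), 0)
        assert np.max(np.abs(F)) == 0.0

    def test_relative_mode_growth_sign(self, grid32):
        # at half the target volume the relative constriction pushes
        # outward: VOL = +M'/2 · |∇φ|
        state = single_cell_state(grid32, radius=4.0)
        vol = pc.integrate(grid32, state.phi[0])
        state.cells[0].target_volume = 2.0 * vol
        params = pc.ModelParams(volume_mode="relative", M_rel=8.0)
        F = pc.assemble_rhs(state, params, 0)
        geom = pc.gradient(grid32, state.phi[0])
        dw = -params.gamma * params.c * pc.double_well_prime(state.phi[0])
        vol_term = F - dw
        expected = 0.5 * params.M_rel * geom.grad_magnitude
        assert np.max(np.abs(vol_term - expected)) < 1e-10

    def test_relative_mode_rejects_nonpositive_target(self, grid32):
        state = single_cell_state(grid32, radius=4.0)
        state.cells[0].target_volume = 0.0
        with pytest.raises(ConfigurationError):
            pc.assemble_rhs(
                state, pc.ModelParams(volume_mode="relative"), 0
            )

    def test_mirror_symmetric_cells_have_mirror_rhs(self, grid32):
        # two cells placed symmetrically about the x mid-plane; the grid
        # maps onto itself under ix -> (nx - ix) % nx
        L = grid32.box[0]
        state = two_cell_state(
            grid32, radius=3.0, centers=[(5.0, 8, 8), (L - 5.0, 8, 8)]
        )
        params = pc.ModelParams()
        F0 = pc.assemble_rhs(state, params, 0)
        F1 = pc.assemble_rhs(state, params, 1)
        mirrored = np.roll(F1[::-1, :, :], 1, axis=0)
        assert np.max(np.abs(F0 - mirrored)) < 1e-10

    def test_assembled_form_equals_literal_forces(self, grid32):
        # the governing forces carry ∇φ/|∇φ|² factors that cancel against
        # the ·∇φ of the transport equation; verify the cancellation
        # numerically on the interface region
        state = two_cell_state(
            grid32, radius=3.0, centers=[(6.0, 8, 8), (11.0, 8, 8)]
        )
        egg = pc.eggshell_field(
            pc.Eggshell(semi_axes=(7, 7, 7), center=(8, 8, 8)), grid32
        )
        state.eggshell = egg
        params = pc.ModelParams()
        i = 0
        phi = state.phi[i]
        geom = pc.gradient(grid32, phi)
        lap = pc.laplacian(grid32, phi)
        gm2 = geom.grad_magnitude**2
        mask = geom.grad_magnitude > 1e-2
        n_hat = geom.inward_normal
        vol_err = pc.integrate(grid32, phi) - state.cells[i].target_volume
        F_ten = (
            -params.gamma
            * (lap - params.c * pc.double_well_prime(phi))
            * geom.grad
            / np.where(mask, gm2, 1.0)
        )
        F_vol = params.M * vol_err * n_hat
        F_rep = (
            (params.g_e * phi * egg**2 + params.g * phi * state.phi[1] ** 2)
            * geom.grad
            / np.where(mask, gm2, 1.0)
        )
        F_atr = state.sigma[i, 1] * pc.gradient(grid32, state.phi[1]).grad
        literal = -np.sum(
            (F_ten + F_vol + F_rep + F_atr) * geom.grad, axis=0
        )
        assembled = params.gamma * lap + pc.assemble_rhs(state, params, i)
        scale = np.max(np.abs(assembled[mask]))
        assert np.max(np.abs(literal[mask] - assembled[mask])) < 1e-8 * scale


class TestFirstOrderStep:
    def test_mode_update_matches_closed_form(self, grid_small):
        state = two_cell_state(
            grid_small, radius=2.0, centers=[(4.0, 4, 4), (8.0, 4, 4)]
        )
        params = pc.ModelParams(dt=2.0, S=12.0)
        Fs = [pc.assemble_rhs(state, params, i) for i in range(2)]
        before = [p.copy() for p in state.phi]
        pc.step_first_order(state, params)
        a = params.tau / params.dt + params.S
        denom = a + params.gamma * grid_small.k_squared
        for i in range(2):
            expect_hat = (
                a * grid_small.fft(before[i]) + grid_small.fft(Fs[i])
            ) / denom
            got_hat = grid_small.fft(state.phi[i])
            assert np.max(np.abs(got_hat - expect_hat)) < 1e-12 * np.max(
                np.abs(expect_hat)
            )

    def test_zero_mode_conserved_when_rhs_vanishes(self, grid_small):
        # uniform interior phase: W'(1) = 0, no gradients, volume on target
        state = single_cell_state(grid_small, radius=2.0)
        state.phi[0] = np.ones(grid_small.shape)
        state.cells[0].target_volume = pc.integrate(
            grid_small, state.phi[0]
        )
        pc.step_first_order(state, pc.ModelParams(dt=2.0, S=12.0))
        assert np.max(np.abs(state.phi[0] - 1.0)) < 1e-12

    def test_agrees_with_explicit_euler_at_second_order_in_dt(
        self, grid_small
    ):
        def gap(dt):
            params = pc.ModelParams(dt=dt, S=0.5)
            s1 = single_cell_state(grid_small, radius=2.5)
            s2 = s1.copy()
            pc.step_first_order(s1, params)
            pc.step_explicit(s2, params)
            return np.max(np.abs(s1.phi[0] - s2.phi[0]))

        ratio = gap(2e-2) / gap(1e-2)
        assert 3.0 < ratio < 5.0  # gap shrinks like O(δt²)

    def test_instability_detected_and_named(self, grid_small):
        state = single_cell_state(grid_small, radius=2.0)
        state.phi[0] = state.phi[0] + 100.0
        with pytest.raises(InstabilityError, match="cell"):
            pc.step_first_order(state, pc.ModelParams())


class TestSecondOrderStep:
    def test_requires_history(self, grid_small):
        state = single_cell_state(grid_small, radius=2.0)
        with pytest.raises(ConfigurationError, match="history"):
            pc.step_second_order(state, pc.ModelParams())

    def test_uniform_fixed_point_unchanged(self, grid_small):
        state = single_cell_state(grid_small, radius=2.0)
        state.phi[0] = np.ones(grid_small.shape)
        state.cells[0].target_volume = pc.integrate(
            grid_small, state.phi[0]
        )
        params = pc.ModelParams(dt=2.0, S=12.0)
        pc.step_first_order(state, params, keep_history=True)
        pc.step_second_order(state, params)
        assert np.max(np.abs(state.phi[0] - 1.0)) < 1e-12

    def test_observed_order_two_on_linear_mode_problem(
        self, grid_small, monkeypatch
    ):
        # per-mode linear test: replace the nonlinear term by λφ so the
        # exact solution is a decaying exponential per Fourier mode, and
        # measure the Richardson slope of the terminal error
        import phasecell.dynamics as dyn

        lam = -0.2
        monkeypatch.setattr(
            dyn,
            "_assemble_all",
            lambda state, params, noise: [lam * p for p in state.phi],
        )
        x, _, _ = grid_small.coords()
        L = grid_small.box[0]
        k = 2 * np.pi / L
        # positive mean keeps the field mass positive (the evolution loop
        # tracks mass centers); mean and cosine modes decay independently
        u0 = 2.0 + np.cos(k * x) * np.ones(grid_small.shape)
        params0 = pc.ModelParams()
        T = 8.0
        exact = 2.0 * np.exp(lam * T / params0.tau) + (
            u0 - 2.0
        ) * np.exp((-params0.gamma * k**2 + lam) * T / params0.tau)

        def solve(dt):
            state = single_cell_state(grid_small, radius=2.5)
            state.phi[0] = u0.copy()
            params = params0.with_(dt=dt, S=3.0)
            pc.evolve(
                state,
                params,
                scheme="semi_implicit_2",
                stop=pc.FixedDuration(T),
                check_every=10**6,
                raise_on_disappearance=False,  # synthetic decaying field
            )
            return state.phi[0]

        errs = [np.max(np.abs(solve(T / n) - exact)) for n in (8, 16, 32)]
        slopes = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(np.abs(slopes - 2.0) < 0.2)

    def test_nonlinear_single_cell_converges_at_second_order(
        self, grid_small
    ):
        # Richardson check on the full nonlinear path at fine steps
        T = 8.0

        def solve(dt):
            state = single_cell_state(grid_small, radius=2.5, width=0.8)
            params = pc.ModelParams(
                dt=dt, S=6.0, volume_mode="relative", c=2.0
            )
            pc.evolve(
                state,
                params,
                scheme="semi_implicit_2",
                stop=pc.FixedDuration(T),
                check_every=10**6,
            )
            return state.phi[0]

        ref = solve(T / 1024)
        errs = [np.max(np.abs(solve(T / n) - ref)) for n in (64, 128)]
        slope = np.log2(errs[0] / errs[1])
        assert abs(slope - 2.0) < 0.2

    def test_bootstrap_after_division_produces_finite_fields(
        self, grid32
    ):
        state = two_cell_state(
            grid32, radius=3.0, centers=[(6.0, 8, 8), (11.0, 8, 8)]
        )
        params = pc.ModelParams(dt=2.0, S=12.0, volume_mode="relative", c=2.0)
        pc.evolve(
            state,
            params,
            scheme="semi_implicit_2",
            stop=pc.FixedDuration(8.0),
        )
        event = pc.DivisionEvent(
            parent="c0",
            axis=(0, 0, 1),
            ratio=0.5,
            group=1,
            child_names=("c0a", "c0b"),
        )
        pc.divide_cell(state, event)
        assert state.history is None  # stale multistep data dropped
        pc.evolve(
            state,
            params,
            scheme="semi_implicit_2",
            stop=pc.FixedDuration(8.0),
        )
        for p in state.phi:
            assert np.all(np.isfinite(p))


class TestEvolve:
    def test_empty_state_returns_immediately(self, grid_small):
        state = pc.SimState(
            grid=grid_small, phi=[], cells=[], sigma=np.zeros((0, 0))
        )
        res = pc.evolve(state, pc.ModelParams(), stop=pc.FixedDuration(10.0))
        assert res.stop_reason == "empty"
        assert res.trajectory == []

    def test_fixed_duration_terminates_on_time(self, grid_small):
        state = single_cell_state(grid_small, radius=2.0)
        params = pc.ModelParams(dt=2.0, volume_mode="relative", c=2.0)
        res = pc.evolve(
            state, params, stop=pc.FixedDuration(100.0), check_every=7
        )
        assert res.state.time == pytest.approx(100.0, abs=params.dt)

    def test_noise_stream_reproducible_from_seed(self, grid_small):
        def run():
            state = single_cell_state(grid_small, radius=2.5)
            state.rng_seed = 77
            params = pc.ModelParams(
                volume_mode="relative",
                c=2.0,
                kappa=0.3,
                noise_on=True,
                dt=1.0,
                S=12.0,
            )
            pc.evolve(state, params, stop=pc.FixedDuration(10.0))
            return state.phi[0]

        assert np.array_equal(run(), run())

    def test_symmetric_initial_data_stays_symmetric(self, grid32):
        L = grid32.box[0]
        state = two_cell_state(
            grid32, radius=3.0, centers=[(5.5, 8, 8), (L - 5.5, 8, 8)]
        )
        params = pc.ModelParams(dt=2.0, S=12.0, volume_mode="relative", c=2.0)
        pc.evolve(state, params, scheme="semi_implicit_2", stop=pc.FixedDuration(40.0))
        mirrored = np.roll(state.phi[1][::-1, :, :], 1, axis=0)
        assert np.max(np.abs(state.phi[0] - mirrored)) < 1e-9


class TestOptimizeStabilization:
    def test_returns_minimal_stable_accurate_value(self):
        def run(S):
            if S < 1.0:
                raise InstabilityError("diverged")
            return S

        scan = pc.optimize_stabilization(
            run, pc.s_grid(0.0, 3.0, 0.5), accuracy_check=lambda s: s <= 2.0
        )
        assert scan.optimal == 1.0
        assert ("ok" == scan.trials[-1][1]) and scan.succeeded

    def test_all_values_pass_for_unconditionally_stable_problem(self):
        scan = pc.optimize_stabilization(lambda S: S, pc.s_grid(0.0, 1.0, 0.1))
        assert scan.optimal == 0.0

    def test_failure_is_reported_not_raised(self):
        def run(S):
            raise InstabilityError("always")

        scan = pc.optimize_stabilization(run, [0.0, 0.1])
        assert not scan.succeeded
        assert all(status == "unstable" for _, status in scan.trials)

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            pc.optimize_stabilization(lambda S: S, [])

    def test_two_cell_problem_stabilized_at_large_dt(self, grid_small):
        # at δt = 2 with a stiffer surface tension the plain semi-implicit
        # scheme (S = 0) diverges while a finite S renders the run finite
        # and keeps the fields phase-like
        def run(S):
            state = two_cell_state(
                grid_small,
                radius=2.0,
                centers=[(4.0, 6, 6), (8.0, 6, 6)],
                width=0.8,
            )
            params = pc.ModelParams(
                dt=2.0,
                S=S,
                gamma=1.0,
                volume_mode="relative",
                c=2.0,
            )
            pc.evolve(
                state,
                params,
                scheme="semi_implicit_1",
                stop=pc.FixedDuration(20.0),
                raise_on_disappearance=False,
            )
            return state

        def accurate(state):
            return all(float(np.max(p)) > 0.5 for p in state.phi)

        scan = pc.optimize_stabilization(
            run, pc.s_grid(0.0, 12.0, 2.0), accuracy_check=accurate
        )
        assert scan.succeeded
        assert scan.trials[0] == (0.0, "unstable")
        assert scan.optimal > 0.0
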