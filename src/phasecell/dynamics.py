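"""Right-hand-side assembly and stabilized semi-implicit time stepping.

The dynamics of each cell is τ ∂φ_i/∂t = γΔφ_i + F_i with the nonlinear
term F_i assembled in the *force-dotted* form (see :mod:`phasecell.params`).
The literal force expressions contain ∇φ/|∇φ|² factors that cancel exactly
against the ·∇φ of the transport equation; only the assembled form is ever
evaluated, so no division by |∇φ| occurs anywhere off the interface.

Three time-stepping schemes advance the fields, all solved per Fourier mode
(the Laplacian is diagonal in k-space):

``explicit``
    Forward Euler, φ^{n+1} = φ^n + (δt/τ)(γΔφ^n + F^n).  Accurate but
    stability-limited to small δt; used mainly as an oracle.
``semi_implicit_1``
    First-order stabilized scheme,
    (τ/δt + S + γ|k|²) φ̂^{n+1} = (τ/δt + S) φ̂^n + F̂^n.
    S = 0 recovers the plain semi-implicit scheme.  The stabilization term
    −S(φ^{n+1} − φ^n) permits large δt but adds O(δt) numerical damping
    (in-silico durations inflate as S·δt grows).
``semi_implicit_2``
    Second-order stabilized scheme (BDF2-type),
    (3τ/(2δt) + S + γ|k|²) φ̂^{n+1}
        = (τ/(2δt))(4φ̂^n − φ̂^{n−1}) + 2F̂^n − F̂^{n−1} + S(2φ̂^n − φ̂^{n−1}).
    The stabilization enters as a second difference, so its damping is
    O(δt²) and the scheme keeps in-silico time scales intact at large δt.
    The first step after a (re)start bootstraps with one first-order step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DisappearanceError,
    InstabilityError,
)
from .grid import Grid, gradient, integrate
from .kinetics import (
    STEADY_THRESHOLD,
    VelocitySeries,
    centers_of_state,
    detect_quasi_steady,
    detect_steady,
    rms_displacement_velocity,
)
from .params import ModelParams
from .state import SimState, make_rng

__all__ = [
    "double_well_prime",
    "assemble_rhs",
    "draw_noise",
    "step_explicit",
    "step_first_order",
    "step_second_order",
    "evolve",
    "EvolveResult",
    "FixedDuration",
    "SteadyState",
    "QuasiSteady",
    "EquilibriumOrCap",
    "optimize_stabilization",
    "StabilizationScan",
    "s_grid",
]

#: |φ| above this is treated as a numerical blow-up.
BLOWUP_THRESHOLD = 10.0

#: Cells whose global max φ drops below this have disappeared.
DISAPPEARANCE_THRESHOLD = 0.5


def double_well_prime(phi: np.ndarray) -> np.ndarray:
    """W′(φ) = 4φ³ − 6φ² + 2φ for the double well W(φ) = φ²(φ−1)²."""
    return phi * (2.0 + phi * (-6.0 + 4.0 * phi))


def draw_noise(n_cells: int, params: ModelParams, rng) -> Optional[np.ndarray]:
    """Per-cell stochastic drift vectors ξ_i for one step, or None.

    Each cell gets an i.i.d. standard-normal 3-vector, redrawn every step.
    With ``noise_sqrt_dt_scaling`` the vectors are scaled by 1/√δt so the
    accumulated displacement variance becomes δt-independent.
    """
    if not params.noise_on or params.kappa == 0.0:
        return None
    xi = rng.standard_normal((n_cells, 3))
    if params.noise_sqrt_dt_scaling:
        xi = xi / np.sqrt(params.dt)
    return xi


def _volume_term(params: ModelParams, volume: float, target: float, gmag):
    if params.volume_mode == "absolute":
        return params.M * (target - volume) * gmag
    if target <= 0:
        raise ConfigurationError(
            "relative volume constriction requires target_volume > 0"
        )
    return params.M_rel * (1.0 - volume / target) * gmag


class _Precomp:
    """Shared per-step quantities: Σφ², all gradients, σ-weighted gradients."""

    __slots__ = ("sumsq", "grads", "gmags", "weighted", "eggshell_sq")

    def __init__(self, state: SimState):
        grid = state.grid
        n = state.n_cells
        self.sumsq = grid.zeros()
        for p in state.phi:
            self.sumsq += p * p
        grads = np.empty((n, 3) + grid.shape)
        self.gmags = []
        for i, p in enumerate(state.phi):
            geom = gradient(grid, p)
            grads[i] = geom.grad
            self.gmags.append(geom.grad_magnitude)
        self.grads = grads
        # Σ_j σ_ij ∇φ_j for every i in one BLAS contraction
        if n and np.any(state.sigma):
            self.weighted = np.tensordot(state.sigma, grads, axes=([1], [0]))
        else:
            self.weighted = None
        self.eggshell_sq = (
            None if state.eggshell is None else state.eggshell**2
        )


def _rhs(state: SimState, params: ModelParams, i: int, pre: _Precomp, xi):
    grid = state.grid
    phi = state.phi[i]
    grad_i = pre.grads[i]
    F = -params.gamma * params.c * double_well_prime(phi)
    if pre.eggshell_sq is not None:
        F -= params.g_e * phi * pre.eggshell_sq
    others_sq = pre.sumsq - phi * phi
    F -= params.g * phi * others_sq
    # attraction: −∇φ_i · Σ_j σ_ij ∇φ_j
    if pre.weighted is not None:
        w = pre.weighted[i]
        F -= grad_i[0] * w[0] + grad_i[1] * w[1] + grad_i[2] * w[2]
    F += _volume_term(
        params, integrate(grid, phi), state.cells[i].target_volume, pre.gmags[i]
    )
    if xi is not None:
        F -= params.kappa * (
            xi[0] * grad_i[0] + xi[1] * grad_i[1] + xi[2] * grad_i[2]
        )
    return F


def assemble_rhs(
    state: SimState,
    params: ModelParams,
    i: int,
    noise: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Nonlinear term F_i for cell ``i`` of the current state.

    ``noise`` is the (N, 3) array of per-cell ξ vectors for this step (from
    :func:`draw_noise`) or None.
    """
    pre = _Precomp(state)
    xi = None if noise is None else noise[i]
    return _rhs(state, params, i, pre, xi)


def _assemble_all(state: SimState, params: ModelParams, noise) -> list:
    pre = _Precomp(state)
    return [
        _rhs(state, params, i, pre, None if noise is None else noise[i])
        for i in range(state.n_cells)
    ]


def _check_stability(state: SimState):
    for i, p in enumerate(state.phi):
        if not np.all(np.isfinite(p)) or np.max(np.abs(p)) > BLOWUP_THRESHOLD:
            raise InstabilityError(
                f"phase field of cell {state.cells[i].name!r} became unstable "
                f"at step {state.step}",
                cell_index=i,
            )


def step_explicit(state: SimState, params: ModelParams, noise=None) -> SimState:
    """One forward-Euler step (spectral Laplacian); mutates ``state``."""
    grid = state.grid
    Fs = _assemble_all(state, params, noise)
    coef = params.dt / params.tau
    for i in range(state.n_cells):
        lap = grid.ifft(-grid.k_squared * grid.fft(state.phi[i]))
        state.phi[i] = state.phi[i] + coef * (params.gamma * lap + Fs[i])
    state.time += params.dt
    state.step += 1
    state.history = None
    _check_stability(state)
    return state


def step_first_order(
    state: SimState, params: ModelParams, noise=None, keep_history: bool = False
) -> SimState:
    """One stabilized first-order semi-implicit step; mutates ``state``.

    Per Fourier mode: φ̂^{n+1} = [(τ/δt + S) φ̂^n + F̂^n] / (τ/δt + S + γ|k|²).
    The k = 0 mode has amplification exactly 1 when F = 0 (mass conserving).
    With ``keep_history`` the pre-step fields and nonlinear terms are stored
    so a second-order scheme can take over next step (bootstrap).
    """
    grid = state.grid
    a = params.tau / params.dt + params.S
    denom = a + params.gamma * grid.k_squared
    Fs = _assemble_all(state, params, noise)
    old = [p.copy() for p in state.phi] if keep_history else None
    for i in range(state.n_cells):
        phat = grid.fft(state.phi[i])
        state.phi[i] = grid.ifft((a * phat + grid.fft(Fs[i])) / denom)
    state.history = {"phi": old, "F": Fs} if keep_history else None
    state.time += params.dt
    state.step += 1
    _check_stability(state)
    return state


def step_second_order(state: SimState, params: ModelParams, noise=None) -> SimState:
    """One stabilized second-order semi-implicit step; mutates ``state``.

    Requires ``state.history`` holding (φ^{n−1}, F^{n−1}); use a
    first-order step with ``keep_history=True`` to bootstrap after a start,
    restart, or division event.
    """
    if state.history is None or state.history["phi"] is None:
        raise ConfigurationError(
            "second-order step requires history; bootstrap with "
            "step_first_order(..., keep_history=True)"
        )
    grid = state.grid
    half = params.tau / (2.0 * params.dt)
    denom = 3.0 * half + params.S + params.gamma * grid.k_squared
    Fs = _assemble_all(state, params, noise)
    phi_prev = state.history["phi"]
    F_prev = state.history["F"]
    new_phi = []
    for i in range(state.n_cells):
        phat = grid.fft(state.phi[i])
        phat_prev = grid.fft(phi_prev[i])
        rhs_hat = (
            half * (4.0 * phat - phat_prev)
            + grid.fft(2.0 * Fs[i] - F_prev[i])
            + params.S * (2.0 * phat - phat_prev)
        )
        new_phi.append(grid.ifft(rhs_hat / denom))
    state.history = {"phi": state.phi, "F": Fs}
    state.phi = new_phi
    state.time += params.dt
    state.step += 1
    _check_stability(state)
    return state


# ---------------------------------------------------------------------------
# stop rules and the evolution loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedDuration:
    """Evolve for a fixed in-silico duration T."""

    T: float


@dataclass(frozen=True)
class SteadyState:
    """Stop at the first v̄ sample below ``threshold`` (steady state)."""

    threshold: float = STEADY_THRESHOLD
    cap_time: Optional[float] = None


@dataclass(frozen=True)
class QuasiSteady:
    """Stop at the first local minimum of the smoothed v̄(t) curve."""

    window: int = 51
    cap_time: Optional[float] = None


@dataclass(frozen=True)
class EquilibriumOrCap:
    """Stop at mechanical equilibrium (v̄ < threshold) or after cap_time."""

    threshold: float = STEADY_THRESHOLD
    cap_time: float = 10000.0


StopRule = FixedDuration | SteadyState | QuasiSteady | EquilibriumOrCap


@dataclass
class EvolveResult:
    """Outcome of :func:`evolve`: final state, snapshots, v̄ series."""

    state: SimState
    trajectory: list
    velocity: VelocitySeries
    stop_reason: str = ""


_STEPPERS = {
    "explicit": step_explicit,
    "semi_implicit_1": step_first_order,
    "semi_implicit_2": step_second_order,
}


def evolve(
    state: SimState,
    params: ModelParams,
    scheme: str = "semi_implicit_1",
    stop: StopRule = FixedDuration(100.0),
    *,
    check_every: int = 10,
    snapshot_every: Optional[int] = None,
    max_steps: int = 2_000_000,
    rng=None,
    raise_on_disappearance: bool = True,
) -> EvolveResult:
    """Advance ``state`` under the chosen scheme until the stop rule fires.

    v̄ is sampled every ``check_every`` steps (displacement over the whole
    interval divided by the elapsed time).  Snapshots are deep copies taken
    every ``snapshot_every`` steps (final state always included).  On
    instability or cell disappearance a structured error carrying the last
    good snapshot is raised; pass ``raise_on_disappearance=False`` to let
    collapsing cells evolve (e.g. for disappearance scans).

    ``state`` is mutated in place and also returned inside the result.
    """
    if scheme not in _STEPPERS:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    if state.n_cells == 0:
        return EvolveResult(state, [], VelocitySeries(), stop_reason="empty")
    if params.noise_on and rng is None:
        rng = make_rng(state.rng_seed, "noise")

    series = VelocitySeries()
    trajectory = []
    prev_centers = centers_of_state(state)
    prev_time = state.time
    t0 = state.time
    last_good = state.copy()
    steps_done = 0
    reason = "step_cap"

    def _take_step():
        noise = draw_noise(state.n_cells, params, rng) if params.noise_on else None
        if scheme == "semi_implicit_2" and (
            state.history is None or state.history.get("phi") is None
        ):
            step_first_order(state, params, noise, keep_history=True)
        else:
            _STEPPERS[scheme](state, params, noise)

    while steps_done < max_steps:
        block = check_every
        if isinstance(stop, FixedDuration):
            remaining = int(round((t0 + stop.T - state.time) / params.dt))
            if remaining <= 0:
                reason = "fixed_duration"
                break
            block = min(block, remaining)
        for _ in range(block):
            try:
                _take_step()
            except InstabilityError as err:
                err.last_state = last_good
                raise
            steps_done += 1
            if snapshot_every and state.step % snapshot_every == 0:
                trajectory.append(state.copy())

        gone = [
            state.cells[i].name
            for i, p in enumerate(state.phi)
            if float(np.max(p)) < DISAPPEARANCE_THRESHOLD
        ]
        if gone:
            if raise_on_disappearance:
                raise DisappearanceError(
                    f"cell(s) disappeared during evolution: {', '.join(gone)}",
                    cell_names=gone,
                    last_state=last_good,
                )
        else:
            last_good = state.copy()

        curr_centers = centers_of_state(state) if not gone else prev_centers
        if not gone:
            series.append(
                state.time,
                rms_displacement_velocity(
                    prev_centers, curr_centers, state.time - prev_time
                ),
            )
            prev_centers, prev_time = curr_centers, state.time

        if isinstance(stop, FixedDuration):
            if state.time - t0 >= stop.T - 1e-9 * max(1.0, stop.T):
                reason = "fixed_duration"
                break
        elif isinstance(stop, SteadyState):
            if series.vbar and series.vbar[-1] < stop.threshold:
                reason = "steady"
                break
            if stop.cap_time is not None and state.time - t0 >= stop.cap_time:
                reason = "cap"
                break
        elif isinstance(stop, QuasiSteady):
            if detect_quasi_steady(series, stop.window) is not None:
                reason = "quasi_steady"
                break
            if stop.cap_time is not None and state.time - t0 >= stop.cap_time:
                reason = "cap"
                break
        elif isinstance(stop, EquilibriumOrCap):
            if series.vbar and series.vbar[-1] < stop.threshold:
                reason = "steady"
                break
            if state.time - t0 >= stop.cap_time - 1e-9 * max(1.0, stop.cap_time):
                reason = "cap"
                break
        else:  # pragma: no cover - guarded by the union type
            raise ConfigurationError(f"unknown stop rule {stop!r}")

    trajectory.append(state.copy())
    return EvolveResult(state, trajectory, series, stop_reason=reason)


# ---------------------------------------------------------------------------
# stabilization-coefficient optimization
# ---------------------------------------------------------------------------


@dataclass
class StabilizationScan:
    """Result of :func:`optimize_stabilization`.

    ``optimal`` is the smallest stable-and-accurate S, or None when no value
    in the grid worked.  ``trials`` lists (S, status) pairs with status in
    {"ok", "unstable", "inaccurate"}.
    """

    optimal: Optional[float]
    trials: list = field(default_factory=list)

    @property
    def succeeded(self) -> bool:
        return self.optimal is not None


def s_grid(start: float, stop: float, step: float = 0.1) -> np.ndarray:
    """Inclusive S scan grid with the conventional step of 0.1."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def optimize_stabilization(
    run: Callable[[float], object],
    S_values: Sequence[float],
    accuracy_check: Optional[Callable[[object], bool]] = None,
) -> StabilizationScan:
    """Scan S values (increasing) for the smallest stable, accurate one.

    ``run(S)`` executes the scenario; instability must surface as an
    :class:`InstabilityError` (or ``NumericalError``).  ``accuracy_check``,
    if given, receives the run outcome and must return True for acceptable
    accuracy.  Returns the first S that is both stable and accurate, with a
    full trial log; when no S works the scan records the failure instead of
    raising.
    """
    S_values = list(S_values)
    if not S_values:
        raise ConfigurationError("empty S grid")
    if any(b < a for a, b in zip(S_values, S_values[1:])):
        raise ConfigurationError("S grid must be increasing")
    trials = []
    optimal = None
    for S in S_values:
        try:
            outcome = run(S)
        except (InstabilityError, FloatingPointError) as exc:
            trials.append((S, "unstable"))
            continue
        if accuracy_check is not None and not accuracy_check(outcome):
            trials.append((S, "inaccurate"))
            continue
        trials.append((S, "ok"))
        optimal = S
        break
    return StabilizationScan(optimal=optimal, trials=trials)
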