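"""Cell division, adhesion rules, and schedule-driven stage pipelines.

Division is an instant splitting of a cell's phase field by a tanh-smoothed
plane normal to a prescribed axis **n** through the cell's mass center r_c,
offset by b along the axis:

    child₊ = φ · (tanh((n·(r − r_c) − b)/ε) + 1)/2,
    child₋ = φ · (tanh((b − n·(r − r_c))/ε) + 1)/2.

The two sigmoids sum to one pointwise, so the split conserves the parent
field exactly; b is solved by bisection so the first child carries a
designated fraction ρ of the parent mass.  Division axes and volume
segregation ratios are *inputs* (measured experimentally in the organism
this emulates), not predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .dynamics import (
    DISAPPEARANCE_THRESHOLD,
    EquilibriumOrCap,
    FixedDuration,
    QuasiSteady,
    SteadyState,
    evolve,
)
from .errors import ConfigurationError, NumericalError, SchedulingError
from .kinetics import center_of_mass
from .params import ModelParams
from .state import AdhesionRules, Cell, SimState

__all__ = [
    "DivisionEvent",
    "Schedule",
    "solve_division_offset",
    "split_phase_field",
    "divide_cell",
    "adhesion_from_rules",
    "detect_disappearance",
    "run_schedule",
    "ScheduleRun",
    "default_stage_trigger",
]


@dataclass(frozen=True)
class DivisionEvent:
    """One prescribed division: parent name, axis, ratio, group index.

    ``ratio`` is the volume fraction assigned to the first child, which
    takes the half-space on the +axis side of the splitting plane.
    """

    parent: str
    axis: tuple
    ratio: float
    group: int
    child_names: tuple

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float)
        norm = float(np.linalg.norm(ax))
        if abs(norm - 1.0) > 1e-3:
            raise ConfigurationError(
                f"division axis of {self.parent!r} is not a unit vector "
                f"(|n| = {norm:.6f})"
            )
        object.__setattr__(self, "axis", tuple(ax / norm))
        if not (0.0 < self.ratio < 1.0):
            raise ConfigurationError(
                f"division ratio of {self.parent!r} must lie in (0, 1), "
                f"got {self.ratio}"
            )
        if len(self.child_names) != 2:
            raise ConfigurationError("child_names must be a pair")


@dataclass
class Schedule:
    """Ordered division groups plus optional per-stage stop rules.

    ``events`` are grouped by their ``group`` index; groups must be numbered
    contiguously from 1 and fire in order.  ``triggers`` optionally maps a
    group index to the stop rule that ends the stage *preceding* it.
    """

    events: list
    triggers: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    @property
    def groups(self) -> list:
        return sorted({e.group for e in self.events})

    def group_events(self, g: int) -> list:
        return [e for e in self.events if e.group == g]

    def validate(self):
        groups = self.groups
        if groups and groups != list(range(1, len(groups) + 1)):
            raise ConfigurationError(
                f"division groups must be contiguous from 1, got {groups}"
            )
        # every parent must exist (as a child of an earlier group or a root)
        produced = set()
        roots = set()
        for g in groups:
            for e in self.group_events(g):
                if e.parent not in produced:
                    roots.add(e.parent)
                for ch in e.child_names:
                    if ch in produced or ch in roots:
                        raise ConfigurationError(
                            f"duplicate cell name {ch!r} in schedule"
                        )
                    produced.add(ch)
        self._roots = roots

    @property
    def roots(self) -> set:
        """Cells the schedule assumes alive before any group fires."""
        return set(self._roots)

    def terminal_names(self, initial=None) -> list:
        """Symbolic execution: run all divisions on names only.

        Starting from ``initial`` (default: the schedule's root cells),
        replace each parent by its two children group by group and return
        the final live-cell name list.  No phase fields are involved.
        """
        alive = list(initial) if initial is not None else sorted(self.roots)
        for g in self.groups:
            for e in self.group_events(g):
                if e.parent not in alive:
                    raise SchedulingError(
                        f"group {g}: parent {e.parent!r} is not alive"
                    )
                idx = alive.index(e.parent)
                alive[idx : idx + 1] = list(e.child_names)
        return alive


def solve_division_offset(
    grid, phi: np.ndarray, axis, ratio: float, eps: float
) -> float:
    """Plane offset b giving the +axis child a mass fraction ``ratio``.

    Solved by bisection over the cell's extent along the axis to a relative
    mass tolerance of 1e-6.
    """
    if not (0.0 < ratio < 1.0):
        raise ConfigurationError("ratio must lie in (0, 1)")
    total = float(np.sum(phi))
    if total <= 0:
        raise NumericalError("cannot split a field with no mass")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rc = center_of_mass(grid, phi)
    x, y, z = grid.coords()
    d = (
        axis[0] * (x - rc[0])
        + axis[1] * (y - rc[1])
        + axis[2] * (z - rc[2])
    )
    support = phi > 1e-6
    if not np.any(support):
        raise NumericalError("degenerate field: empty support")
    lo = float(np.min(d[support])) - 4.0 * eps
    hi = float(np.max(d[support])) + 4.0 * eps

    def frac_minus_target(b):
        w = 0.5 * (np.tanh((d - b) / eps) + 1.0)
        return float(np.sum(phi * w)) / total - ratio

    f_lo, f_hi = frac_minus_target(lo), frac_minus_target(hi)
    if not (f_lo > 0 > f_hi):
        raise NumericalError(
            "division offset does not bracket the requested ratio "
            f"(f({lo:.3g}) = {f_lo:.3g}, f({hi:.3g}) = {f_hi:.3g})"
        )
    return float(brentq(frac_minus_target, lo, hi, xtol=1e-9, rtol=1e-12))


def split_phase_field(grid, phi: np.ndarray, axis, b: float, eps: float):
    """Split φ by the tanh plane; returns (child₊, child₋).

    The two children sum to the parent pointwise (the sigmoid pair is an
    exact partition of unity), so field mass is conserved to rounding.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rc = center_of_mass(grid, phi)
    x, y, z = grid.coords()
    d = (
        axis[0] * (x - rc[0])
        + axis[1] * (y - rc[1])
        + axis[2] * (z - rc[2])
    )
    w = 0.5 * (np.tanh((d - b) / eps) + 1.0)
    return phi * w, phi * (1.0 - w)


def adhesion_from_rules(cells, rules: AdhesionRules) -> np.ndarray:
    """Build the symmetric σ matrix from a binarized adhesion program.

    Listed weak pairs (by cell name) and, when ``sisters_weak`` is set, all
    sister pairs get σ_W; every other off-diagonal entry gets σ_S.
    """
    names = [c.name for c in cells]
    known = set(names)
    for pair in rules.weak_pairs:
        for nm in pair:
            if nm not in known:
                raise ConfigurationError(
                    f"weak pair references unknown cell {nm!r}"
                )
    n = len(cells)
    sigma = np.full((n, n), rules.sigma_strong)
    np.fill_diagonal(sigma, 0.0)
    by_id = {c.id: i for i, c in enumerate(cells)}
    for i in range(n):
        for j in range(i + 1, n):
            weak = frozenset((names[i], names[j])) in rules.weak_pairs
            if rules.sisters_weak and cells[i].sister == cells[j].id:
                weak = True
            if weak:
                sigma[i, j] = sigma[j, i] = rules.sigma_weak
    return sigma


def detect_disappearance(state: SimState) -> list:
    """Ids of cells whose phase field is globally below 0.5."""
    return [
        state.cells[i].id
        for i, p in enumerate(state.phi)
        if float(np.max(p)) < DISAPPEARANCE_THRESHOLD
    ]


def divide_cell(
    state: SimState,
    event: DivisionEvent,
    eps: Optional[float] = None,
) -> SimState:
    """Execute one division in place: replace the parent by two children.

    The children inherit ρ·V and (1−ρ)·V as target volumes, mutual sister
    links, and adhesion rows rebuilt from ``state.adhesion_rules`` when
    present (otherwise both children copy the parent's rows, with a zero
    sister entry).  ``eps`` defaults to 2·δl.
    """
    if eps is None:
        eps = 2.0 * state.grid.spacing
    try:
        idx = state.index_of(event.parent)
    except KeyError:
        raise SchedulingError(
            f"cannot divide {event.parent!r}: not among the live cells"
        ) from None
    parent = state.cells[idx]
    phi = state.phi[idx]
    if float(np.max(phi)) < DISAPPEARANCE_THRESHOLD:
        raise SchedulingError(
            f"cannot divide {event.parent!r}: phase field has disappeared"
        )
    b = solve_division_offset(state.grid, phi, event.axis, event.ratio, eps)
    child_plus, child_minus = split_phase_field(
        state.grid, phi, event.axis, b, eps
    )
    next_id = max((c.id for c in state.cells), default=-1) + 1
    name1, name2 = event.child_names
    c1 = Cell(
        id=next_id,
        name=name1,
        type_label=parent.type_label,
        parent=parent.name,
        sister=next_id + 1,
        generation=parent.generation + 1,
        target_volume=event.ratio * parent.target_volume,
    )
    c2 = Cell(
        id=next_id + 1,
        name=name2,
        type_label=parent.type_label,
        parent=parent.name,
        sister=next_id,
        generation=parent.generation + 1,
        target_volume=(1.0 - event.ratio) * parent.target_volume,
    )
    state.cells[idx : idx + 1] = [c1, c2]
    state.phi[idx : idx + 1] = [child_plus, child_minus]
    if state.adhesion_rules is not None:
        state.sigma = adhesion_from_rules(state.cells, state.adhesion_rules)
    else:
        n_old = state.sigma.shape[0]
        sigma = np.insert(state.sigma, idx, state.sigma[idx], axis=0)
        sigma = np.insert(sigma, idx, sigma[:, idx], axis=1)
        sigma[idx, idx + 1] = sigma[idx + 1, idx] = 0.0
        np.fill_diagonal(sigma, 0.0)
        state.sigma = sigma
    state.history = None  # multistep history is invalid across divisions
    state.validate()
    return state


def default_stage_trigger(n_cells: int):
    """Stage-ending stop rule used when a schedule does not override it.

    Steady state for the 1- to 4-cell stages, first quasi-steady state for
    the 6- and 7-cell stages, a fixed in-silico duration of 15,000 for the
    8-cell stage, and equilibrium-or-10,000-cap afterwards.
    """
    if n_cells <= 4:
        return SteadyState()
    if n_cells in (5, 6, 7):
        return QuasiSteady()
    if n_cells == 8:
        return FixedDuration(15000.0)
    return EquilibriumOrCap(cap_time=10000.0)


@dataclass
class ScheduleRun:
    """Trajectory and event log of :func:`run_schedule`."""

    state: SimState
    snapshots: list
    events: list  # JSON-able dicts
    velocity: dict  # group index (stage label) -> VelocitySeries


def run_schedule(
    schedule: Schedule,
    params: ModelParams,
    initial: SimState,
    *,
    scheme: str = "semi_implicit_2",
    eps: Optional[float] = None,
    terminal_stop=None,
    check_every: int = 10,
    max_steps_per_stage: int = 200_000,
) -> ScheduleRun:
    """Run the evolve → trigger → divide loop over all division groups.

    Each stage evolves under its trigger (``schedule.triggers[group]`` or
    the cell-count default), then the group's divisions fire instantly in
    listed order.  After the last group the system evolves once more under
    ``terminal_stop`` (default: the cell-count default rule).  Cell
    disappearance aborts the run with a structured error naming the cell.
    """
    state = initial
    events_log = []
    snapshots = []
    velocity = {}

    for g in schedule.groups:
        stop = schedule.triggers.get(g, default_stage_trigger(state.n_cells))
        res = evolve(
            state,
            params,
            scheme=scheme,
            stop=stop,
            check_every=check_every,
            max_steps=max_steps_per_stage,
        )
        velocity[g] = res.velocity
        events_log.append(
            {
                "kind": "stage",
                "before_group": g,
                "n_cells": state.n_cells,
                "duration": res.velocity.t[-1] - res.velocity.t[0]
                if len(res.velocity) > 1
                else state.time,
                "stop_reason": res.stop_reason,
                "time": state.time,
            }
        )
        for e in schedule.group_events(g):
            divide_cell(state, e, eps=eps)
            events_log.append(
                {
                    "kind": "division",
                    "group": g,
                    "parent": e.parent,
                    "children": list(e.child_names),
                    "ratio": e.ratio,
                    "time": state.time,
                }
            )
        snapshots.append(state.copy())

    stop = terminal_stop or default_stage_trigger(state.n_cells)
    res = evolve(
        state,
        params,
        scheme=scheme,
        stop=stop,
        check_every=check_every,
        max_steps=max_steps_per_stage,
    )
    velocity["terminal"] = res.velocity
    events_log.append(
        {
            "kind": "stage",
            "before_group": None,
            "n_cells": state.n_cells,
            "stop_reason": res.stop_reason,
            "time": state.time,
        }
    )
    snapshots.append(state.copy())
    return ScheduleRun(
        state=state, snapshots=snapshots, events=events_log, velocity=velocity
    )
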