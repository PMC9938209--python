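"""Eggshell environments and synthetic-multicellular scenario building.

Two confinement styles are supported: a (truncated-)ellipsoidal eggshell
phase field φ_e that repels cells inward through the g_e coupling, and the
open cubic domain of the engineered-aggregate (synNotch-style) scenarios,
where overlap-free initial positions are produced by a random packing
relaxation:

    F_{i,j}        = k₁ (r̄_i − r̄_j)      when |r̄_i − r̄_j| < 2R, else 0,
    F_{boundary,i} = k₂ (d − R) inward    when a wall distance d < R, else 0,

iterated as r̄_i ← r̄_i + F_{boundary,i} + Σ_{j≠i} F_{i,j} until every pair
is at least 2R apart and every center at least R from the walls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError, PackingError
from .grid import Grid, tanh_ball
from .kinetics import center_of_mass
from .state import Cell, SimState

__all__ = [
    "Eggshell",
    "eggshell_field",
    "PackingState",
    "pack_initial_positions",
    "fields_from_centers",
    "apply_type_transition",
    "ablate_half",
    "dissociate",
]

#: Default synNotch noise strength κ = √5/10.
SYNNOTCH_KAPPA = np.sqrt(5.0) / 10.0

#: Numerical tolerance (µm) on the packing clearances.  The relaxation
#: approaches the clearance targets asymptotically from below, so an exact
#: inequality would never terminate; 1e-6 µm (a picometer) is far below any
#: physically meaningful scale and below the grid resolution by six orders.
CLEARANCE_TOL = 1e-6


@dataclass(frozen=True)
class Eggshell:
    """Truncated-ellipsoid eggshell specification.

    ``semi_axes`` are the ellipsoid semi-axes (µm), ``center`` its center in
    box coordinates; ``truncation`` is an optional (normal, offset) pair
    clipping the interior to the half-space normal·(r − center) < offset.
    The resulting field φ_e is ≈ 0 strictly inside and ≈ 1 strictly outside
    (the opposite convention to cell fields), with a tanh profile of width
    ``interface_width`` across the shell.
    """

    semi_axes: tuple
    center: tuple
    truncation: Optional[tuple] = None
    interface_width: float = 1.0

    def __post_init__(self):
        if len(self.semi_axes) != 3 or any(a <= 0 for a in self.semi_axes):
            raise ConfigurationError("eggshell needs three positive semi-axes")
        if self.interface_width <= 0:
            raise ConfigurationError("eggshell interface_width must be > 0")


def eggshell_field(spec: Eggshell, grid: Grid) -> np.ndarray:
    """Rasterize the eggshell phase field φ_e on the grid.

    Uses the first-order signed-distance estimate d ≈ (ρ − 1)/|∇ρ| of the
    scaled ellipsoid coordinate ρ(r) = sqrt(Σ ((x − c)/a)²), which is exact
    for a sphere and a good approximation for moderate aspect ratios.
    """
    a = np.asarray(spec.semi_axes, dtype=float)
    c = np.asarray(spec.center, dtype=float)
    box = np.asarray(grid.box)
    if np.any(c - a < 0) or np.any(c + a > box):
        raise ConfigurationError(
            f"eggshell (center {c.tolist()}, semi-axes {a.tolist()}) exceeds "
            f"the periodic box {box.tolist()}"
        )
    x, y, z = grid.coords()
    u = [(x - c[0]) / a[0], (y - c[1]) / a[1], (z - c[2]) / a[2]]
    rho = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    # signed distance ≈ (ρ − 1)/|∇ρ| with |∇ρ| = sqrt(Σ u_k²/a_k²)/ρ;
    # near the center the quotient degenerates (0/0) and the true distance
    # approaches −min(a), so branch there
    denom = np.sqrt(
        (u[0] / a[0]) ** 2 + (u[1] / a[1]) ** 2 + (u[2] / a[2]) ** 2
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(
            rho > 1e-6,
            (rho - 1.0) * rho / np.maximum(denom, 1e-300),
            -float(np.min(a)),
        )
    phi_e = 0.5 * (1.0 + np.tanh(dist / spec.interface_width))
    if spec.truncation is not None:
        normal, offset = spec.truncation
        normal = np.asarray(normal, dtype=float)
        normal = normal / np.linalg.norm(normal)
        d_plane = (
            normal[0] * (x - c[0])
            + normal[1] * (y - c[1])
            + normal[2] * (z - c[2])
            - offset
        )
        phi_plane = 0.5 * (1.0 + np.tanh(d_plane / spec.interface_width))
        # interior = ellipsoid interior ∩ half-space: union of exteriors
        phi_e = 1.0 - (1.0 - phi_e) * (1.0 - phi_plane)
    return phi_e


@dataclass
class PackingState:
    """Overlap-free random packing of equal spheres in a cube.

    ``centers`` is (N, 3) in µm inside [0, L]³; ``type_labels`` assigns each
    center its cell type; ``iterations`` is the number of relaxation sweeps
    needed to satisfy the postcondition (pairwise distance ≥ 2R, wall
    clearance ≥ R).
    """

    centers: np.ndarray
    type_labels: list
    radius: float
    box_side: float
    k1: float
    k2: float
    iterations: int = 0

    def verify(self):
        r = self.centers
        if r.shape[0] > 1:
            d = np.linalg.norm(r[:, None, :] - r[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 2.0 * self.radius - CLEARANCE_TOL:
                raise PackingError(
                    f"pairwise distance {d.min():.3f} < 2R = {2 * self.radius}"
                )
        wall = np.minimum(r, self.box_side - r)
        if r.size and wall.min() < self.radius - CLEARANCE_TOL:
            raise PackingError(
                f"wall clearance {wall.min():.3f} < R = {self.radius}"
            )


def _relax_once(r, R, L, k1, k2):
    """One synchronous update of all centers; returns the new array."""
    n = len(r)
    force = np.zeros_like(r)
    if n > 1:
        diff = r[:, None, :] - r[None, :, :]  # r_i - r_j
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        overlap = dist < 2.0 * R
        if overlap.any():
            force += k1 * np.sum(diff * overlap[..., None], axis=1)
    # wall repulsion: push inward wherever the near-wall distance < R
    low = r < R
    force += np.where(low, k2 * (R - r), 0.0)
    high = (L - r) < R
    force += np.where(high, -k2 * (R - (L - r)), 0.0)
    return r + force


def pack_initial_positions(
    counts_by_type: dict,
    radius: float,
    box_side: float,
    k1: float = 0.05,
    k2: float = 0.1,
    seed: int = 0,
    max_iter: int = 10000,
    max_restarts: int = 3,
    rng=None,
) -> PackingState:
    """Random overlap-free packing of ``counts_by_type`` spheres in a cube.

    Centers start uniformly random in [0, L]³ and relax under the pairwise
    and boundary repulsions until the postcondition holds.  If the
    iteration cap is hit, packing restarts from a fresh draw of the same
    stream (up to ``max_restarts`` times) before failing.
    """
    if k1 <= 0 or k2 <= 0:
        raise ConfigurationError("packing gains k1, k2 must be > 0")
    n = int(sum(counts_by_type.values()))
    if n == 0:
        return PackingState(
            np.zeros((0, 3)), [], radius, box_side, k1, k2, iterations=0
        )
    fraction = n * (4.0 / 3.0) * np.pi * radius**3 / box_side**3
    if fraction >= 0.45:
        raise ConfigurationError(
            f"packing fraction {fraction:.2f} too dense (must be < 0.45)"
        )
    labels = [t for t, cnt in counts_by_type.items() for _ in range(int(cnt))]
    if rng is None:
        rng = np.random.default_rng(seed)
    for _attempt in range(max_restarts + 1):
        r = rng.uniform(0.0, box_side, size=(n, 3))
        for it in range(1, max_iter + 1):
            state = PackingState(r, labels, radius, box_side, k1, k2, it - 1)
            try:
                state.verify()
                return state
            except PackingError:
                pass
            r = _relax_once(r, radius, box_side, k1, k2)
        final = PackingState(r, labels, radius, box_side, k1, k2, max_iter)
        try:
            final.verify()
            return final
        except PackingError:
            continue
    raise PackingError(
        f"packing did not converge within {max_iter} iterations "
        f"({max_restarts + 1} attempts)"
    )


def fields_from_centers(
    packing: PackingState,
    grid: Grid,
    width: float = 1.0,
    sigma_by_type: Optional[dict] = None,
    rng_seed: int = 0,
) -> SimState:
    """Build a SimState with one tanh ball per packed center.

    ``sigma_by_type`` maps unordered type pairs, e.g. ``{("1", "1"): 0.9,
    ("1", "2"): 0.5, ("2", "2"): 0.9}``, to attraction strengths; missing
    pairs default to 0.  Target volumes are the nominal sphere volumes.
    """
    packing.verify()
    n = len(packing.centers)
    volume = (4.0 / 3.0) * np.pi * packing.radius**3
    cells = [
        Cell(
            id=i,
            name=f"cell{i:03d}",
            type_label=str(packing.type_labels[i]),
            target_volume=volume,
        )
        for i in range(n)
    ]
    phi = [
        tanh_ball(grid, packing.centers[i], packing.radius, width)
        for i in range(n)
    ]
    sigma = np.zeros((n, n))
    if sigma_by_type:
        lookup = {}
        for (a, b), v in sigma_by_type.items():
            lookup[(str(a), str(b))] = float(v)
            lookup[(str(b), str(a))] = float(v)
        for i in range(n):
            for j in range(n):
                if i != j:
                    sigma[i, j] = lookup.get(
                        (cells[i].type_label, cells[j].type_label), 0.0
                    )
    return SimState(
        grid=grid, phi=phi, cells=cells, sigma=sigma, rng_seed=rng_seed
    )


def apply_type_transition(
    state: SimState,
    contacts,
    from_type: str,
    touching_type: str,
    to_type: str,
) -> SimState:
    """Contact-dependent differentiation: relabel touching cells in place.

    Every cell of ``from_type`` with at least one contact-graph edge to a
    ``touching_type`` cell becomes ``to_type``.  Mechanics (σ matrix,
    fields) are untouched: the new type keeps the old adhesion program, as
    in the engineered system this models.  Idempotent.
    """
    types = {c.type_label for c in state.cells}
    for t in (from_type, touching_type):
        if t not in types:
            raise ConfigurationError(f"unknown cell type {t!r}")
    by_id = {c.id: c for c in state.cells}
    for cell in state.cells:
        if cell.type_label != from_type:
            continue
        for nb in contacts.graph.neighbors(cell.id) if contacts.graph.has_node(
            cell.id
        ) else ():
            if by_id[nb].type_label == touching_type:
                cell.type_label = to_type
                break
    return state


def ablate_half(state: SimState, contacts, plane_z: float = None) -> SimState:
    """Remove cells below the mid-plane, then disconnected satellites.

    Cells whose mass-center z lies below ``plane_z`` (default: the domain
    mid-plane, i.e. z = 0 with the origin at the box center) are removed;
    afterwards any cell with no contact path to the largest connected
    component of the survivors' contact graph is removed too.  Mirrors the
    experimental cleavage of an aggregate before self-repair.
    """
    import networkx as nx

    if plane_z is None:
        plane_z = 0.5 * state.grid.box[2]
    keep = []
    for i, p in enumerate(state.phi):
        zc = center_of_mass(state.grid, p)[2]
        if zc >= plane_z:
            keep.append(i)
    kept_ids = {state.cells[i].id for i in keep}
    sub = contacts.graph.subgraph(kept_ids)
    if len(sub) > 0:
        largest = max(nx.connected_components(sub), key=len)
        keep = [i for i in keep if state.cells[i].id in largest]
    if not keep:
        warnings.warn("ablation removed every cell", stacklevel=2)
    state.phi = [state.phi[i] for i in keep]
    state.cells = [state.cells[i] for i in keep]
    state.sigma = state.sigma[np.ix_(keep, keep)]
    state.history = None
    state.validate()
    return state


def dissociate(state: SimState, sigma_value: float = 0.0) -> SimState:
    """Set every off-diagonal attraction to ``sigma_value`` (in place).

    With σ = 0 the aggregate becomes purely repulsive and disperses under
    noise — the in-silico analogue of eliminating the adhesion protein.
    """
    if sigma_value < 0:
        raise ConfigurationError("sigma_value must be >= 0")
    n = state.n_cells
    sigma = np.full((n, n), float(sigma_value))
    np.fill_diagonal(sigma, 0.0)
    state.sigma = sigma
    return state
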