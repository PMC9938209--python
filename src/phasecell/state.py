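"""Cells, adhesion rules and the full simulation state."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .grid import Grid

__all__ = ["Cell", "AdhesionRules", "SimState", "make_rng"]


@dataclass
class Cell:
    """Bookkeeping record of one live cell.

    ``name`` is the lineage name (AB, P1, ABpl, ...) for embryo runs or an
    arbitrary label; ``type_label`` is a free tag used by the synthetic
    multicellular scenarios (cell types with distinct adhesion programs).
    ``target_volume`` is the prescribed volume V_i (µm³) the volume
    constriction drives the cell toward; it is piecewise constant in time,
    updated at division.
    """

    id: int
    name: str
    type_label: str = ""
    parent: Optional[str] = None
    sister: Optional[int] = None
    generation: int = 0
    target_volume: float = 0.0

    def __post_init__(self):
        if self.target_volume < 0:
            raise ConfigurationError(
                f"cell {self.name!r}: target_volume must be >= 0"
            )


@dataclass(frozen=True)
class AdhesionRules:
    """Binarized adhesion program σ ∈ {σ_S, σ_W}.

    All ordered cell pairs get the strong attraction ``sigma_strong`` except
    the explicitly listed weak pairs and, when ``sisters_weak`` is set, all
    sister pairs, which get ``sigma_weak``.  This mirrors the experimental
    observation that adhesive protein is scarce on newly formed sister-sister
    membranes and on a few specific contacts (e.g. EMS–P2, ABpl–E).
    """

    sigma_strong: float = 0.5
    sigma_weak: float = 0.0
    weak_pairs: frozenset = frozenset()
    sisters_weak: bool = False

    def __post_init__(self):
        if not (self.sigma_strong >= self.sigma_weak >= 0):
            raise ConfigurationError("adhesion rules require σ_S >= σ_W >= 0")
        pairs = frozenset(frozenset(p) for p in self.weak_pairs)
        object.__setattr__(self, "weak_pairs", pairs)


@dataclass
class SimState:
    """Complete state of a multicellular simulation.

    ``phi`` holds one phase field per live cell (same order as ``cells``);
    ``sigma`` is the (N, N) attraction matrix with zero diagonal (asymmetric
    entries are allowed); ``eggshell`` is the environment field φ_e (1
    outside the shell, 0 inside) or ``None`` for an open boundary.
    ``history`` carries (φ^{n-1}, F^{n-1}) for the second-order scheme and
    is ``None`` until that scheme has bootstrapped.
    """

    grid: Grid
    phi: list  # list of np.ndarray
    cells: list  # list of Cell
    sigma: np.ndarray
    eggshell: Optional[np.ndarray] = None
    time: float = 0.0
    step: int = 0
    history: Optional[dict] = None
    rng_seed: int = 0
    adhesion_rules: Optional[AdhesionRules] = None

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.validate()

    def validate(self):
        n = len(self.cells)
        if len(self.phi) != n:
            raise ConfigurationError(
                f"{len(self.phi)} fields for {n} cells"
            )
        if self.sigma.shape != (n, n):
            raise ConfigurationError(
                f"sigma shape {self.sigma.shape} does not match {n} cells"
            )
        if n and np.any(np.diag(self.sigma) != 0):
            raise ConfigurationError("sigma must have a zero diagonal")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_by_name(self, name: str) -> Cell:
        for c in self.cells:
            if c.name == name:
                return c
        raise KeyError(name)

    def index_of(self, name: str) -> int:
        for i, c in enumerate(self.cells):
            if c.name == name:
                return i
        raise KeyError(name)

    def copy(self, deep_fields: bool = True) -> "SimState":
        """Snapshot copy; fields are copied unless ``deep_fields=False``."""
        return SimState(
            grid=self.grid,
            phi=[p.copy() for p in self.phi] if deep_fields else list(self.phi),
            cells=[replace(c) for c in self.cells],
            sigma=self.sigma.copy(),
            eggshell=None if self.eggshell is None else self.eggshell,
            time=self.time,
            step=self.step,
            history=None
            if self.history is None
            else {
                "phi": [p.copy() for p in self.history["phi"]],
                "F": [f.copy() for f in self.history["F"]],
            },
            rng_seed=self.rng_seed,
            adhesion_rules=self.adhesion_rules,
        )


def make_rng(root_seed: int, purpose: str) -> np.random.Generator:
    """Deterministic per-purpose child RNG from one root seed.

    Separate purposes ("packing", "noise", ...) get independent streams, so
    e.g. toggling noise does not perturb the packed initial condition.
    """
    ss = np.random.SeedSequence(
        root_seed, spawn_key=tuple(ord(ch) for ch in purpose)
    )
    return np.random.default_rng(ss)
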