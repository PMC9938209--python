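"""Cell centers, RMS center velocity, and steady-state detectors.

Division scheduling is driven by the root-mean-square velocity of all
cells' mass centers, v̄.  Early stages divide when the system is steady
(v̄ < 1e-4), intermediate stages at the first quasi-steady state (the first
local minimum of v̄(t)), and later stages on a fixed duration or an
equilibrium-or-cap rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalError, ConfigurationError
from .grid import Grid

__all__ = [
    "center_of_mass",
    "VelocitySeries",
    "rms_center_velocity",
    "detect_steady",
    "detect_quasi_steady",
    "STEADY_THRESHOLD",
]

#: Default v̄ threshold defining a steady state / mechanical equilibrium.
STEADY_THRESHOLD = 1e-4


def center_of_mass(grid: Grid, phi: np.ndarray) -> np.ndarray:
    """Field-weighted mean position r_c = ∫ r φ dr / ∫ φ dr (µm).

    Raises :class:`NumericalError` when the field has no mass (∫φ = 0),
    which is the signature of a disappeared cell.
    """
    total = float(np.sum(phi))
    if total <= 0:
        raise NumericalError("center of mass undefined: field has no mass")
    x, y, z = grid.coords()
    return np.array(
        [
            float(np.sum(phi * x)) / total,
            float(np.sum(phi * y)) / total,
            float(np.sum(phi * z)) / total,
        ]
    )


def centers_of_state(state) -> np.ndarray:
    """(N, 3) array of all live-cell mass centers."""
    return np.array([center_of_mass(state.grid, p) for p in state.phi]).reshape(
        -1, 3
    )


@dataclass
class VelocitySeries:
    """Sampled v̄(t) curve with strictly increasing times."""

    t: list = field(default_factory=list)
    vbar: list = field(default_factory=list)

    def append(self, t: float, v: float):
        if self.t and t <= self.t[-1]:
            raise ConfigurationError("velocity series times must increase")
        if v < 0:
            raise ConfigurationError("vbar must be >= 0")
        self.t.append(float(t))
        self.vbar.append(float(v))

    def __len__(self):
        return len(self.t)


def rms_center_velocity(prev, curr) -> float:
    """v̄ between two states: RMS center displacement over elapsed time.

    Both states must hold the same live-cell set.  For states one step
    apart this is the per-step RMS velocity sqrt(mean_i |Δr_i|²)/δt.
    """
    prev_names = [c.name for c in prev.cells]
    curr_names = [c.name for c in curr.cells]
    if prev_names != curr_names:
        raise ConfigurationError(
            "rms_center_velocity requires identical live-cell sets"
        )
    dt = curr.time - prev.time
    if dt <= 0:
        raise ConfigurationError("states must be time-ordered")
    d = centers_of_state(curr) - centers_of_state(prev)
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))) / dt)


def rms_displacement_velocity(
    prev_centers: np.ndarray, curr_centers: np.ndarray, dt: float
) -> float:
    """v̄ from precomputed center arrays (used inside the evolution loop)."""
    if prev_centers.shape != curr_centers.shape:
        raise ConfigurationError("center arrays must have identical shapes")
    d = curr_centers - prev_centers
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))) / dt)


def detect_steady(series: VelocitySeries, threshold: float = STEADY_THRESHOLD):
    """Earliest time with v̄ < threshold, or None.

    The first sample strictly below the threshold wins; no smoothing.
    """
    if threshold <= 0:
        raise ConfigurationError("steady threshold must be > 0")
    for t, v in zip(series.t, series.vbar):
        if v < threshold:
            return t
    return None


def smooth_series(values, window: int) -> np.ndarray:
    """Centered moving average with edge truncation."""
    v = np.asarray(values, dtype=float)
    if window <= 1:
        return v
    half = window // 2
    out = np.empty_like(v)
    for i in range(len(v)):
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        out[i] = v[lo:hi].mean()
    return out


def detect_quasi_steady(series: VelocitySeries, window: int = 51):
    """First quasi-steady time t_q: first strict local minimum of v̄(t).

    The discrete analogue of dv̄/dt = 0 with d²v̄/dt² > 0.  The series is
    smoothed with a centered moving average of ``window`` samples before
    the local-minimum scan (the raw discrete derivative is too noisy to
    satisfy the two conditions literally).  Returns None when the series is
    shorter than the window or has no interior strict minimum.
    """
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    if len(series) < max(3, window):
        return None
    v = smooth_series(series.vbar, window)
    for i in range(1, len(v) - 1):
        if v[i] < v[i - 1] and v[i] < v[i + 1]:
            return series.t[i]
    return None
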