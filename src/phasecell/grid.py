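"""Periodic 3D grid and Fourier-spectral differential operators.

Every field in phasecell lives on a shared uniform periodic grid and is
represented as a plain ``numpy.ndarray`` of shape ``grid.shape``.  Spatial
derivatives are evaluated pseudo-spectrally: a field is transformed with a
real-to-complex FFT, each mode is multiplied by the appropriate power of the
angular wavenumber, and the result is transformed back.  This is exact for
band-limited fields and spectrally accurate for the smooth tanh profiles the
simulator works with.

Because the discretisation is spectral, the domain is periodic in all three
axes; scenario builders are responsible for keeping cells at least a couple
of interface widths away from the box faces (the eggshell or the cubic
boundary repulsion guarantees this in practice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property
from typing import NamedTuple

import numpy as np
import scipy.fft as _sp_fft

from .errors import ConfigurationError, NumericalError

__all__ = [
    "Grid",
    "FieldGeometry",
    "make_grid",
    "laplacian",
    "gradient",
    "integrate",
    "tanh_ball",
]

#: Tolerance band around [0, 1] within which a well-formed phase field lives.
PHASE_BAND = 0.1

#: |∇φ| floor (in units of 1/δl) below which the inward normal is set to 0.
NORMAL_FLOOR = 1e-8


@dataclass(frozen=True)
class Grid:
    """Uniform periodic grid with precomputed wavenumber tables.

    Parameters
    ----------
    shape : tuple of int
        Number of nodes along x, y, z.  Each entry must be >= 8.
    spacing : float
        Isotropic node spacing δl in µm; the periodic box has side
        ``n * spacing`` along each axis.
    """

    shape: tuple[int, int, int]
    spacing: float

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n < 8 for n in shape):
            raise ConfigurationError(
                f"grid shape must be a triple with entries >= 8, got {self.shape!r}"
            )
        if not np.isfinite(self.spacing) or self.spacing <= 0:
            raise ConfigurationError(f"grid spacing must be > 0, got {self.spacing!r}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", float(self.spacing))

    @property
    def box(self) -> tuple[float, float, float]:
        """Physical box side lengths (µm)."""
        return tuple(n * self.spacing for n in self.shape)

    @property
    def cell_volume(self) -> float:
        """Volume element δl³ (µm³)."""
        return self.spacing**3

    @cached_property
    def wavenumbers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Angular wavenumber table per axis (z axis in rfft layout).

        The zero mode is exactly 0 by construction of ``fftfreq``.
        """
        nx, ny, nz = self.shape
        kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=self.spacing)
        ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=self.spacing)
        kz = 2.0 * np.pi * np.fft.rfftfreq(nz, d=self.spacing)
        return kx, ky, kz

    @cached_property
    def k_squared(self) -> np.ndarray:
        """|k|² on the rfftn output layout."""
        kx, ky, kz = self.wavenumbers
        return (
            kx[:, None, None] ** 2 + ky[None, :, None] ** 2 + kz[None, None, :] ** 2
        )

    @cached_property
    def _k_broadcast(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """First-derivative wavenumber tables.

        The Nyquist mode of an even-length axis is zeroed: its sine
        component is not representable, and keeping ±k_nyq in an odd-order
        derivative breaks the mirror equivariance of the operator.
        """
        kx, ky, kz = (k.copy() for k in self.wavenumbers)
        for k, n in zip((kx, ky, kz), self.shape):
            if n % 2 == 0:
                k[n // 2] = 0.0  # full and rfft layouts both index Nyquist here
        return kx[:, None, None], ky[None, :, None], kz[None, None, :]

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Node coordinates (µm) as broadcastable open-grid arrays."""
        ax = [np.arange(n) * self.spacing for n in self.shape]
        return np.ix_(*ax)

    def fft(self, f: np.ndarray) -> np.ndarray:
        return _sp_fft.rfftn(f)

    def ifft(self, fhat: np.ndarray) -> np.ndarray:
        return _sp_fft.irfftn(fhat, s=self.shape)

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)


class FieldGeometry(NamedTuple):
    """Gradient data of a scalar field.

    ``grad`` stacks the three spectral partial derivatives along axis 0;
    ``grad_magnitude`` is the pointwise Euclidean norm; ``inward_normal`` is
    ∇φ/|∇φ| where the magnitude exceeds a floor and the zero vector
    elsewhere (for a phase field that is ≈1 inside, ∇φ points inward on the
    interface, hence the name).
    """

    grad: np.ndarray
    grad_magnitude: np.ndarray
    inward_normal: np.ndarray


def make_grid(shape, spacing) -> Grid:
    """Build an immutable periodic grid (see :class:`Grid`)."""
    return Grid(tuple(shape), float(spacing))


def _check_finite(f: np.ndarray, what: str = "field"):
    if not np.all(np.isfinite(f)):
        raise NumericalError(f"non-finite values in {what}")


def laplacian(grid: Grid, f: np.ndarray) -> np.ndarray:
    """Spectral Laplacian Δf: each Fourier mode is multiplied by −|k|²."""
    _check_finite(f, "laplacian input")
    return grid.ifft(-grid.k_squared * grid.fft(f))


def gradient(grid: Grid, f: np.ndarray) -> FieldGeometry:
    """Spectral gradient of ``f`` together with its magnitude and unit normal."""
    _check_finite(f, "gradient input")
    fhat = grid.fft(f)
    kx, ky, kz = grid._k_broadcast
    grad = np.stack(
        [
            grid.ifft(1j * kx * fhat),
            grid.ifft(1j * ky * fhat),
            grid.ifft(1j * kz * fhat),
        ]
    )
    gmag = np.sqrt(np.sum(grad**2, axis=0))
    floor = NORMAL_FLOOR / grid.spacing
    with np.errstate(invalid="ignore", divide="ignore"):
        normal = np.where(gmag > floor, grad / gmag, 0.0)
    return FieldGeometry(grad=grad, grad_magnitude=gmag, inward_normal=normal)


def integrate(grid: Grid, f: np.ndarray) -> float:
    """Volume integral Σ f · δl³ over the periodic box (µm³)."""
    return float(np.sum(f)) * grid.cell_volume


def tanh_ball(grid: Grid, center, radius: float, width: float) -> np.ndarray:
    """Spherical phase field with a tanh interface profile.

    φ(r) = (1 − tanh((|r − center| − R)/width)) / 2, evaluated with the
    minimum-image distance so the field is smooth across the periodic box.
    φ ≈ 1 deep inside, 0.5 on the radius-R shell, ≈ 0 outside.

    Emits a warning when the ball comes within two interface widths of a
    box face (periodic wrap-around would then distort the shape).
    """
    if radius <= 0 or width <= 0:
        raise ConfigurationError("tanh_ball requires radius > 0 and width > 0")
    center = np.asarray(center, dtype=float)
    box = np.asarray(grid.box)
    margin = np.minimum(center % box, box - (center % box)) - radius
    if np.any(margin < 2.0 * width - 1e-3):
        warnings.warn(
            "tanh_ball touches the periodic box boundary "
            f"(center {center.tolist()}, R={radius}); expect wrap-around",
            stacklevel=2,
        )
    x, y, z = grid.coords()
    d2 = grid.zeros()
    for axis_coord, c, L in zip((x, y, z), center, box):
        delta = (axis_coord - c + 0.5 * L) % L - 0.5 * L
        d2 = d2 + delta**2
    r = np.sqrt(d2)
    return 0.5 * (1.0 - np.tanh((r - radius) / width))
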