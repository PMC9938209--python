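import numpy as np
import pytest

import phasecell as pc


@pytest.fixture(scope="session")
def grid32():
    return pc.make_grid((32, 32, 32), 0.5)


@pytest.fixture(scope="session")
def grid_small():
    return pc.make_grid((24, 24, 24), 0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def smooth_random_field(grid, rng, kmax=3):
    """Band-limited random field: a few low-k Fourier modes."""
    x, y, z = grid.coords()
    Lx, Ly, Lz = grid.box
    f = np.zeros(grid.shape)
    for _ in range(6):
        kx, ky, kz = rng.integers(-kmax, kmax + 1, size=3)
        amp = rng.normal()
        phase = rng.uniform(0, 2 * np.pi)
        f = f + amp * np.cos(
            2 * np.pi * (kx * x / Lx + ky * y / Ly + kz * z / Lz) + phase
        )
    return f


def single_cell_state(grid, radius, width=1.0, center=None, target=None):
    center = (
        np.array(grid.box) / 2 if center is None else np.asarray(center, float)
    )
    V = 4.0 / 3.0 * np.pi * radius**3 if target is None else target
    phi = pc.tanh_ball(grid, center, radius, width)
    cell = pc.Cell(id=0, name="cell", target_volume=V)
    return pc.SimState(
        grid=grid, phi=[phi], cells=[cell], sigma=np.zeros((1, 1))
    )


def two_cell_state(grid, radius, centers, sigma=0.5, width=1.0):
    V = 4.0 / 3.0 * np.pi * radius**3
    phi = [pc.tanh_ball(grid, c, radius, width) for c in centers]
    cells = [
        pc.Cell(id=i, name=f"c{i}", target_volume=V) for i in range(len(centers))
    ]
    n = len(centers)
    sig = np.full((n, n), sigma, dtype=float)
    np.fill_diagonal(sig, 0.0)
    return pc.SimState(grid=grid, phi=phi, cells=cells, sigma=sig)
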