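"""Scenario presets: load, scale down, and build initial states.

Presets describe the engineered-aggregate scenarios (separation, layering,
self-repair, dissociation) at full scale: a 64-µm cubic domain on a
128³ grid, δl = 0.5 µm, δt = 1.25, R = 5 µm spheres, noise κ = √5/10.
``scale_down`` shrinks a preset (cell count, box, grid) for desk-scale
property checks while keeping the adhesion program intact.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .environment import (
    SYNNOTCH_KAPPA,
    fields_from_centers,
    pack_initial_positions,
)
from .errors import ConfigurationError
from .grid import make_grid
from .params import ModelParams
from .state import make_rng

__all__ = ["available_presets", "load_preset", "scale_down", "setup_scenario"]


def available_presets() -> list:
    pkg = resources.files("phasecell") / "presets"
    return sorted(p.name[: -len(".yaml")] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> dict:
    """Load a bundled scenario preset by name."""
    pkg = resources.files("phasecell") / "presets" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    return yaml.safe_load(text)


def scale_down(preset: dict, total_cells: int, grid_shape=(48, 48, 48)) -> dict:
    """Shrink a preset to ``total_cells`` in a proportionally smaller box.

    Cell counts are rescaled preserving the type proportions (at least one
    cell per type); the box side is chosen to keep the original packing
    fraction, rounded to the given grid.  Adhesion, noise and time step are
    untouched.
    """
    p = dict(preset)
    counts = preset["counts"]
    n_orig = sum(counts.values())
    scaled = {
        t: max(1, int(round(c * total_cells / n_orig)))
        for t, c in counts.items()
    }
    p["counts"] = scaled
    p["grid_shape"] = list(grid_shape)
    return p


def _sigma_by_type(preset: dict) -> dict:
    out = {}
    for key, v in preset.get("sigma", {}).items():
        a, b = (s.strip() for s in str(key).split(","))
        out[(a, b)] = float(v)
    # a differentiated type keeps the program of its origin type
    tr = preset.get("transition")
    if tr:
        src, new = str(tr["from_type"]), str(tr["to_type"])
        extra = {}
        for (a, b), v in out.items():
            if a == src:
                extra[(new, b)] = v
            if b == src:
                extra[(a, new)] = v
        extra[(new, new)] = out.get((src, src), 0.0)
        out.update(extra)
    return out


def setup_scenario(preset, seed: int = 0, interface_width: float = 1.0):
    """Pack centers and build (SimState, ModelParams) for a preset.

    ``preset`` is a name or a preset dict.  The packing RNG is a child
    stream of ``seed`` so toggling noise later does not change the packed
    configuration.  Returns ``(state, params, preset_dict)``.
    """
    if isinstance(preset, str):
        preset = load_preset(preset)
    grid = make_grid(tuple(preset["grid_shape"]), float(preset["grid_spacing"]))
    box = grid.box
    if abs(box[0] - box[1]) > 1e-9 or abs(box[0] - box[2]) > 1e-9:
        raise ConfigurationError("scenario domain must be cubic")
    # Pack inside an inner cube two interface widths off the periodic faces:
    # the boundary repulsion keeps *centers* R from the walls, so without the
    # pad a cell surface would touch the face and wrap around spectrally.
    pad = 2.0 * interface_width
    inner = box[0] - 2.0 * pad
    if inner <= 4.0 * float(preset["radius"]):
        raise ConfigurationError("domain too small for the packing pad")
    packing = pack_initial_positions(
        preset["counts"],
        radius=float(preset["radius"]),
        box_side=inner,
        k1=float(preset.get("k1", 0.05)),
        k2=float(preset.get("k2", 0.1)),
        rng=make_rng(seed, "packing"),
    )
    packing.centers = packing.centers + pad
    packing.box_side = box[0]  # clearances now hold w.r.t. the full box
    state = fields_from_centers(
        packing,
        grid,
        width=interface_width,
        sigma_by_type=_sigma_by_type(preset),
        rng_seed=seed,
    )
    kappa = SYNNOTCH_KAPPA if preset.get("kappa_sqrt5_over_10", True) else float(
        preset.get("kappa", 0.0)
    )
    params = ModelParams(
        volume_mode="relative",
        c=2.0,
        dt=float(preset.get("dt", 1.25)),
        kappa=kappa,
        noise_on=kappa > 0,
    )
    return state, params, preset
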