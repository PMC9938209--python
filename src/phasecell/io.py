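"""File formats: schedule CSV, HDF5 snapshots, TIFF/VTK export, run configs.

Schedules are CSV with columns
``parent, child1, child2, group, axis_x, axis_y, axis_z, ratio``; snapshots
are HDF5 with layout ``/meta`` (time, step, seed, format version),
``/cells/<id>/{field,...}`` and ``/sigma``; visual export rasterizes the
state into a per-cell label volume (argmax over fields where max φ ≥ 0.5).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field as dc_field
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from .division import DivisionEvent, Schedule
from .errors import ConfigurationError, ScheduleParseError
from .grid import Grid, make_grid
from .params import ModelParams
from .state import AdhesionRules, Cell, SimState

__all__ = [
    "read_schedule_csv",
    "write_schedule_csv",
    "write_snapshot",
    "read_snapshot",
    "export_visual",
    "RunConfig",
]

SNAPSHOT_FORMAT_VERSION = 1

SCHEDULE_COLUMNS = [
    "parent",
    "child1",
    "child2",
    "group",
    "axis_x",
    "axis_y",
    "axis_z",
    "ratio",
]


def read_schedule_csv(path) -> Schedule:
    """Parse and validate a division schedule from CSV.

    Axes are renormalized when |n| deviates from 1 by less than 1e-3 and
    rejected otherwise; parse errors carry the offending line number.
    """
    df = pd.read_csv(path)
    missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise ScheduleParseError(
            f"{path}: missing columns {missing}", line=1
        )
    events = []
    for row in df.itertuples():
        line = row.Index + 2  # header is line 1
        axis = np.array(
            [float(row.axis_x), float(row.axis_y), float(row.axis_z)]
        )
        norm = float(np.linalg.norm(axis))
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-3:
            raise ScheduleParseError(
                f"{path}:{line}: axis norm {norm:.6f} deviates from 1 by "
                "more than 1e-3",
                line=line,
            )
        ratio = float(row.ratio)
        if not (0.0 < ratio < 1.0):
            raise ScheduleParseError(
                f"{path}:{line}: ratio {ratio} outside (0, 1)", line=line
            )
        try:
            events.append(
                DivisionEvent(
                    parent=str(row.parent),
                    axis=tuple(axis / norm),
                    ratio=ratio,
                    group=int(row.group),
                    child_names=(str(row.child1), str(row.child2)),
                )
            )
        except ConfigurationError as exc:
            raise ScheduleParseError(f"{path}:{line}: {exc}", line=line)
    try:
        return Schedule(events=events)
    except ConfigurationError as exc:
        raise ScheduleParseError(f"{path}: {exc}")


def write_schedule_csv(schedule: Schedule, path):
    rows = [
        {
            "parent": e.parent,
            "child1": e.child_names[0],
            "child2": e.child_names[1],
            "group": e.group,
            "axis_x": e.axis[0],
            "axis_y": e.axis[1],
            "axis_z": e.axis[2],
            "ratio": e.ratio,
        }
        for e in schedule.events
    ]
    pd.DataFrame(rows, columns=SCHEDULE_COLUMNS).to_csv(path, index=False)


def write_snapshot(state: SimState, path):
    """Write the full state to HDF5; round-trips bit-exactly."""
    with h5py.File(path, "w") as fh:
        meta = fh.create_group("meta")
        meta.attrs["format_version"] = SNAPSHOT_FORMAT_VERSION
        meta.attrs["time"] = state.time
        meta.attrs["step"] = state.step
        meta.attrs["rng_seed"] = state.rng_seed
        meta.attrs["grid_shape"] = state.grid.shape
        meta.attrs["grid_spacing"] = state.grid.spacing
        if state.adhesion_rules is not None:
            r = state.adhesion_rules
            meta.attrs["adhesion_rules"] = json.dumps(
                {
                    "sigma_strong": r.sigma_strong,
                    "sigma_weak": r.sigma_weak,
                    "weak_pairs": [sorted(p) for p in r.weak_pairs],
                    "sisters_weak": r.sisters_weak,
                }
            )
        fh.create_dataset("sigma", data=state.sigma)
        if state.eggshell is not None:
            fh.create_dataset("eggshell", data=state.eggshell)
        cells = fh.create_group("cells")
        for cell, phi in zip(state.cells, state.phi):
            g = cells.create_group(str(cell.id))
            g.create_dataset("field", data=phi)
            g.attrs["name"] = cell.name
            g.attrs["type_label"] = cell.type_label
            g.attrs["parent"] = cell.parent if cell.parent is not None else ""
            g.attrs["sister"] = cell.sister if cell.sister is not None else -1
            g.attrs["generation"] = cell.generation
            g.attrs["target_volume"] = cell.target_volume
        if state.history is not None and state.history.get("phi") is not None:
            h = fh.create_group("history")
            for k in ("phi", "F"):
                grp = h.create_group(k)
                for cell, arr in zip(state.cells, state.history[k]):
                    grp.create_dataset(str(cell.id), data=arr)


def read_snapshot(path) -> SimState:
    """Read a state written by :func:`write_snapshot`."""
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise ConfigurationError(f"cannot open snapshot {path}: {exc}")
    with fh:
        if "meta" not in fh:
            raise ConfigurationError(f"{path}: not a phasecell snapshot")
        meta = fh["meta"]
        version = int(meta.attrs.get("format_version", -1))
        if version != SNAPSHOT_FORMAT_VERSION:
            raise ConfigurationError(
                f"{path}: snapshot format version {version} != "
                f"{SNAPSHOT_FORMAT_VERSION}"
            )
        grid = make_grid(
            tuple(int(n) for n in meta.attrs["grid_shape"]),
            float(meta.attrs["grid_spacing"]),
        )
        cells, phi = [], []
        ids = sorted(fh["cells"].keys(), key=int)
        for cid in ids:
            g = fh["cells"][cid]
            parent_attr = str(g.attrs["parent"])
            sister = int(g.attrs["sister"])
            cells.append(
                Cell(
                    id=int(cid),
                    name=str(g.attrs["name"]),
                    type_label=str(g.attrs["type_label"]),
                    parent=parent_attr or None,
                    sister=None if sister < 0 else sister,
                    generation=int(g.attrs["generation"]),
                    target_volume=float(g.attrs["target_volume"]),
                )
            )
            phi.append(g["field"][()])
        rules = None
        if "adhesion_rules" in meta.attrs:
            d = json.loads(meta.attrs["adhesion_rules"])
            rules = AdhesionRules(
                sigma_strong=d["sigma_strong"],
                sigma_weak=d["sigma_weak"],
                weak_pairs=frozenset(
                    frozenset(p) for p in d["weak_pairs"]
                ),
                sisters_weak=d["sisters_weak"],
            )
        history = None
        if "history" in fh:
            history = {
                k: [fh["history"][k][cid][()] for cid in ids]
                for k in ("phi", "F")
            }
        return SimState(
            grid=grid,
            phi=phi,
            cells=cells,
            sigma=fh["sigma"][()],
            eggshell=fh["eggshell"][()] if "eggshell" in fh else None,
            time=float(meta.attrs["time"]),
            step=int(meta.attrs["step"]),
            history=history,
            rng_seed=int(meta.attrs["rng_seed"]),
            adhesion_rules=rules,
        )


def label_volume(state: SimState) -> np.ndarray:
    """Per-cell label volume: argmax cell id + 1 where max φ ≥ 0.5, else 0."""
    labels = np.zeros(state.grid.shape, dtype=np.uint16)
    if state.n_cells == 0:
        return labels
    stack = np.stack(state.phi)
    winner = np.argmax(stack, axis=0)
    occupied = np.max(stack, axis=0) >= 0.5
    ids = np.array([c.id for c in state.cells], dtype=np.uint16)
    labels[occupied] = ids[winner[occupied]] + 1
    return labels


def export_visual(state: SimState, path, fmt: str = "tiff"):
    """Export the state for visualization.

    ``tiff``: the label volume as a z-stack TIFF (background = 0, cell i
    labelled id+1).  ``vtk``: legacy ASCII STRUCTURED_POINTS with the label
    volume plus one scalar array per cell field.
    """
    if fmt == "tiff":
        import tifffile

        labels = label_volume(state)
        tifffile.imwrite(path, np.moveaxis(labels, 2, 0))  # z-major stack
        return path
    if fmt == "vtk":
        labels = label_volume(state)
        nx_, ny_, nz_ = state.grid.shape
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write("phasecell state\nASCII\nDATASET STRUCTURED_POINTS\n")
            fh.write(f"DIMENSIONS {nx_} {ny_} {nz_}\n")
            fh.write("ORIGIN 0 0 0\n")
            s = state.grid.spacing
            fh.write(f"SPACING {s} {s} {s}\n")
            fh.write(f"POINT_DATA {labels.size}\n")
            fh.write("SCALARS label unsigned_short 1\nLOOKUP_TABLE default\n")
            labels.transpose(2, 1, 0).ravel().tofile(fh, sep="\n")
            fh.write("\n")
            for cell, phi in zip(state.cells, state.phi):
                fh.write(f"SCALARS phi_{cell.name} float 1\n")
                fh.write("LOOKUP_TABLE default\n")
                phi.transpose(2, 1, 0).astype(np.float32).ravel().tofile(
                    fh, sep="\n"
                )
                fh.write("\n")
        return path
    raise ConfigurationError(f"unknown export format {fmt!r}")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated run configuration (YAML-backed).

    Every run writes its resolved configuration next to its outputs so a
    result is reproducible from the emitted config plus the seed.
    """

    grid_shape: tuple = (64, 64, 64)
    grid_spacing: float = 0.5
    params: ModelParams = dc_field(default_factory=ModelParams)
    scheme: str = "semi_implicit_2"
    seed: int = 0
    snapshot_interval: int = 0  # steps; 0 = final state only
    duration: float = 100.0
    schedule: Optional[str] = None  # path or preset name
    preset: Optional[str] = None
    output_dir: str = "."

    def __post_init__(self):
        make_grid(self.grid_shape, self.grid_spacing)  # validates
        if self.scheme not in ("explicit", "semi_implicit_1", "semi_implicit_2"):
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        if self.snapshot_interval < 0:
            raise ConfigurationError("snapshot_interval must be >= 0")
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        if not os.path.exists(path):
            raise ConfigurationError(f"config file {path} does not exist")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        params = ModelParams(**raw.pop("params", {}))
        known = {
            "grid_shape",
            "grid_spacing",
            "scheme",
            "seed",
            "snapshot_interval",
            "duration",
            "schedule",
            "preset",
            "output_dir",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(params=params, **raw)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    def write_resolved(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
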