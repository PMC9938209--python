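"""Derived quantities: contact graphs, sorting indices, run reports.

Two cells are in contact when their phase-field overlap integral
∫ φ_i φ_j dr exceeds a threshold θ_c (default 1 µm³).  The overlap is a
natural diffuse-interface contact-area proxy: it is ~0 for separated cells
and grows with the shared interface.  θ_c is a package convention (exposed
everywhere it is used) — the criterion itself, not its exact value, is what
the downstream rules (differentiation triggers, ablation connectivity,
sorting indices) depend on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .errors import ConfigurationError
from .state import SimState

__all__ = ["ContactGraph", "contact_map", "sorting_index", "run_report", "THETA_C"]

#: Default contact threshold θ_c on ∫ φ_i φ_j dr (µm³).
THETA_C = 1.0


@dataclass
class ContactGraph:
    """Undirected weighted cell–cell contact graph.

    Nodes are cell ids; each edge carries the overlap integral (µm³) as
    ``weight``.  Only pairs with weight > ``threshold`` become edges.
    """

    graph: nx.Graph
    threshold: float

    @property
    def edges(self):
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def weight(self, i: int, j: int) -> float:
        if self.graph.has_edge(i, j):
            return self.graph[i][j]["weight"]
        return 0.0

    def to_graphml(self, path):
        nx.write_graphml(self.graph, path)


def _support_box(phi: np.ndarray, tol: float = 1e-6):
    """Axis-aligned index bounding box of {φ > tol}, or None if empty."""
    mask = phi > tol
    if not mask.any():
        return None
    idx = np.nonzero(mask)
    return tuple((int(ax.min()), int(ax.max()) + 1) for ax in idx)


def contact_map(state: SimState, theta_c: float = THETA_C) -> ContactGraph:
    """Contact graph of the current state.

    Overlap integrals are evaluated in real space, restricted to the
    intersection of the two cells' support bounding boxes so that distant
    pairs cost nothing.
    """
    if theta_c <= 0:
        raise ConfigurationError("theta_c must be > 0")
    g = nx.Graph()
    for c in state.cells:
        g.add_node(c.id, name=c.name, type_label=c.type_label)
    boxes = [_support_box(p) for p in state.phi]
    dv = state.grid.cell_volume
    n = state.n_cells
    for i in range(n):
        if boxes[i] is None:
            continue
        for j in range(i + 1, n):
            if boxes[j] is None:
                continue
            sl = []
            empty = False
            for (alo, ahi), (blo, bhi) in zip(boxes[i], boxes[j]):
                lo, hi = max(alo, blo), min(ahi, bhi)
                if lo >= hi:
                    empty = True
                    break
                sl.append(slice(lo, hi))
            if empty:
                continue
            sl = tuple(sl)
            w = float(np.sum(state.phi[i][sl] * state.phi[j][sl])) * dv
            if w > theta_c:
                g.add_edge(state.cells[i].id, state.cells[j].id, weight=w)
    return ContactGraph(graph=g, threshold=theta_c)


def sorting_index(state: SimState, contacts: ContactGraph) -> float:
    """Fraction of contact edges joining cells of the same type ∈ [0, 1].

    Quantifies differential-adhesion sorting: a well-sorted two-type
    aggregate has mostly homotypic contacts.  NaN when the graph has no
    edges.  Invariant under renaming of the type labels.
    """
    by_id = {c.id: c.type_label for c in state.cells}
    total = contacts.graph.number_of_edges()
    if total == 0:
        return float("nan")
    same = sum(
        1 for u, v in contacts.graph.edges() if by_id[u] == by_id[v]
    )
    return same / total


def run_report(run, theta_c: float = THETA_C) -> dict:
    """JSON-able summary of a :class:`~phasecell.division.ScheduleRun`.

    Collects per-stage durations and stop reasons, cell counts over time,
    division events, disappearance flags, and the terminal contact map
    (keyed by cell *names*, so the report is invariant under re-indexing).
    """
    if run is None or not getattr(run, "events", None):
        return {"stages": [], "divisions": [], "cell_counts": [], "terminal": {}}
    stages = [e for e in run.events if e["kind"] == "stage"]
    divisions = [e for e in run.events if e["kind"] == "division"]
    counts = []
    n = None
    for e in run.events:
        if e["kind"] == "stage":
            n = e["n_cells"]
        elif e["kind"] == "division":
            n = (n or 0) + 1
        counts.append({"time": e["time"], "n_cells": n})
    state = run.state
    contacts = contact_map(state, theta_c)
    by_id = {c.id: c.name for c in state.cells}
    terminal = {
        "n_cells": state.n_cells,
        "names": sorted(c.name for c in state.cells),
        "contacts": sorted(
            [sorted((by_id[u], by_id[v])) + [w] for u, v, w in contacts.edges]
        ),
        "disappeared": [
            c.name
            for c, p in zip(state.cells, state.phi)
            if float(np.max(p)) < 0.5
        ],
    }
    vbar = {
        str(k): {"t": list(v.t), "vbar": list(v.vbar)}
        for k, v in getattr(run, "velocity", {}).items()
    }
    return {
        "stages": stages,
        "divisions": divisions,
        "cell_counts": counts,
        "vbar": vbar,
        "terminal": terminal,
    }


def save_report(report: dict, path):
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
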