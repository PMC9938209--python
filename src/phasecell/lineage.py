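"""Bundled division schedules: a nematode-like 24-group lineage and random trees.

The built-in schedule reproduces the *topology and grouping* of early
C. elegans embryogenesis: the zygote P0 divides through the P lineage
(P0, P1, P2, P3) and EMS, producing the six founder cells AB, MS, E, C, D
and P4, whose descendants divide in pseudo-synchronous generations
(AB: 6 generations → 64 cells, MS: 4 → 16, E: 3 → 8, C: 3 → 8, D: 2 → 4,
P4: 1 → 2).  With the 5 single P-lineage/EMS divisions this yields 24
division groups and 102 terminal cells.

Division *axes and volume-segregation ratios* are documented stand-ins
(configurable), not measured values: axes cycle through the coordinate
directions by generation and ratios default to 0.5 except for the
well-known asymmetric early divisions.  Topology-sensitive conclusions
drawn from this fixture are therefore qualitative.
"""

from __future__ import annotations

import numpy as np

from .division import DivisionEvent, Schedule
from .errors import ConfigurationError

__all__ = ["builtin_celegans_schedule", "random_schedule", "FOUNDER_GENERATIONS"]

#: Founder cells and the number of synchronous division generations each
#: undergoes in the bundled schedule.
FOUNDER_GENERATIONS = {"AB": 6, "MS": 4, "E": 3, "C": 3, "D": 2, "P4": 1}

#: Stand-in volume fractions (first child) for the asymmetric divisions of
#: the early lineage; every other division is symmetric.
DEFAULT_RATIOS = {
    "P0": 0.60,  # AB | P1
    "P1": 0.55,  # EMS | P2
    "EMS": 0.55,  # MS | E
    "P2": 0.60,  # C | P3
    "P3": 0.60,  # D | P4
}

_AXES = [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)]
_SUFFIXES = [("a", "p"), ("l", "r"), ("d", "v")]

#: (parent, children, group) for the non-founder-generation divisions.
_EARLY = [
    ("P0", ("AB", "P1"), 1),
    ("P1", ("EMS", "P2"), 3),
    ("EMS", ("MS", "E"), 5),
    ("P2", ("C", "P3"), 6),
    ("P3", ("D", "P4"), 12),
]

#: Group index of each founder generation (generation 1, 2, ... in order).
_FOUNDER_GROUPS = {
    "AB": [2, 4, 7, 11, 15, 19],
    "MS": [8, 13, 17, 22],
    "E": [9, 14, 20],
    "C": [10, 16, 21],
    "D": [18, 23],
    "P4": [24],
}


def _axis_for(generation: int):
    return _AXES[generation % 3]


def builtin_celegans_schedule(ratios=None) -> Schedule:
    """The bundled 24-group, 101-event, 102-terminal-cell schedule.

    ``ratios`` may override the stand-in volume fractions per parent name.
    """
    ratios = {**DEFAULT_RATIOS, **(ratios or {})}
    events = []
    for parent, children, group in _EARLY:
        events.append(
            DivisionEvent(
                parent=parent,
                axis=_axis_for(len(events) % 3),
                ratio=ratios.get(parent, 0.5),
                group=group,
                child_names=children,
            )
        )
    for founder, groups in _FOUNDER_GROUPS.items():
        if founder == "P4":
            events.append(
                DivisionEvent(
                    parent="P4",
                    axis=_axis_for(0),
                    ratio=ratios.get("P4", 0.5),
                    group=groups[0],
                    child_names=("Z2", "Z3"),
                )
            )
            continue
        cohort = [founder]
        for gen, group in enumerate(groups):
            suffix_a, suffix_b = _SUFFIXES[gen % 3]
            next_cohort = []
            for name in cohort:
                children = (name + suffix_a, name + suffix_b)
                events.append(
                    DivisionEvent(
                        parent=name,
                        axis=_axis_for(gen),
                        ratio=ratios.get(name, 0.5),
                        group=group,
                        child_names=children,
                    )
                )
                next_cohort.extend(children)
            cohort = next_cohort
    events.sort(key=lambda e: e.group)
    return Schedule(events=events)


def random_schedule(n_groups: int, seed: int = 0, ratio_range=(0.3, 0.7)) -> Schedule:
    """Random binary-division schedule for testing: one division per group.

    Starting from a single root cell ``C``, each group divides one uniformly
    chosen live cell along a random unit axis with a ratio drawn from
    ``ratio_range``.  Child names encode the lineage path (suffix 0/1).
    """
    if n_groups < 1:
        raise ConfigurationError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    alive = ["C"]
    events = []
    for g in range(1, n_groups + 1):
        parent = alive[rng.integers(len(alive))]
        axis = rng.standard_normal(3)
        axis = axis / np.linalg.norm(axis)
        ratio = float(rng.uniform(*ratio_range))
        children = (parent + "0", parent + "1")
        events.append(
            DivisionEvent(
                parent=parent,
                axis=tuple(axis),
                ratio=ratio,
                group=g,
                child_names=children,
            )
        )
        alive.remove(parent)
        alive.extend(children)
    return Schedule(events=events)
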