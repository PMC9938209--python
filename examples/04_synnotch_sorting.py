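"""Cell sorting by differential adhesion (scaled-down aggregate scenario).

Two cell types with strong homotypic (σ = 0.9) and weak heterotypic
(σ = 0.5) adhesion are packed at random in a cubic domain and evolved with
motion noise.  Differential adhesion drives the types to demix; the
sorting index (fraction of homotypic contact edges) quantifies it.
This is the desk-scale version of the 125-cell separation scenario.
"""

import warnings

import phasecell as pc

warnings.filterwarnings("ignore", message="tanh_ball touches")

preset = pc.scale_down(
    pc.load_preset("sym_separation"), total_cells=16, grid_shape=(40, 40, 40)
)
preset["radius"] = 2.5
state, params, _ = pc.setup_scenario(preset, seed=0)

graph0 = pc.contact_map(state, theta_c=0.5)
si0 = pc.sorting_index(state, graph0)
print(f"packed {state.n_cells} cells "
      f"({sum(c.type_label == '1' for c in state.cells)} type 1, "
      f"{sum(c.type_label == '2' for c in state.cells)} type 2)")
print(f"initial sorting index: {si0:.3f}")

for stop_t in (250.0, 500.0):
    pc.evolve(
        state,
        params,
        scheme="semi_implicit_2",
        stop=pc.FixedDuration(250.0),
        check_every=25,
    )
    si = pc.sorting_index(state, pc.contact_map(state, theta_c=0.5))
    print(f"sorting index at t = {stop_t:4.0f}: {si:.3f}")

# A random packing has a sorting index near the unsorted expectation
# (~0.4-0.5 for these type proportions); differential adhesion raises it
# as homotypic neighbourhoods coarsen, exactly as the full-scale
# engineered aggregates separate into two regions.
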