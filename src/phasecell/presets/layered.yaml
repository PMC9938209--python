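# Layered (core-shell) structure: strongly adhesive type 1 forms the core,
# weakly adhesive type 2 the shell.  Also the starting point of the
# self-repairing scenario (ablate half, evolve again).
name: layered
grid_shape: [128, 128, 128]
grid_spacing: 0.5
radius: 5.0
k1: 0.05
k2: 0.1
counts: {"1": 24, "2": 32}
sigma:
  "1,1": 0.9
  "1,2": 0.5
  "2,2": 0.3
duration: 50000
dt: 1.25
kappa_sqrt5_over_10: true
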