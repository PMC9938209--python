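# Dissociation: uniform residual adhesion of 0.3 across all pairs
# (set to 0 via the dissociate() operation to disperse fully).
name: dissociation
grid_shape: [128, 128, 128]
grid_spacing: 0.5
radius: 5.0
k1: 0.05
k2: 0.1
counts: {"1": 50, "2": 75}
sigma:
  "1,1": 0.3
  "1,2": 0.3
  "2,2": 0.3
duration: 50000
dt: 1.25
kappa_sqrt5_over_10: true
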