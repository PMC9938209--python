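# Spherically asymmetric separation, two cell types, no differentiation.
name: asym_separation_2type
grid_shape: [128, 128, 128]
grid_spacing: 0.5
radius: 5.0
k1: 0.05
k2: 0.1
counts: {"1": 62, "2": 62}
sigma:
  "1,1": 0.9
  "1,2": 0.5
  "2,2": 0.9
duration: 50000
dt: 1.25
kappa_sqrt5_over_10: true
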