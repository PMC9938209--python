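# Spherically asymmetric separation with contact-dependent differentiation:
# type-1 cells touching a type-2 cell relabel to type 3 from t = 40000
# (mechanics unchanged; type 3 keeps the type-1 adhesion program).
name: asym_separation_3type
grid_shape: [128, 128, 128]
grid_spacing: 0.5
radius: 5.0
k1: 0.05
k2: 0.1
counts: {"1": 80, "2": 40}
sigma:
  "1,1": 0.9
  "1,2": 0.5
  "2,2": 0.9
transition: {from_type: "1", touching_type: "2", to_type: "3", at_time: 40000}
duration: 50000
dt: 1.25
kappa_sqrt5_over_10: true
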