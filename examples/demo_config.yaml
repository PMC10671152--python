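# Synthetic demo project: a 250 x 4.6 mm, 10 µm column, 1 mL dwell volume,
# the default 12-run calibration design and a coarse design-space grid.
column:
  length_mm: 250
  id_mm: 4.6
  particle_um: 10
  porosity: 0.68
instrument:
  dwell_ml: 1.0
design:
  tG_levels: [20, 60]
  T_levels: [5, 35]
  tC_levels: [0.0, 0.5, 1.0]
  phi0: 0.30
  phif: 1.00
  flow_ml_min: 0.5
grid:
  tG_points: 9
  T_points: 7
  tC_points: 5
rs_threshold: 1.5
n_analytes: 9
seed: 1
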