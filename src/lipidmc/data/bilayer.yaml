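# DPPC bilayer patch, 2D-periodic cubic cell, constant pressure (NPT).
# Build the start structure first:
#   lipidmc build --system dppc-bilayer --out start/ --seed 1
system:
  parameter_file: null
  plan_file: null
  n_molecules: 64             # 32 per leaflet, 8x4 rectangular lattice
run:
  temperature: 323.0          # K
  pressure: 1.0               # atm
  n_cycles: 500
  save_every: 50
  list_update_every: 10       # pair-list refresh period (cycles)
  seed: 1
  ensemble: NPT_bilayer
  cutoff: 10.0                # Å, plain truncation
  shell: 10.0                 # Å, pair-list shell (10..20 Å stored)
  dielectric: {plateau_d: 78.0, slope_s: 0.654}
  dielectric_mode: pair
  constant_epsilon: 1.0
  max_dlnv: 0.02              # volume move step in ln V, one move per cycle
  step_scale: 1.0
  include_jacobian: true
  check_every: 50
  cbla_tol: 1.0e-6
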