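# Single united-atom DPPC molecule, canonical (NVT) sampling, no box.
# Every default is stated explicitly.
system:
  parameter_file: null        # null = shipped dppc.ff
  plan_file: null             # null = shipped dppc.moves (88 DOF)
  n_molecules: 1
run:
  temperature: 323.0          # K
  pressure: 1.0               # atm (unused without a box)
  n_cycles: 2000
  save_every: 100
  list_update_every: 10
  seed: 1
  ensemble: NVT_monomer
  cutoff: null                # all intramolecular pairs
  shell: 10.0
  dielectric: {plateau_d: 78.0, slope_s: 0.654}
  dielectric_mode: pair
  constant_epsilon: 1.0
  max_dlnv: 0.02
  step_scale: 1.0
  include_jacobian: true
  check_every: 50
  cbla_tol: 1.0e-6
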