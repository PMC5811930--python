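# Two-active-state, two-G-protein system with a dual agonist
# (stronger for pathway 1). All unlisted parameters take package defaults;
# see gpcrbias.model_core.default_parameters for values and units.
model:
  n_active: 2
  n_gprot: 2
  ligand_mode: constant
parameters:
  zeta_plus: [1000.0, 200.0]
protocol:
  post_ligand_time: 3600.0
  n_points: 400
readout:
  C_s: 2.0
  C_i: 1.0
  normalisation: percent-of-reference
  reference_signal: 5.0e-7
seed: 0
output_dir: out
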