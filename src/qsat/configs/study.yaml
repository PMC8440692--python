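# Default simulation study: four virtual observers x four procedures,
# 2048 trials per run.  Reduce n_reps for quick exploration.
master_seed: 0
n_reps: 200
output_dir: qsat_out

task:
  chance: 0.5
  window: 0.2

observers:
  - {id: 1, lam: 0.470, gam: 7.5, delta: 0.28, rt: {mu: 0.3, sigma: 0.06, tau: 0.08}}
  - {id: 2, lam: 0.450, gam: 5.0, delta: 0.22, rt: {mu: 0.3, sigma: 0.06, tau: 0.08}}
  - {id: 3, lam: 0.495, gam: 22.0, delta: 0.24, rt: {mu: 0.3, sigma: 0.06, tau: 0.08}}
  - {id: 4, lam: 0.495, gam: 20.0, delta: 0.36, rt: {mu: 0.3, sigma: 0.06, tau: 0.08}}

grid:
  lam: [0.4, 0.5, 21]
  gam: [1, 30, 30]
  delta: [0.02, 0.5, 25]

stimulus_space:
  min: 0.0
  max: 1.2
  n: 49

procedures:
  - {procedure_id: 1}
  - {procedure_id: 2}
  - {procedure_id: 3}
  - {procedure_id: 4}

eval:
  eval_times: [0.06, 0.09, 0.12, 0.24, 0.36, 0.48, 0.60, 1.20]
  precision_threshold: 0.02
  hwci_level: 0.682
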