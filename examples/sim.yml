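# Simulated culture: 3 ages, baseline vs methamphetamine, 15% threshold
outdir: out/sim
sim:
  n_neurons: 50
  n_modules: 4
  within_module_share: 0.35
  base_rate: 1.0
  duration_s: 120.0
  frame_rate_hz: 10.0
  drug_factor: 0.5
  div_decay: 0.9
  seed: 1
divs: [9, 15, 21]
treatment: meth
threshold:
  mode: proportional
  p: 0.15
restarts: 10
topology_seed: 0
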