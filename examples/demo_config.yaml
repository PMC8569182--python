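# Small end-to-end run: generate a modular connectome, calibrate feedback
# inhibition, simulate neuronal + BOLD activity, extract networks at two
# temporal scales and compute occupancy entropy.
seed: 7
output_dir: demo_out
connectome:
  n_regions: 20
  n_modules: 4
  density: 0.3
simulation:
  G: 1.5
  duration: 60.0
  transient: 10.0
extraction:
  temporal_bins_ms: [100.0, 300.0]
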