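# Two-condition ligand-density demo cohort (rendered stacks).
# Equivalent to caflow.pipeline.demo_config(); runs end-to-end in seconds.
mode: simulate-stack
seed: 0
simulate:
  conditions:
    2 ug/mL:
      median_delay_s: 35.0
      median_rise_s: 12.0
      median_peak_ratio: 2.2
    20 ug/mL:
      median_delay_s: 18.0
      median_rise_s: 9.0
      median_peak_ratio: 2.6
  n_cells_per_condition: 4
  cells_per_scene: 4
  frame_interval_s: 0.1
adhesion:
  window_s: 60.0        # firm adhesion: < 10 µm displacement per 1 min
  threshold_um: 10.0
  assay_s: 420.0
quant:
  k: 3.0                # onset trigger: plateau mean + k·SD, m frames
  m: 5
  ip_mode: raw-ratio
  activation_threshold: 1.5
stats:
  alpha: 0.05
  welch: false
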