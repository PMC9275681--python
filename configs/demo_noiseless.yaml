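# Noiseless demonstration run: detection power 1, no false peaks, no
# center jitter, no n.s. masking — the pipeline must recover the planted
# regulon exactly and reproduce byte-identical outputs on rerun.
seed: 1
simulate:
  seed: 1
  n_tus: 20
  n_direct_targets: 12
  frac_repressed: 0.25
  detection_power: 1.0
  jitter_sd: 0.0
  peak_fpr: 0.0
  ns_frac: 0.0
  lfc_effect_sd: 0.05
motif_width_min: 14
motif_width_max: 15
motif_restarts: 4
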