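# Demo pipeline run: simulates every input, then runs all four analysis
# stages on the simulated files. Completes in well under five minutes on a
# single CPU.
seed: 1
outdir: demo_out

simulate:
  enabled: true
  peak_window: 1000
  config:
    n_promoters: 2000
    n_cells: 400
    n_genes: 600
    n_clusters: 3
    program_size: 40
    program_effect: 1.0
    nb_dispersion: 0.3
    bliss_delta: 10.0
    noise_cv: 0.05
    n_bait_enriched: 25
    bait_rate_ratio: 20.0

programs:
  enabled: true
  n_perm: 300
  spline_df: 5
  gsea_fdr: 0.25

chromstate:
  enabled: true
  window: 2000
  direction: up
  q_max: 0.05

synergy:
  enabled: true

rime:
  enabled: true
  mode: fdr
  q: 0.1
  min_detected: 2
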