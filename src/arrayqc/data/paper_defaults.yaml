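call_rate_threshold: 0.95
cbs_alpha: 0.01
cbs_min_probes: 20
cbs_permutations: 200
cnv_max_pairs: 8
cnv_overlap: 0.5
cnv_sd_gate: 0.3
duplicate_threshold: 0.99
gc_score_threshold: 0.25
het_fence_k: 3.0
sim:
  baf_noise_sd: 0.03
  chip_fail_rate: 0.005
  chip_lrr_offset_sd: 0.05
  chips_per_plate: 24
  chromosome_length_bp: 30000000
  cluster_r: 2.0
  cluster_thetas:
  - 0.1
  - 0.5
  - 0.9
  cnv_spec:
  - kind: gain
    mosaic_fraction: null
    n_carriers: 6
    n_probes: 30
  - kind: loss
    mosaic_fraction: null
    n_carriers: 3
    n_probes: 25
  - kind: cnloh
    mosaic_fraction: null
    n_carriers: 1
    n_probes: 40
  - kind: mosaic_cnloh
    mosaic_fraction: 0.4
    n_carriers: 2
    n_probes: 60
  complete_fail_fraction: 0.0019
  cpg_wave_amplitude: 2.0
  dropout_given_vulnerable: 0.8
  dropout_vulnerability_coef: 0.0143
  duplicate_locus_fraction: 0.015
  end_fail_fraction: 0.5
  gc_score_good_params:
  - 5.0
  - 1.5
  gc_score_threshold: 0.25
  gc_wave_amplitude: 0.6
  genotype_error_rate: 5.0e-05
  lrr_noise_sd: 0.12
  lrr_shift:
    cnloh: 0.0
    gain: 0.32
    loss: -0.45
    mosaic_cnloh: 0.0
  maf_mixture:
  - - 0.744
    - 0.35
    - 6.0
  - - 0.256
    - 1.8
    - 1.2
  n_chromosomes: 8
  n_individuals: 400
  n_loci: 4000
  nocall_rate_coef: 0.1
  noise_jitter_sd: 0.15
  plate_fail_rate: 0.01
  quality_model:
    gDNA:blood:
    - 0.772
    - 0.15
    gDNA:buccal:
    - 0.76
    - 0.15
    gDNA:oragene:
    - 0.763
    - 0.15
    wgaDNA:blood:
    - 0.701
    - 0.15
    wgaDNA:buccal:
    - 0.604
    - 0.15
    wgaDNA:oragene:
    - 0.723
    - 0.15
  replicate_design:
    n_full: 81
    n_partial_gg: 18
    n_partial_gw: 21
    n_partial_ww: 5
  seed: 0
  singleton_gdna_fraction: 0.63
  source_mix:
    blood: 0.215
    buccal: 0.285
    oragene: 0.5
  str_contamination_rate: 0.005
  str_dropout_coef: 0.35
  str_failure_coef: 0.08
  subtelomere_fail_prob: 0.8
  subtelomere_windows: 3
  wave_sample_sd: 0.2
  wga_noise_coef: 1.2
  window_size: 50000
subtelomere_k: 3
wave_degree: 2
window_size: 50000
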