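# Matched FF/FFPET breast-tumor cohort: 8 ER+ and 8 ER- pairs, three
# FFPET amplification-kit degradation profiles plus a degradation-free
# control kit ("perfect") whose FFPET cohort is byte-identical to FF.
seed: 1
n_genes: 200
transcript_length_range: [600, 1200]
probe_sets_per_gene: {1: 0.70, 2: 0.25, 3: 0.05}
probes_per_set: 11
probe_length: 25
frac_nonmatching_probes: 0.06
frac_crosshyb_probes: 0.03
n_complete_mismatch_sets: 25
n_pairs_per_group: 8
frac_de_genes: 0.2
effect_log2_range: [1.2, 3.0]
background_mean: 50.0
background_sd: 10.0
background_scale_sd: 0.3
probe_affinity_sd: 0.5
measurement_sd_ff: 0.25
tissue_sd: 0.5
baseline_log2_range: [6.0, 10.0]
kit_profiles:
  perfect: {}
  nugen:
    three_prime_decay: 0.0035
    extra_noise_sd: 0.3
    dropout_prob: 0.02
    global_attenuation: 1.0
  affy2c:
    three_prime_decay: 0.006
    extra_noise_sd: 0.6
    dropout_prob: 0.05
    global_attenuation: 2.0
  wta:
    three_prime_decay: 0.008
    extra_noise_sd: 1.0
    dropout_prob: 0.10
    global_attenuation: 3.0
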