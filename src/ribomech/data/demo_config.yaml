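# Demo pipeline configuration: every stage on, desk-scale sizes.
seed: 1
outdir: ribomech_out
run_kinetics: true
run_ph: true
run_thermo: true
run_landscape: true
run_alchemical: true
n_replicates: 3
kinetics_noise_sd: 0.02
ph_cv: 0.10
ph_n_reps: 3
barrier: 16.3
ts2_xi_at: -0.24
n_images: 32
string_max_iter: 2000
n_lambda: 25
n_per_lambda: 300
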