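{
  "description": "Published measured and computed quantities for the MTR1 alkyl-transferase ribozyme and its atomic variants: observed rate constants for 4-aminomethyl-benzyl transfer (min^-1, 37 C) with s.d. over >= 3 replicates and printed relative rates (vs unmodified at pH 6.0, 2 significant figures); free-energy barriers (kcal/mol), relative intrinsic rates, and the solution -> ribozyme pKa chain from QM/MM + alchemical free-energy simulations.",
  "reference_cell": {"variant": "C10/A63", "pH": 6.0},
  "table1": [
    {"variant": "C10/A63", "pH": 6.0, "k_obs": 0.6, "sd": 0.01, "rel_rate_printed": 1.0},
    {"variant": "C10/A63", "pH": 7.5, "k_obs": 0.019, "sd": 0.003, "rel_rate_printed": 0.032},
    {"variant": "C10/A63", "pH": 8.0, "k_obs": 0.013, "sd": 0.001, "rel_rate_printed": 0.022},
    {"variant": "C10 n1c", "pH": 6.0, "k_obs": 4.4e-5, "sd": 1.7e-5, "rel_rate_printed": 7.3e-5},
    {"variant": "C10 n1c", "pH": 8.0, "k_obs": 5.0e-5, "sd": 4.0e-6, "rel_rate_printed": 8.3e-5},
    {"variant": "C10 n1c c5n", "pH": 6.0, "k_obs": 0.67, "sd": 0.08, "rel_rate_printed": 1.1},
    {"variant": "C10 n1c c5n", "pH": 7.5, "k_obs": 0.06, "sd": 0.01, "rel_rate_printed": 0.1},
    {"variant": "C10 n1c c5n", "pH": 8.0, "k_obs": 0.0158, "sd": 0.0006, "rel_rate_printed": 0.026},
    {"variant": "A63 n7c", "pH": 6.0, "k_obs": 5.1, "sd": 0.4, "rel_rate_printed": 8.5},
    {"variant": "A63 n7c", "pH": 7.5, "k_obs": 0.52, "sd": 0.03, "rel_rate_printed": 0.87},
    {"variant": "A63 n7c", "pH": 8.0, "k_obs": 0.38, "sd": 0.06, "rel_rate_printed": 0.63}
  ],
  "table2": [
    {"variant": "MTR1", "dG_barrier": 16.3, "k_int_rel_calc_printed": 1.0,
     "k_int_rel_expt": 1.0, "pka_soln": 4.2, "dpka_shift": 2.1,
     "pka_ribozyme_printed": 6.3, "pka_apparent_expt": 6.4,
     "order_of_magnitude_only": false},
    {"variant": "C10(n1c)", "dG_barrier": 30.3, "k_int_rel_calc_printed": 1e-11,
     "k_int_rel_expt": 1e-4, "pka_soln": 11.4, "dpka_shift": 5.2,
     "pka_ribozyme_printed": 16.6, "pka_apparent_expt": null,
     "order_of_magnitude_only": true},
    {"variant": "C10(n1c,c5n)", "dG_barrier": 15.7, "k_int_rel_calc_printed": 2.7,
     "k_int_rel_expt": 1.1, "pka_soln": 3.7, "dpka_shift": 2.9,
     "pka_ribozyme_printed": 6.6, "pka_apparent_expt": 6.5,
     "order_of_magnitude_only": false},
    {"variant": "A63(n7c)", "dG_barrier": 15.4, "k_int_rel_calc_printed": 4.3,
     "k_int_rel_expt": 6.1, "pka_soln": 4.2, "dpka_shift": 2.1,
     "pka_ribozyme_printed": 6.3, "pka_apparent_expt": 6.9,
     "order_of_magnitude_only": false}
  ],
  "bronsted": {
    "pka_nuc": [3.7, 5.3],
    "relative_rates": [1.0, 6.1],
    "beta_printed": 0.5
  },
  "kinetics": {
    "k_obs_ph6_unmodified": 0.60,
    "k_obs_slow_n1c": 4e-5,
    "k_obs_slow_n1c_band": 2e-5,
    "apparent_pka": {"C10/A63": 6.4, "C10 n1c c5n": 6.5, "A63 n7c": 6.9}
  },
  "ts2_xi_at": -0.24
}
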