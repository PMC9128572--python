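{
  "bke_amplitude": {
    "image": [64, 64],
    "h": 16.0,
    "w_m": 3.87,
    "sigma_n": 40.0,
    "w_s": 1.0,
    "r_s": [32.0, 32.0],
    "amplitude_prior": {"dist": "normal", "mu": 9.0, "sigma": 4.0},
    "utility": {"kind": "gaussian", "param": 3.0},
    "n_test_per_class": 1000,
    "n_val_per_class": 1000
  },
  "lumpy_location": {
    "image": [64, 64],
    "h": 40.0,
    "w_m": 0.5,
    "sigma_n": 320.0,
    "A_s": 6.0,
    "w_s": 3.0,
    "location_prior": {"dist": "uniform", "lo": 16.0, "hi": 48.0},
    "lumpy": {"N_bar": 5.0, "a": 10.0, "w_b": 7.0},
    "l1_utility_param": 20.0,
    "quadratic_utility_params": [100.0, 200.0],
    "n_train_per_class": 150000,
    "n_test_per_class": 1000
  },
  "clb_width": {
    "image": [64, 64],
    "sigma_n": 0.33,
    "A_s": 0.05,
    "r_s": [32.0, 32.0],
    "width_prior": {"dist": "uniform", "lo": 1.0, "hi": 6.0},
    "clb": {"K_bar": 70.0, "N_bar": 20.0, "L_x": 5.0, "L_y": 2.0,
            "alpha_blob": 2.1, "beta": 0.5, "sigma_cluster": 12.0},
    "utility": {"kind": "gaussian", "param": 3.0},
    "n_train_per_class": 200000,
    "n_test_per_class": 1000
  },
  "slo_fit_images_per_class": 4000,
  "mcmc_proposal_std": {"bke_amplitude": 3.0, "lumpy_location": 4.0}
}
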