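name: bke_amplitude
n_rows: 64
n_cols: 64
h: 16.0
w_m: 3.87
sigma_n: 40.0
signal:
  A_s:
    dist: normal
    mu: 9.0
    sigma: 4.0
  w_s: 1.0
  r_s:
  - 32.0
  - 32.0
background:
  kind: none
utility:
  kind: gaussian
  param: 3.0
n_train_present: 150000
n_train_absent: 150000
n_val_present: 1000
n_val_absent: 1000
n_test_present: 1000
n_test_absent: 1000
seed: 0
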