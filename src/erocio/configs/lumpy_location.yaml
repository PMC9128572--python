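name: lumpy_location
n_rows: 64
n_cols: 64
h: 40.0
w_m: 0.5
sigma_n: 320.0
signal:
  A_s: 6.0
  w_s: 3.0
  r_s:
    dist: uniform
    lo: 16.0
    hi: 48.0
    vector: true
background:
  kind: lumpy
  N_bar: 5.0
  a: 10.0
  w_b: 7.0
utility:
  kind: l1
  param: 20.0
n_train_present: 150000
n_train_absent: 150000
n_val_present: 1000
n_val_absent: 1000
n_test_present: 1000
n_test_absent: 1000
seed: 0
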