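name: clb_width
n_rows: 64
n_cols: 64
h: 1.0
w_m: 0.0
sigma_n: 0.33
signal:
  A_s: 0.05
  w_s:
    dist: uniform
    lo: 1.0
    hi: 6.0
  r_s:
  - 32.0
  - 32.0
background:
  kind: clb
  K_bar: 70.0
  N_bar: 20.0
  L_x: 5.0
  L_y: 2.0
  alpha_blob: 2.1
  beta: 0.5
  sigma_cluster: 12.0
utility:
  kind: gaussian
  param: 3.0
n_train_present: 200000
n_train_absent: 200000
n_val_present: 1000
n_val_absent: 1000
n_test_present: 1000
n_test_absent: 1000
seed: 0
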