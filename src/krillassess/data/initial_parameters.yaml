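ln_R0: 16.0
ln_Rbar: 16.0
eps_R:
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
ln_sigma_R: -0.3567
ln_M: -0.2232
alpha_s:
- 3.3
- 1.3
- 1.3
- 1.3
- 1.3
- 1.3
beta_s:
- 0.06
- 2.8
- 2.8
- 2.8
- 2.8
- 2.8
alpha_f: 1.3
beta_f: 2.8
mu_f: -2.3026
eps_f:
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
sigma_C: 0.1
ln_q_f: 0.0
h: 0.85
ln_q_s:
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
ln_Linf: 4.11
ln_k: -0.799
ln_sigma_v: 1.459
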