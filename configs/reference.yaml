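c_ratio: 0.5
d_ratio: 0.8
design:
  '40':
  - 10.0
  - 20.0
  - 30.0
  - 40.0
  - 50.0
  - 60.0
  '50':
  - 5.0
  - 10.0
  - 20.0
  - 30.0
  - 40.0
  - 50.0
  - 60.0
forces:
- 10.0
- 30.0
- 50.0
n_per_cell: 10
pop_models:
  '40':
    intercept: -5.0
    slope: 0.05
  '50':
    intercept: -3.5
    slope: 0.06
seed: 0
truths:
- cf_g: 10.0
  k: 0.06223202954037962
  noise_sd: 0.3
  power_w: 40.0
  response: depth
  ymax: 4.997040699384828
- cf_g: 10.0
  k: 0.08788492721351321
  noise_sd: 0.3
  power_w: 40.0
  response: diameter
  ymax: 8.0
- cf_g: 10.0
  k: 0.049095630980683286
  noise_cv: 0.1
  power_w: 40.0
  response: li_drop
  ymax: 120.0
- cf_g: 30.0
  k: 0.06223202954037962
  noise_sd: 0.3
  power_w: 40.0
  response: depth
  ymax: 5.245947020801861
- cf_g: 30.0
  k: 0.10372004923396604
  noise_sd: 0.3
  power_w: 40.0
  response: diameter
  ymax: 8.0
- cf_g: 30.0
  k: 0.059192418843034604
  noise_cv: 0.1
  power_w: 40.0
  response: li_drop
  ymax: 120.0
- cf_g: 50.0
  k: 0.0691466994893107
  noise_sd: 0.3
  power_w: 40.0
  response: depth
  ymax: 5.339324097170625
- cf_g: 50.0
  k: 0.10964690919019267
  noise_sd: 0.3
  power_w: 40.0
  response: diameter
  ymax: 8.0
- cf_g: 50.0
  k: 0.05671391854665137
  noise_cv: 0.1
  power_w: 40.0
  response: li_drop
  ymax: 120.0
- cf_g: 10.0
  k: 0.08136343084784614
  noise_sd: 0.3
  power_w: 50.0
  response: depth
  ymax: 4.893522991815729
- cf_g: 10.0
  k: 0.09715548915586691
  noise_sd: 0.3
  power_w: 50.0
  response: diameter
  ymax: 8.0
- cf_g: 10.0
  k: 0.07995087128451549
  noise_cv: 0.1
  power_w: 50.0
  response: li_drop
  ymax: 120.0
- cf_g: 30.0
  k: 0.18569234620919725
  noise_sd: 0.3
  power_w: 50.0
  response: depth
  ymax: 4.503418804149476
- cf_g: 30.0
  k: 0.19349454562975174
  noise_sd: 0.3
  power_w: 50.0
  response: diameter
  ymax: 8.0
- cf_g: 30.0
  k: 0.09398306502016514
  noise_cv: 0.1
  power_w: 50.0
  response: li_drop
  ymax: 120.0
- cf_g: 50.0
  k: 0.10233711524417982
  noise_sd: 0.3
  power_w: 50.0
  response: depth
  ymax: 4.652102633542625
- cf_g: 50.0
  k: 0.10372004923396604
  noise_sd: 0.3
  power_w: 50.0
  response: diameter
  ymax: 8.0
- cf_g: 50.0
  k: 0.07475925626604045
  noise_cv: 0.1
  power_w: 50.0
  response: li_drop
  ymax: 120.0
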