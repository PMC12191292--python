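n_subjects: 80
null_effect: false
p_male: 0.475
pd_bound: 1.2
pd_strata:
  classical|0:
  - 0.701
  - - 0.687
    - 0.72
  classical|1:
  - 0.765
  - - 0.761
    - 0.784
  other|0:
  - 0.664
  - - 0.619
    - 0.719
  other|1:
  - 0.674
  - - 0.641
    - 0.736
phenotype_probs:
- 0.225
- 0.675
- 0.1
seed: 0
sfn_link:
- -0.87
- 0.42
t2_strata:
  classical|0:
  - 102.1
  - - 92.0
    - 117.9
  classical|1:
  - 104.4
  - - 93.5
    - 113.9
  other|0:
  - 94.1
  - - 83.8
    - 101.4
  other|1:
  - 92.3
  - - 89.7
    - 99.8
vol_by_sex:
  f:
  - 987.8
  - - 769.1
    - 1187.5
  m:
  - 1342.1
  - - 1012.6
    - 1610.7
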