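# Default analysis configuration: the shipped 432-subject arm table,
# ATRC thresholding at the 95% sham level for stages SD and CD, and the
# He/Si/Fe x {0,1,5,10} cGy subset analyzed with GNB, SVM and ANN.
classifiers:
- GNB
- SVM
- ANN
cutoff: 0.5
design:
  arms:
  - - sham
    - 0.0
    - 62
  - - He
    - 1.0
    - 19
  - - He
    - 5.0
    - 20
  - - He
    - 10.0
    - 15
  - - O
    - 1.5
    - 6
  - - O
    - 5.0
    - 18
  - - O
    - 10.0
    - 11
  - - Si
    - 1.0
    - 15
  - - Si
    - 3.0
    - 14
  - - Si
    - 5.0
    - 63
  - - Si
    - 10.0
    - 45
  - - Si
    - 15.0
    - 15
  - - Ti
    - 3.0
    - 8
  - - Ti
    - 5.0
    - 16
  - - Ti
    - 10.0
    - 12
  - - Ti
    - 15.0
    - 10
  - - Fe
    - 1.0
    - 9
  - - Fe
    - 3.0
    - 15
  - - Fe
    - 5.0
    - 26
  - - Fe
    - 10.0
    - 17
  - - Fe
    - 15.0
    - 16
  stages_post:
  - SD
  - CD
  - CDR
  - IDS
  - IDR
  - EDS
  - EDR
  stages_prescreen:
  - SD
  - CD
  - CDR
  - IDS
doses:
- 0.0
- 1.0
- 5.0
- 10.0
feature_stages:
- SD
- CD
- CDR
- IDS
hyperparams: {}
input_path: null
ions:
- He
- Si
- Fe
level: 0.95
params:
  ability_mean: 1.6
  ability_sd: 0.3
  baseline_coef: 0.05
  dose_overrides:
  - - Si
    - CD
    - - - 1.0
        - 0.15
      - - 5.0
        - 0.05
      - - 10.0
        - 0.85
      - - 15.0
        - 1.2
  latency_meanlog: 2.302585092994046
  latency_sdlog: 0.4
  learning_rate: 0.12
  max_stage_failures: 2
  retest_sd: 0.8
  susceptibility:
  - - Fe
    - SD
    - 0.14
  - - Fe
    - CD
    - 0.135
  - - Si
    - SD
    - 0.11
  - - He
    - SD
    - 0.0
  - - He
    - CD
    - 0.02
  - - O
    - SD
    - 0.06
  - - Ti
    - SD
    - 0.07
score_type: ATRC
seed: 0
source: synthetic
stages:
- SD
- CD
tie_rule: strict_below
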