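arm:
  label: option1
  control_rate: 0.62
  human_cost: 24469.97
  project_cost: 1278.47
  n_enrolled: 415
  intervention_span_years: 1.5
  lifelong_programme: true
transitions:
  p0.5_1: 0.0413
  p0.5_2: 0.0056
  p0.5_3: 0.0016
  p1_0.5: 0.1675
  p1_2: 0.0072
  p1_3: 0.0016
  p2_0.5: 0.0227
  p2_1: 0.0289
  p2_3: 0.0008
  p3_0.5: 0.006
  p3_1: 0.006
  p3_2: 0.0008
  p0.5_MI: 0.0014
  P1_MI: 0.0022
  P2_MI: 0.0035
  P3_MI: 0.0035
  P0.5_CHF: 0.0002
  P1_CHF: 0.0003
  P2_CHF: 0.0004
  P3_CHF: 0.0004
  P0.5_Stroke: 0.0011
  P1_Stroke: 0.002
  P2_Stroke: 0.0035
  P3_Stroke: 0.0035
  pMI_Death: 0.0049
  pCHF_Death: 0.0007
  pStroke_Death: 0.004
  P1_ESRD: 0.0152
  P2_ESRD: 0.0078
  P3_ESRD: 0.0017
  pESRD_Death: 0.0552
utilities:
  U_pre: 0.651375
  U_1: 0.65525
  U_2: 0.683
  U_3: 0.669
  U_MI: 0.684
  U_Stroke: 0.605
  U_CHF: 0.64
  U_ESRD: 0.6
costs:
  cprehy: 140.69
  chy1: 150.87
  chy2: 187.08
  chy3: 468.15
  cMI: 4953.07
  cCHF: 1754.3
  cStroke: 1974.68
  cESRD: 19406.36
mortality:
  35: 0.0012
  40: 0.0018
  45: 0.0026
  50: 0.0042
  55: 0.0062
  60: 0.0103
  65: 0.0172
  70: 0.0306
  75: 0.0495
  80: 0.0848
  85: 0.1274
  90: 0.1908
  95: 0.2171
  100: 0.4543
economics:
  discount_rate: 0.05
  discount_rate_range:
  - 0.0
  - 0.08
  wtp: 1599.16
  horizon: 65
  cycle_length: 1.0
  start_age: 35.0
  reference_control_rate: 0.61
  initial_distribution:
    prehypertension: 0.32
    L1: 0.53
    L2: 0.12
    L3: 0.03
sensitivity:
  p0.5_1:
    low: 0.033
    high: 0.0496
    distribution: beta
  p0.5_2:
    low: 0.0045
    high: 0.0067
    distribution: beta
  p0.5_3:
    low: 0.0013
    high: 0.0019
    distribution: beta
  p1_0.5:
    low: 0.134
    high: 0.201
    distribution: beta
  p1_2:
    low: 0.0058
    high: 0.0086
    distribution: beta
  p1_3:
    low: 0.0013
    high: 0.0019
    distribution: beta
  p2_0.5:
    low: 0.0182
    high: 0.0272
    distribution: beta
  p2_1:
    low: 0.0231
    high: 0.0347
    distribution: beta
  p2_3:
    low: 0.0006
    high: 0.001
    distribution: beta
  p3_0.5:
    low: 0.0048
    high: 0.0072
    distribution: beta
  p3_1:
    low: 0.0048
    high: 0.0072
    distribution: beta
  p3_2:
    low: 0.0006
    high: 0.001
    distribution: beta
  p0.5_MI:
    low: 0.0012
    high: 0.0017
    distribution: beta
  P1_MI:
    low: 0.0018
    high: 0.0027
    distribution: beta
  P2_MI:
    low: 0.0028
    high: 0.0042
    distribution: beta
  P3_MI:
    low: 0.0028
    high: 0.0042
    distribution: beta
  P0.5_CHF:
    low: 0.0002
    high: 0.0003
    distribution: beta
  P1_CHF:
    low: 0.0003
    high: 0.0004
    distribution: beta
  P2_CHF:
    low: 0.0003
    high: 0.0005
    distribution: beta
  P3_CHF:
    low: 0.0003
    high: 0.0005
    distribution: beta
  P0.5_Stroke:
    low: 0.0009
    high: 0.0013
    distribution: beta
  P1_Stroke:
    low: 0.0016
    high: 0.0024
    distribution: beta
  P2_Stroke:
    low: 0.0028
    high: 0.0042
    distribution: beta
  P3_Stroke:
    low: 0.0028
    high: 0.0042
    distribution: beta
  pMI_Death:
    low: 0.00392
    high: 0.00588
    distribution: beta
  pCHF_Death:
    low: 0.00053
    high: 0.00076
    distribution: beta
  pStroke_Death:
    low: 0.0032
    high: 0.0048
    distribution: beta
  P1_ESRD:
    low: 0.0121
    high: 0.0182
    distribution: beta
  P2_ESRD:
    low: 0.0063
    high: 0.0094
    distribution: beta
  P3_ESRD:
    low: 0.0014
    high: 0.002
    distribution: beta
  pESRD_Death:
    low: 0.0442
    high: 0.0662
    distribution: beta
  U_pre:
    low: 0.6066
    high: 0.6962
    distribution: beta
  U_1:
    low: 0.6057
    high: 0.7048
    distribution: beta
  U_2:
    low: 0.5595
    high: 0.8065
    distribution: beta
  U_3:
    low: 0.5153
    high: 0.8227
    distribution: beta
  U_MI:
    low: 0.6165
    high: 0.7524
    distribution: beta
  U_Stroke:
    low: 0.5445
    high: 0.6655
    distribution: beta
  U_CHF:
    low: 0.6086
    high: 0.6714
    distribution: beta
  U_ESRD:
    low: 0.39
    high: 0.81
    distribution: beta
  cprehy:
    low: 112.55
    high: 168.83
    distribution: gamma
  chy1:
    low: 120.7
    high: 181.05
    distribution: gamma
  chy2:
    low: 149.66
    high: 224.49
    distribution: gamma
  chy3:
    low: 374.52
    high: 561.78
    distribution: gamma
  cMI:
    low: 3962.45
    high: 5943.68
    distribution: gamma
  cCHF:
    low: 1403.44
    high: 2105.16
    distribution: gamma
  cStroke:
    low: 1579.74
    high: 2369.61
    distribution: gamma
  cESRD:
    low: 15525.09
    high: 23287.63
    distribution: gamma
  discount_rate:
    low: 0.0
    high: 0.08
    distribution: fixed
  control_rate:
    low: 0.33
    high: 0.92
    distribution: beta
  human_cost:
    low: 15798.43
    high: 33141.5
    distribution: gamma
  project_cost:
    low: 204.85
    high: 2352.09
    distribution: gamma
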