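strategies:
- name: Conventional Care
  p_death:
    base: 0.54
    low: 0.47
    high: 0.61
  p_good_given_survival:
    base: 0.69
    low: 0.6
    high: 0.77
  cooling_cost:
    base: 0.0
    low: 0.0
    high: 0.0
  sedation_cost:
    base: 0.0
    low: 0.0
    high: 0.0
  icu_days_survivor:
    base: 3
    low: 1
    high: 5
  icu_days_nonsurvivor:
    base: 1
    low: 0.5
    high: 3
  floor_days:
    base: 18
    low: 10
    high: 36
- name: Cooling Blankets
  p_death:
    base: 0.5
    low: 0.45
    high: 0.54
  p_good_given_survival:
    base: 0.86
    low: 0.8
    high: 0.9
  cooling_cost:
    base: 6729
    low: 4526
    high: 8951
  sedation_cost:
    base: 1197
    low: 854
    high: 1708
  icu_days_survivor:
    base: 5
    low: 2
    high: 7
  icu_days_nonsurvivor:
    base: 1
    low: 0.5
    high: 3
  floor_days:
    base: 18
    low: 10
    high: 36
- name: Peritoneal Lavage
  p_death:
    base: 0.31
    low: 0.13
    high: 0.56
  p_good_given_survival:
    base: 0.86
    low: 0.8
    high: 0.9
  cooling_cost:
    base: 9284
    low: 8234
    high: 9784
  sedation_cost:
    base: 1197
    low: 854
    high: 1708
  icu_days_survivor:
    base: 5
    low: 2
    high: 7
  icu_days_nonsurvivor:
    base: 1
    low: 0.5
    high: 3
  floor_days:
    base: 18
    low: 10
    high: 36
- name: V-V ECMO
  p_death:
    base: 0.5
    low: 0.2
    high: 0.8
  p_good_given_survival:
    base: 0.75
    low: 0.28
    high: 0.97
  cooling_cost:
    base: 39038
    low: 19519
    high: 58557
  sedation_cost:
    base: 1197
    low: 854
    high: 1708
  icu_days_survivor:
    base: 5
    low: 2
    high: 7
  icu_days_nonsurvivor:
    base: 1
    low: 0.5
    high: 3
  floor_days:
    base: 18
    low: 10
    high: 36
shared:
  c_icu_day:
    base: 4973
    low: 3730
    high: 6216
  c_floor_day:
    base: 2365
    low: 1774
    high: 2956
  icd_cost:
    base: 35868
    low: 26901
    high: 44835
  rehab_daily:
    base: 1443
    low: 1082
    high: 1804
  rehab_days:
    base: 30
    low: 10
    high: 90
  transport_annual_good:
    base: 22
    low: 17
    high: 28
  caregiver_clinic_annual:
    base: 175
    low: 131
    high: 219
  outpatient_annual_good:
    base: 1305
    low: 1180
    high: 1430
  outpatient_annual_poor:
    base: 2345
    low: 2140
    high: 2550
  vent_daily:
    base: 1582
    low: 1187
    high: 1978
  ltc_daily:
    base: 257
    low: 193
    high: 321
  opportunity_cost_annual_poor:
    base: 36410
    low: 27308
    high: 45513
  transport_annual_poor:
    base: 44
    low: 33
    high: 55
  f_vent:
    base: 0.6194618151648111
    low: 0.6194618151648111
    high: 0.6194618151648111
  le_good:
    base: 5.5
    low: 4
    high: 10
  le_poor:
    base: 1.0
    low: 0.25
    high: 3.0
  u_good:
    base: 0.76
    low: 0.55
    high: 0.97
  u_poor:
    base: 0.35
    low: 0.2
    high: 0.5
  discount_rate:
    base: 0.03
    low: 0.0
    high: 0.05
wtp_default: 100000.0
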