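# Bundled base case: published 2023 Turkish cost/utility inputs
# (US$ at 28.0153 TRY/US$), illustrative transition defaults, and
# a synthetic Gompertz-Makeham life table. Units documented in
# remarkov.config_io.
run:
  start_age: 40
  horizon: 60
  cycle_length: 1.0
  discount_rate: 0.03
  discount_timing: first-cycle-undiscounted
  half_cycle_correction: false
  perspective: SUT
  cohort_size: 1000
  wtp_thresholds:
  - 10994.0
  - 39330.0
  master_seed: 20231019
  try_per_usd: 28.0153
utilities:
  t2dm: 0.772
  remission: 0.812
transitions:
  PT:
    p_remission: 0.05
    p_relapse: 0.1
    lockout_cycles: 2
    mortality_hr_t2dm: 1.5
    mortality_hr_remission: 1.0
    p_periop_death: 0.0
  SG:
    p_remission: 0.35
    p_relapse: 0.04
    lockout_cycles: 2
    mortality_hr_t2dm: 1.5
    mortality_hr_remission: 1.0
    p_periop_death: 0.0
life_table:
  gompertz_makeham:
    makeham: 0.0005
    gompertz_a: 2.0e-05
    gompertz_b: 0.1
    age_lo: 40
    age_hi: 99
costs:
  PT:
    bands:
      years1_2:
      - 1
      - 2
      year3plus:
      - 3
      - null
    PHSP:
      REMISSION:
        year3plus:
          outpatient: 17.85
          hba1c: 9.07
          symptomatic_drugs: 46.31
        years1_2:
          outpatient: 53.54
          consultation: 1.68
          tests: 10.58
          t2dm_drugs: 75.15
          obesity_drugs: 772.85
          symptomatic_drugs: 61.75
          strip: 3.45
      T2DM:
        year3plus:
          outpatient: 35.69
          consultation: 1.68
          tests: 10.58
          t2dm_drugs: 75.15
          symptomatic_drugs: 65.77
          strip: 3.45
        years1_2:
          outpatient: 53.54
          consultation: 1.68
          tests: 10.58
          t2dm_drugs: 75.15
          obesity_drugs: 772.85
          symptomatic_drugs: 61.75
          strip: 3.45
    printed_totals:
      PHSP:
        REMISSION:
          year3plus: 73.23
          years1_2: 975.55
        T2DM:
          year3plus: 192.32
          years1_2: 975.55
      SUT:
        REMISSION:
          year3plus: 48.83
          years1_2: 697.88
        T2DM:
          year3plus: 128.36
          years1_2: 697.88
    SUT:
      REMISSION:
        year3plus:
          outpatient: 13.06
          hba1c: 6.54
          symptomatic_drugs: 29.23
        years1_2:
          outpatient: 39.19
          consultation: 0.34
          tests: 7.2
          t2dm_drugs: 54.26
          obesity_drugs: 556.45
          symptomatic_drugs: 38.98
          strip: 1.45
      T2DM:
        year3plus:
          outpatient: 26.13
          consultation: 0.34
          tests: 7.2
          t2dm_drugs: 54.26
          symptomatic_drugs: 38.98
          strip: 1.45
        years1_2:
          outpatient: 39.19
          consultation: 0.34
          tests: 7.2
          t2dm_drugs: 54.26
          obesity_drugs: 556.45
          symptomatic_drugs: 38.98
          strip: 1.45
  SG:
    bands:
      year1:
      - 1
      - 1
      year2plus:
      - 2
      - null
    PHSP:
      REMISSION:
        year1:
          outpatient: 98.16
          operation: 2342.33
          consultation: 1.68
          tests: 10.58
          t2dm_drugs: 75.15
          sg_drugs: 65.77
          symptomatic_drugs: 61.75
          strip: 3.45
        year2plus:
          outpatient: 26.77
          hba1c: 9.07
          symptomatic_drugs: 46.31
      T2DM:
        year1:
          outpatient: 98.16
          operation: 2342.3
          consultation: 1.68
          tests: 10.58
          t2dm_drugs: 75.15
          sg_drugs: 65.77
          symptomatic_drugs: 61.75
          strip: 3.45
        year2plus:
          outpatient: 44.62
          consultation: 1.68
          tests: 10.58
          t2dm_drugs: 75.15
          symptomatic_drugs: 61.75
          strip: 3.45
    printed_totals:
      PHSP:
        REMISSION:
          year1: 2658.87
          year2plus: 82.15
        T2DM:
          year1: 2658.87
          year2plus: 197.23
      SUT:
        REMISSION:
          year1: 1391.4
          year2plus: 55.37
        T2DM:
          year1: 1391.4
          year2plus: 133.45
    SUT:
      REMISSION:
        year1:
          outpatient: 71.85
          operation: 1171.16
          consultation: 0.34
          tests: 7.2
          t2dm_drugs: 54.26
          sg_drugs: 47.59
          symptomatic_drugs: 38.98
          strip: 1.45
        year2plus:
          outpatient: 19.6
          hba1c: 6.54
          symptomatic_drugs: 29.23
      T2DM:
        year1:
          outpatient: 71.85
          operation: 1171.16
          consultation: 0.34
          tests: 7.2
          t2dm_drugs: 54.26
          sg_drugs: 47.59
          symptomatic_drugs: 38.98
          strip: 1.45
        year2plus:
          outpatient: 32.66
          consultation: 0.34
          tests: 7.2
          t2dm_drugs: 54.26
          symptomatic_drugs: 38.98
          strip: 1.45
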