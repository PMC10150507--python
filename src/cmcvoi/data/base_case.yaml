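# Base-case model configuration: decision-tree inputs for end-stage thumb CMC
# arthritis (conservative management vs trapeziectomy vs trapeziectomy + LRTI).
# Fees are 2020 US Medicare amounts (CPT 25210 trapeziectomy, CPT 25447 LRTI,
# CPT 26356 flexor tendon repair); utilities are EQ-5D index values from the
# UK Hand Registry. Non-uniform distributions take mean = base and
# sd = (high - low) / 4; low == high collapses to a point mass.
parameters:
  age: {base: 62, low: 61, high: 64, family: uniform}
  life_expectancy: {base: 86, low: 82, high: 98, family: uniform}
  discount_rate: 0.03
  retirement_age: {base: 66, low: 60, high: 70, family: truncated_normal_positive}
  annual_wage: {base: 51960, low: 10000, high: 250000, family: truncated_normal_positive}
  days_off_trap: {base: 30, low: 14, high: 84, family: truncated_normal_positive}
  days_off_lrti: {base: 30, low: 14, high: 84, family: truncated_normal_positive}

  p_fail_cons: 1.0
  p_crps_trap: {base: 0.029, low: 0.016, high: 0.095, family: beta}
  p_rupture_trap: 0.0
  p_fail_trap: {base: 0.079, low: 0.04, high: 0.13, family: beta}
  p_crps_lrti: {base: 0.04, low: 0.018, high: 0.08, family: beta}
  p_rupture_lrti: {base: 0.043, low: 0.043, high: 0.043, family: beta}
  p_fail_lrti: {base: 0.066, low: 0.01, high: 0.13, family: beta}

  fee_physician_trap: {base: 508.39, low: 448.62, high: 702.02, family: truncated_normal_positive}
  fee_anesthesia_trap: {base: 151, low: 135.9, high: 166.1, family: truncated_normal_positive}
  fee_facility_trap: {base: 2830.40, low: 2547.36, high: 3113.44, family: truncated_normal_positive}
  fee_hand_therapy_trap: {base: 477.28, low: 432.36, high: 673.75, family: truncated_normal_positive}
  fee_physician_lrti: {base: 854.53, low: 756.87, high: 1181.55, family: truncated_normal_positive}
  fee_anesthesia_lrti: {base: 194, low: 174.6, high: 213.4, family: truncated_normal_positive}
  fee_facility_lrti: {base: 2830.40, low: 2547.36, high: 3113.44, family: truncated_normal_positive}
  fee_hand_therapy_lrti: {base: 477.28, low: 432.36, high: 673.75, family: truncated_normal_positive}
  fee_crps_physician: {base: 444, low: 399.6, high: 488.4, family: truncated_normal_positive}
  fee_repair_physician: {base: 822.05, low: 739.845, high: 904.255, family: truncated_normal_positive}
  fee_repair_anesthesia: {base: 124.7233, low: 112.251, high: 137.1957, family: truncated_normal_positive}
  fee_repair_hospital: {base: 2623.34, low: 2361.006, high: 2885.674, family: truncated_normal_positive}

  u_baseline: {base: 0.675, low: 0.26, high: 0.8, family: normal, support: [-0.594, 1.0]}
  du_trap: {base: 0.16, low: 0.14, high: 0.19, family: normal}
  du_lrti: {base: 0.14, low: 0.11, high: 0.17, family: normal}
  du_crps_decrement: 0.0
  du_fail_decrement: 0.0

  wtp: 100000

study:
  annual_cases: 40000
  horizon_years: 10
  population_discount_rate: 0.03
  cost_per_participant: 10000
  sigma_individual: 0.30
  trial_n_grid: [250, 500, 750, 1000, 1250]
  # Published EVSI curve anchor (per-person value of a 250-per-arm two-arm
  # utility trial) used by the sigma_individual calibration helper.
  evsi_calibration: {n_per_arm: 250, evsi_per_person: 713.0}

scenarios:
  # LRTI's 12-month utility gain set 0.01 above trapeziectomy's: the
  # head-to-head threshold scenario under which LRTI becomes cost-effective.
  lrti_gain_plus_001:
    du_lrti: {offset_from: du_trap, offset: 0.01}
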