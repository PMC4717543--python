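# The seven built-in scenarios.
#
# Treatment scenarios change the uptake of medical therapies from the 2012
# baseline toward conservative / feasible / optimal targets (optimal targets
# follow achievements of exemplar countries; conservative is broadly a 10%
# relative increase, with some targets set directly; feasible is halfway
# between).  The printed target uptakes below are authoritative — the
# conservative column is NOT recomputed as 1.1 x baseline, because some
# published targets (e.g. primary-prevention smoking cessation 0.04 -> 0.07)
# deviate from that rule.
#
# Policy scenarios change population-level risk-factor exposures by the dose
# shown (same units as the effect's reference dose).

treatments:
  thrombolysis:
    category: acute
    effect: thrombolysis
    uptake: {baseline: 0.01, conservative: 0.011, feasible: 0.05, optimal: 0.13}
  aspirin_acute:
    category: acute
    effect: aspirin_acute
    uptake: {baseline: 0.50, conservative: 0.55, feasible: 0.70, optimal: 0.85}
  stroke_unit:
    category: acute
    effect: stroke_unit
    uptake: {baseline: 0.00, conservative: 0.01, feasible: 0.40, optimal: 0.85}
  aspirin_secondary:
    category: secondary
    effect: aspirin_secondary
    uptake: {baseline: 0.26, conservative: 0.29, feasible: 0.50, optimal: 0.81}
  statin_secondary:
    category: secondary
    effect: statin_secondary
    uptake: {baseline: 0.48, conservative: 0.53, feasible: 0.70, optimal: 0.80}
  warfarin_secondary:
    category: secondary
    effect: warfarin_secondary
    uptake: {baseline: 0.14, conservative: 0.20, feasible: 0.40, optimal: 0.50}
  bp_control_secondary:
    category: secondary
    effect: bp_control_secondary
    uptake: {baseline: 0.35, conservative: 0.39, feasible: 0.50, optimal: 0.62}
  smoking_cessation_secondary:
    category: secondary
    effect: smoking_cessation
    uptake: {baseline: 0.30, conservative: 0.33, feasible: 0.50, optimal: 0.60}
  bp_control_primary:
    category: primary
    effect: bp_control_primary
    uptake: {baseline: 0.07, conservative: 0.08, feasible: 0.10, optimal: 0.12}
  hba1c_control_primary:
    category: primary
    effect: hba1c_control
    uptake: {baseline: 0.49, conservative: 0.54, feasible: 0.70, optimal: 0.80}
  smoking_cessation_primary:
    category: primary
    effect: smoking_cessation
    uptake: {baseline: 0.04, conservative: 0.07, feasible: 0.10, optimal: 0.13}
  warfarin_primary:
    category: primary
    effect: warfarin_primary
    uptake: {baseline: 0.30, conservative: 0.33, feasible: 0.50, optimal: 0.78}

policies:
  salt:
    effect: salt
    dose: {conservative: 1.0, feasible: 3.0, optimal: 5.0}
  transfat:
    effect: transfat
    dose: {conservative: 0.5, feasible: 1.0, optimal: 2.0}
  saturated_fat:
    effect: saturated_fat
    dose: {conservative: 1.0, feasible: 3.0, optimal: 5.0}
  fruit_veg:
    effect: fruit_veg
    dose: {conservative: 1.0, feasible: 2.0, optimal: 3.0}
  smoking_prevalence:
    effect: smoking_prevalence
    dose: {conservative: 5.0, feasible: 10.0, optimal: 15.0}
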