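# Relative risk reductions (RRR, with 95% CIs) for each intervention,
# drawn from the randomised trials and meta-analyses behind the model.
# Values are proportions (0.11 = 11%).  Some sources print internally
# inconsistent CI orderings; they are kept as printed here and normalised
# (sorted, widened to include the central value) only when a probability
# distribution is fitted for sensitivity analysis.
#
# scope:       which cause-specific transitions the effect touches
# half_effect: the RRR was quantified for coronary heart disease and is
#              applied to stroke at half strength
# reference_dose / dose_unit: exposure change at which the RRR applies
#              (policy effects only; treatment effects act per treated patient)

effects:
  # --- acute stroke treatments -------------------------------------------
  - name: thrombolysis
    kind: treatment
    rrr: 0.11
    ci: [0.05, 0.16]
    scope: stroke
    description: RRR for stroke death or dependency when given within 4.5 h
  - name: aspirin_acute
    kind: treatment
    rrr: 0.026
    ci: [0.004, 0.04]
    scope: stroke
    description: RRR for stroke death or dependency, 160-300 mg within 48 h of onset
  - name: stroke_unit
    kind: treatment
    rrr: 0.061
    ci: [0.000009, 0.11]
    scope: stroke
    description: RRR for stroke death or dependency with organised stroke-unit care

  # --- secondary prevention ----------------------------------------------
  - name: aspirin_secondary
    kind: treatment
    rrr: 0.03
    ci: [0.06, 0.19]        # printed bounds; inconsistent with central value
    scope: both
    description: RRR for vascular events (stroke or IHD death), any dose above 30 mg daily
  - name: statin_secondary
    kind: treatment
    rrr: 0.12
    ci: [-0.01, 0.21]
    scope: stroke
    description: RRR for recurrent stroke per 1 mmol/L LDL reduction
  - name: warfarin_secondary
    kind: treatment
    rrr: 0.61
    ci: [0.37, 0.75]
    scope: stroke
    description: RRR for recurrent stroke or systemic embolism in AF after TIA/minor stroke
  - name: bp_control_secondary
    kind: treatment
    rrr: 0.34
    ci: [0.21, 0.44]
    scope: stroke
    description: RRR for stroke with 4-25 mmHg systolic (3-13 diastolic) BP reduction
  - name: smoking_cessation
    kind: treatment
    rrr: 0.48
    ci: [0.29, 0.57]
    scope: stroke
    description: RRR for stroke death or dependency after smoking cessation

  # --- primary prevention -------------------------------------------------
  - name: bp_control_primary
    kind: treatment
    rrr: 0.46
    ci: [0.35, 0.55]
    scope: stroke
    description: RRR for stroke with a 5 mmHg BP reduction from any pre-treatment level
  - name: hba1c_control
    kind: treatment
    rrr: 0.07
    ci: [0.04, 0.19]
    scope: stroke
    description: RRR for stroke per 0.9% HbA1c reduction
  - name: warfarin_primary
    kind: treatment
    rrr: 0.64
    ci: [0.49, 0.74]
    scope: stroke
    description: RRR for stroke with adjusted-dose warfarin in atrial fibrillation

  # --- population-level policies ------------------------------------------
  - name: salt
    kind: policy
    rrr: 0.17
    ci: [0.06, 0.43]
    reference_dose: 5.0
    dose_unit: g/day
    scope: stroke
    half_effect: false
    description: RRR for stroke per 5 g/day change in dietary salt intake
  - name: transfat
    kind: policy
    rrr: 0.12
    ci: [0.055, 0.185]
    reference_dose: 1.0
    dose_unit: "% energy"
    scope: both
    half_effect: true
    description: >
      RRR for coronary heart disease when 1% of energy from trans-fat is
      replaced with unsaturated fats; half effect assumed for stroke
  - name: saturated_fat
    kind: policy
    rrr: 0.13
    ci: [0.01, 0.06]        # printed bounds; inconsistent with central value
    reference_dose: 5.0
    dose_unit: "% energy"
    scope: both
    half_effect: true
    description: >
      RRR for coronary heart disease when 5% of energy from saturated fat is
      replaced with polyunsaturates; half effect assumed for stroke
  - name: fruit_veg
    kind: policy
    rrr: 0.04
    ci: [0.03, 0.08]
    reference_dose: 1.0
    dose_unit: portion/day
    scope: stroke
    half_effect: false
    description: RRR for stroke per additional daily portion of fruit and vegetables
  - name: smoking_prevalence
    kind: policy
    rrr: 0.019
    ci: [0.015, 0.023]
    reference_dose: 1.0
    dose_unit: "% prevalence"
    scope: both
    half_effect: false
    description: RRR per 1% absolute reduction in population smoking prevalence
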