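"""Generate a synthetic national input bundle and inspect its structure.

The bundle bundles everything the model needs: an age-sex population table,
all-cause/CVD/IHD/stroke mortality rates, stroke prevalence, first-year case
fatality by severity, and baseline treatment uptakes.
"""

import strokesim as ss

bundle = ss.generate_bundle(seed=1)

print("population (head):")
print(bundle.population.head(4).to_string(index=False))
print(f"\ntotal population 35-94: {bundle.population['count'].sum():,}")

mort = bundle.mortality.set_index(["sex", "age_band"])
print("\nall-cause mortality per person-year (male):")
print(f"  35-39: {mort.loc[('male', '35-39'), 'all_cause_rate']:.4f}")
print(f"  90-94: {mort.loc[('male', '90-94'), 'all_cause_rate']:.4f}")

violations = ss.validate_bundle(bundle)
print(f"\nvalidation violations: {len(violations)}")
# Counts decline with age, rates rise with age, CVD deaths never exceed
# all-cause deaths -- the structural assumptions every downstream module
# relies on, checked here rather than assumed.
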