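"""Scenario machinery: dose scaling, uptake multipliers, DPP accounting."""

import math

import numpy as np
import pytest

import strokesim as ss
from strokesim.engine import S
from strokesim.scenarios import PolicyIntervention, Scenario, TreatmentIntervention


def _policy_effect(rrr=0.5, scope="stroke", half_effect=False, ref=1.0):
    return ss.EffectSize(
        name="test_policy",
        rrr=rrr,
        ci_low=rrr,
        ci_high=rrr,
        scope=scope,
        half_effect=half_effect,
        reference_dose=ref,
    )


class TestScaleRR:
    def test_reference_dose_returns_one_minus_rrr(self, effects):
        assert ss.scale_rr(effects["salt"], 5.0) == 1 - 0.17
        assert ss.scale_rr(effects["smoking_prevalence"], 1.0) == 1 - 0.019

    def test_zero_dose_is_null(self, effects):
        assert ss.scale_rr(effects["salt"], 0.0) == 1.0

    def test_partial_dose_log_linear(self, effects):
        got = ss.scale_rr(effects["salt"], 3.0)
        assert got == pytest.approx(math.exp((3 / 5) * math.log(0.83)), rel=1e-12)

    def test_half_effect_halves_stroke_rrr(self, effects):
        tf = effects["transfat"]
        assert ss.scale_rr(tf, tf.reference_dose, "stroke") == 1 - tf.rrr / 2
        assert ss.scale_rr(tf, tf.reference_dose, "ihd") == 1 - tf.rrr

    def test_bad_inputs_rejected(self, effects):
        with pytest.raises(ValueError):
            ss.scale_rr(effects["salt"], -1.0)
        no_ref = ss.EffectSize("x", 0.1, 0.1, 0.1, reference_dose=None)
        with pytest.raises(ValueError, match="reference dose"):
            ss.scale_rr(no_ref, 1.0)


class TestTreatmentMultiplier:
    def _iv(self, u0, u1, rrr, eligible=1.0):
        eff = ss.EffectSize("t", rrr, rrr, rrr, scope="stroke")
        return TreatmentIntervention("t", "acute", eff, u0, u1, eligible)

    def test_thrombolysis_feasible_arithmetic(self):
        got = ss.treatment_multiplier(self._iv(0.01, 0.05, 0.11))
        assert got == 1.0 - (0.05 - 0.01) * 1.0 * 0.11

    def test_null_cases(self):
        assert ss.treatment_multiplier(self._iv(0.3, 0.3, 0.5)) == 1.0
        assert ss.treatment_multiplier(self._iv(0.1, 0.9, 0.0)) == 1.0

    def test_implausible_multiplier_rejected(self):
        with pytest.raises(ValueError, match="implausible"):
            ss.treatment_multiplier(self._iv(0.0, 1.0, 1.2))


def test_combine_products():
    assert ss.combine([0.9, 0.8]) == pytest.approx(0.72, rel=1e-12)
    assert ss.combine([1.0, 1.0, 1.0]) == 1.0
    assert ss.combine([]) == 1.0
    with pytest.raises(ValueError):
        ss.combine([0.9, 0.0])


def test_combine_feasible_policies_against_log_sum_oracle(effects):
    scen = ss.build_scenario("policy_feasible", effects=effects)
    mults = [
        ss.scale_rr(iv.effect, iv.dose_change, "stroke")
        for iv in scen.policies
        if iv.effect.applies_to("stroke")
    ]
    assert ss.combine(mults) == pytest.approx(math.exp(sum(math.log(m) for m in mults)), rel=1e-12)


class TestApplyScenario:
    def test_baseline_leaves_tables_untouched(self, baseline_tts):
        out = ss.apply_scenario(baseline_tts, Scenario("baseline"))
        np.testing.assert_array_equal(out.probs, baseline_tts.probs)

    def test_single_policy_halves_entry_and_conserves_mass(self, baseline_tts):
        scen = Scenario("half", policies=[PolicyIntervention("p", _policy_effect(0.5), 1.0)])
        out = ss.apply_scenario(baseline_tts, scen)
        old = baseline_tts.probs[..., S["WELL"], :]
        new = out.probs[..., S["WELL"], :]
        np.testing.assert_allclose(
            new[..., S["ACUTE_MINOR"]], 0.5 * old[..., S["ACUTE_MINOR"]], rtol=1e-15
        )
        np.testing.assert_allclose(
            new[..., S["WELL"]] - old[..., S["WELL"]],
            0.5 * (old[..., S["ACUTE_MINOR"]] + old[..., S["ACUTE_MAJOR"]]),
            rtol=1e-9,
        )
        np.testing.assert_allclose(out.probs.sum(axis=3), 1.0, atol=1e-12)

    def test_feasible_policy_rows_remain_stochastic(self, baseline_tts, effects):
        scen = ss.build_scenario("policy_feasible", effects=effects)
        out = ss.apply_scenario(baseline_tts, scen)
        np.testing.assert_allclose(out.probs.sum(axis=3), 1.0, atol=1e-12)

    def test_stroke_only_effect_leaves_ihd_transitions_untouched(self, baseline_tts, effects):
        scen = Scenario(
            "fv", policies=[PolicyIntervention("fruit_veg", effects["fruit_veg"], 2.0)]
        )
        out = ss.apply_scenario(baseline_tts, scen)
        np.testing.assert_array_equal(
            out.probs[..., S["WELL"], S["DEAD_IHD"]],
            baseline_tts.probs[..., S["WELL"], S["DEAD_IHD"]],
        )
        assert np.all(
            out.probs[..., S["WELL"], S["ACUTE_MINOR"]]
            < baseline_tts.probs[..., S["WELL"], S["ACUTE_MINOR"]]
        )

    def test_half_effect_flag_changes_only_stroke_multipliers(self, effects):
        tf = effects["transfat"]
        with_half = Scenario("a", policies=[PolicyIntervention("tf", tf, 1.0)])
        import dataclasses

        no_half = Scenario(
            "b",
            policies=[
                PolicyIntervention("tf", dataclasses.replace(tf, half_effect=False), 1.0)
            ],
        )
        ma = ss.transition_multipliers(with_half)
        mb = ss.transition_multipliers(no_half)
        assert ma[S["WELL"], S["DEAD_IHD"]] == mb[S["WELL"], S["DEAD_IHD"]]
        assert ma[S["WELL"], S["ACUTE_MINOR"]] > mb[S["WELL"], S["ACUTE_MINOR"]]

    def test_overdriven_scenario_raises(self, baseline_tts):
        # a multiplier > 1 large enough to push ACUTE death probability past 1
        eff = ss.EffectSize("bad", -60.0, -60.0, -60.0, scope="stroke", reference_dose=1.0)
        scen = Scenario("bad", policies=[PolicyIntervention("bad", eff, 1.0)])
        with pytest.raises(ss.TransitionError):
            ss.apply_scenario(baseline_tts, scen)


class TestDPP:
    def test_baseline_dpp_is_exactly_zero(self, baseline_run):
        d = ss.compute_dpp(baseline_run, baseline_run, "baseline")
        assert d.dpp == {"total": 0.0, "male": 0.0, "female": 0.0}

    def test_maximal_effect_recovers_all_stroke_ihd_deaths(self, bundle, baseline_tts, baseline_run):
        blocked = baseline_tts.copy()
        p = blocked.probs
        for r in range(5):  # live states: zero every stroke/IHD death exit
            for c in (S["DEAD_STROKE"], S["DEAD_IHD"]):
                p[:, :, r, r] += p[:, :, r, c]
                p[:, :, r, c] = 0.0
        blocked.validate()
        occ0 = ss.initialize_cohort(bundle.population, bundle.prevalence)
        srun = ss.run(occ0, blocked, horizon=10)
        d = ss.compute_dpp(baseline_run, srun, "blocked")
        assert d.dpp["total"] == pytest.approx(
            baseline_run.cumulative_deaths(("stroke", "ihd")), rel=1e-12
        )
        assert d.percent_reduction["total"] == pytest.approx(100.0, rel=1e-12)

    def test_mismatched_horizons_rejected(self, bundle, baseline_tts, baseline_run):
        occ0 = ss.initialize_cohort(bundle.population, bundle.prevalence)
        r5 = ss.run(occ0, baseline_tts, horizon=5)
        with pytest.raises(ValueError, match="horizon"):
            ss.compute_dpp(baseline_run, r5)


class TestAttribution:
    def test_single_intervention_gets_full_share(self, bundle, effects):
        scen = Scenario(
            "solo", policies=[PolicyIntervention("salt", effects["salt"], 3.0)]
        )
        attr = ss.attribute(bundle, scen, horizon=10)
        assert list(attr) == ["salt"]
        assert attr["salt"]["share_pct"] == pytest.approx(100.0)

    def test_identical_interventions_split_evenly(self, bundle):
        eff = _policy_effect(0.2)
        scen = Scenario(
            "twin",
            policies=[
                PolicyIntervention("a", eff, 1.0),
                PolicyIntervention("b", eff, 1.0),
            ],
        )
        attr = ss.attribute(bundle, scen, horizon=10)
        assert attr["a"]["share_pct"] == pytest.approx(50.0, abs=1e-6)
        assert attr["b"]["share_pct"] == pytest.approx(50.0, abs=1e-6)

    def test_feasible_policy_shares_sum_to_100(self, bundle, effects):
        attr = ss.attribute(bundle, "policy_feasible", horizon=10, effects=effects)
        assert len(attr) == 5
        assert sum(v["share_pct"] for v in attr.values()) == pytest.approx(100.0, abs=1e-6)


def test_unknown_scenario_name_lists_valid_names():
    with pytest.raises(ValueError, match="baseline.*policy_optimal"):
        ss.build_scenario("nope")


def test_shipped_config_covers_all_interventions(effects):
    config = ss.load_scenario_config()
    assert len(config["treatments"]) == 12
    assert len(config["policies"]) == 5
    for spec in config["treatments"].values():
        assert spec["effect"] in effects
        u = spec["uptake"]
        assert u["baseline"] <= u["conservative"] <= u["feasible"] <= u["optimal"]
    for spec in config["policies"].values():
        d = spec["dose"]
        assert 0 < d["conservative"] <= d["feasible"] <= d["optimal"]
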