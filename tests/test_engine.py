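"""Markov engine: transition-table construction, stepping, cohort runs."""

import numpy as np
import pandas as pd
import pytest

import strokesim as ss
from strokesim.engine import N_STATES, S
from strokesim.tables import N_AGES, N_BANDS, frame_from_array


def _mortality_frame(all_cause=0.0, cvd=0.0, ihd=0.0, stroke=0.0):
    full = np.full((2, N_BANDS), float(all_cause))
    df = frame_from_array(full, "all_cause_rate")
    df["cvd_rate"] = cvd
    df["ihd_rate"] = ihd
    df["stroke_death_rate"] = stroke
    return df


def _cf_frame(minor=0.0, major=0.0):
    rows = []
    for sex in ss.SEXES:
        for band in ss.AGE_BANDS:
            rows.append({"sex": sex, "age_band": band, "severity": "minor", "first_year_cf": minor})
            rows.append({"sex": sex, "age_band": band, "severity": "major", "first_year_cf": major})
    return pd.DataFrame(rows)


def _incidence_frame(rate=0.0):
    return frame_from_array(np.full((2, N_BANDS), float(rate)), "incidence_rate")


def test_all_zero_rates_give_identity_up_to_acute_tunnel():
    """With every rate zero nobody moves — except that the acute states are
    one-year tunnel states whose survivors always continue to POST_STROKE."""
    tts = ss.build_transition_tables(_mortality_frame(), _incidence_frame(), _cf_frame())
    expected = np.zeros((N_STATES, N_STATES))
    np.fill_diagonal(expected, 1.0)
    for acute in ("ACUTE_MINOR", "ACUTE_MAJOR"):
        expected[S[acute], S[acute]] = 0.0
        expected[S[acute], S["POST_STROKE"]] = 1.0
    np.testing.assert_array_equal(
        tts.probs, np.broadcast_to(expected, tts.probs.shape)
    )


def test_single_exit_construction():
    tts = ss.build_transition_tables(
        _mortality_frame(all_cause=0.01, cvd=0.01, ihd=0.01),
        _incidence_frame(),
        _cf_frame(),
    )
    well = tts.probs[0, 0, S["WELL"]]
    assert well[S["WELL"]] == pytest.approx(0.99, abs=1e-15)
    assert well[S["DEAD_IHD"]] == 0.01
    assert well.sum() == pytest.approx(1.0, abs=1e-15)


def test_rows_sum_to_one_on_synthetic_bundle(baseline_tts):
    sums = baseline_tts.probs.sum(axis=3)
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)
    assert baseline_tts.probs.min() >= 0.0
    assert baseline_tts.probs.max() <= 1.0


def test_overflowing_exits_raise_naming_stratum():
    with pytest.raises(ss.TransitionError, match=r"exceed 1.*\(male, 35-39\)"):
        ss.build_transition_tables(
            _mortality_frame(all_cause=0.3, cvd=0.1, ihd=0.1, stroke=0.1),
            _incidence_frame(0.5),  # recurrence multiplier 2 -> POST exits exceed 1
            _cf_frame(),
        )


def test_initialize_cohort_excludes_prevalent_cases(bundle):
    pop = bundle.population.copy()
    prev = bundle.prevalence.copy()
    occ = ss.initialize_cohort(pop, prev)
    counts = pop.set_index(["sex", "age_band"])["count"]
    prevalence = prev.set_index(["sex", "age_band"])["stroke_prevalence"]
    # per-band WELL mass equals count * (1 - prevalence)
    band0 = occ[0, 0:5, S["WELL"]].sum()
    assert band0 == pytest.approx(
        counts[("male", "35-39")] * (1 - prevalence[("male", "35-39")]), rel=1e-12
    )
    assert occ[:, :, [s for s in range(N_STATES) if s != S["WELL"]]].sum() == 0.0
    expected_total = (counts * (1 - prevalence)).sum()
    assert occ.sum() == pytest.approx(expected_total, rel=1e-12)


def test_initialize_rejects_bad_prevalence(bundle):
    bad = bundle.prevalence.copy()
    bad.loc[0, "stroke_prevalence"] = 1.5
    with pytest.raises(ValueError):
        ss.initialize_cohort(bundle.population, bad)


def test_step_identity_and_split():
    occ = np.zeros(N_STATES)
    occ[S["WELL"]] = 100.0
    assert np.array_equal(ss.step(occ, np.eye(N_STATES)), occ)
    m = np.eye(N_STATES)
    m[S["WELL"], S["WELL"]] = 0.9
    m[S["WELL"], S["DEAD_OTHER"]] = 0.1
    out = ss.step(occ, m)
    assert out[S["WELL"]] == pytest.approx(90.0)
    assert out[S["DEAD_OTHER"]] == pytest.approx(10.0)
    assert out.sum() == pytest.approx(100.0, abs=1e-9)


def test_step_matches_double_loop_oracle():
    rng = np.random.default_rng(11)
    occ = rng.uniform(0, 100, N_STATES)
    m = rng.dirichlet(np.ones(N_STATES), size=N_STATES)
    got = ss.step(occ, m)
    oracle = np.zeros(N_STATES)
    for j in range(N_STATES):
        for i in range(N_STATES):
            oracle[j] += occ[i] * m[i, j]
    np.testing.assert_allclose(got, oracle, rtol=1e-12)


def test_step_rejects_non_stochastic_matrix():
    occ = np.ones(N_STATES)
    bad = np.eye(N_STATES) * 0.5
    with pytest.raises(ss.TransitionError):
        ss.step(occ, bad)


def test_zero_horizon_run(bundle, baseline_tts):
    occ0 = ss.initialize_cohort(bundle.population, bundle.prevalence)
    r = ss.run(occ0, baseline_tts, horizon=0)
    assert r.deaths.size == 0
    np.testing.assert_array_equal(r.final_occupancy, occ0)
    with pytest.raises(ValueError):
        ss.run(occ0, baseline_tts, horizon=-1)


def test_twenty_year_run_prefix_equals_ten_year_run(bundle, baseline_tts):
    occ0 = ss.initialize_cohort(bundle.population, bundle.prevalence)
    r10 = ss.run(occ0, baseline_tts, horizon=10)
    r20 = ss.run(occ0, baseline_tts, horizon=20)
    np.testing.assert_array_equal(r20.deaths[:10], r10.deaths)


def test_cumulative_deaths_monotone_in_time(baseline_run):
    for cause in ss.CAUSES:
        series = np.cumsum(baseline_run.deaths[..., ss.CAUSES.index(cause)].sum(axis=(1, 2)))
        assert np.all(np.diff(series) >= 0)


def test_conservation_and_aged_out(bundle, baseline_tts):
    occ0 = ss.initialize_cohort(bundle.population, bundle.prevalence)
    r = ss.run(occ0, baseline_tts, horizon=20)
    assert r.conservation_gap.max() <= 1e-9 * r.initial_total
    # over 20 years the oldest starters leave the modelled range alive or dead
    assert r.aged_out.sum() > 0
    # nobody younger than 55 remains: the youngest starters were 35
    assert r.final_occupancy[:, : 55 - 35, :].sum() == 0.0


def test_deaths_frame_shape(baseline_run):
    df = baseline_run.deaths_frame()
    assert list(df.columns) == ["year", "sex", "age_band", "cause", "deaths"]
    assert df["year"].min() == 2013 and df["year"].max() == 2022
    assert df["deaths"].sum() == pytest.approx(baseline_run.deaths.sum(), rel=1e-12)
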