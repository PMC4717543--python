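"""Synthetic, internally consistent input bundles.

The generator emulates the statistical shape of the national data the model
consumes — a middle-income population pyramid for ages 35-94, Gompertz-like
all-cause mortality, cardiovascular cause fractions, stroke prevalence rising
logistically with age, and first-year case fatality rising with age and
severity — without fitting any real country's marginals.  All randomness
flows through one `numpy.random.Generator` seeded explicitly, so a seed fully
determines the bundle down to the serialised bytes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (
    AGE_BANDS,
    Bundle,
    N_BANDS,
    SEXES,
    SEVERITIES,
    band_midpoints,
)

#: Baseline (2012) uptake proportions of the twelve medical therapies.
BASELINE_UPTAKES: dict[str, float] = {
    "thrombolysis": 0.01,
    "aspirin_acute": 0.50,
    "stroke_unit": 0.00,
    "aspirin_secondary": 0.26,
    "statin_secondary": 0.48,
    "warfarin_secondary": 0.14,
    "bp_control_secondary": 0.35,
    "smoking_cessation_secondary": 0.30,
    "bp_control_primary": 0.07,
    "hba1c_control_primary": 0.49,
    "smoking_cessation_primary": 0.04,
    "warfarin_primary": 0.30,
}


def default_uptakes() -> dict[str, float]:
    """Return the published baseline treatment uptake rates for 2012."""
    return dict(BASELINE_UPTAKES)


def generate_population(seed: int, scale: float = 1_000_000) -> pd.DataFrame:
    """Generate an age-sex population table with counts declining in age.

    Parameters
    ----------
    seed :
        Seed for the generator; identical seeds give identical tables.
    scale :
        Approximate total population over all 24 strata (persons).
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    rng = np.random.default_rng(seed)
    rows = []
    weights = np.empty((len(SEXES), N_BANDS))
    for i, sex in enumerate(SEXES):
        # Successive band ratios < 1 give a strictly declining pyramid.
        ratios = rng.uniform(0.70, 0.88, size=N_BANDS - 1)
        w = np.concatenate([[1.0], np.cumprod(ratios)])
        w *= 1.02 if sex == "male" else 0.98
        weights[i] = w
    weights *= scale / weights.sum()
    for i, sex in enumerate(SEXES):
        for j, band in enumerate(AGE_BANDS):
            rows.append({"sex": sex, "age_band": band, "count": int(round(weights[i, j]))})
    return pd.DataFrame(rows, columns=["sex", "age_band", "count"])


def generate_epi_bundle(
    seed: int, population: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate mortality, prevalence and case-fatality tables for a population.

    All-cause mortality follows a Gompertz hazard ``A * exp(b * (age - 37))``
    with a higher level for men; CVD, IHD and stroke deaths are fixed
    (age-increasing) fractions of it; ischemic stroke prevalence is logistic
    in age; first-year case fatality ramps up with age and is always higher
    for major than minor strokes.  Seed-level jitter perturbs the global
    parameters, never individual bands, so the monotone age gradients are
    preserved exactly.
    """
    if not isinstance(population, pd.DataFrame) or "count" not in population.columns:
        raise ValueError("population must be a PopulationTable DataFrame")
    rng = np.random.default_rng(seed)
    mids = band_midpoints()
    grid = np.arange(N_BANDS) / (N_BANDS - 1)  # 0 .. 1 across bands

    mort_rows, prev_rows, cf_rows = [], [], []
    for sex in SEXES:
        level = (0.0026 if sex == "male" else 0.0017) * rng.uniform(0.9, 1.1)
        slope = 0.085 * rng.uniform(0.97, 1.03)
        all_cause = level * np.exp(slope * (mids - mids[0]))

        # CVD share of all deaths rises with age; IHD and stroke split it.
        cvd_frac = (0.18 + 0.26 * grid) * rng.uniform(0.92, 1.08)
        ihd_share = rng.uniform(0.40, 0.48)
        stroke_share = rng.uniform(0.18, 0.25)
        cvd = all_cause * cvd_frac
        ihd = cvd * ihd_share
        stroke_death = cvd * stroke_share

        pmax = (0.055 if sex == "male" else 0.045) * rng.uniform(0.85, 1.15)
        centre = rng.uniform(68.0, 74.0)
        width = rng.uniform(8.0, 10.0)
        prevalence = pmax / (1.0 + np.exp(-(mids - centre) / width))

        cf_minor = (0.04 + 0.16 * grid) * rng.uniform(0.9, 1.1)
        cf_major = (0.20 + 0.32 * grid) * rng.uniform(0.9, 1.1)

        for j, band in enumerate(AGE_BANDS):
            mort_rows.append(
                {
                    "sex": sex,
                    "age_band": band,
                    "all_cause_rate": all_cause[j],
                    "cvd_rate": cvd[j],
                    "ihd_rate": ihd[j],
                    "stroke_death_rate": stroke_death[j],
                }
            )
            prev_rows.append(
                {"sex": sex, "age_band": band, "stroke_prevalence": prevalence[j]}
            )
            for severity, cf in zip(SEVERITIES, (cf_minor[j], cf_major[j])):
                cf_rows.append(
                    {
                        "sex": sex,
                        "age_band": band,
                        "severity": severity,
                        "first_year_cf": cf,
                    }
                )

    mortality = pd.DataFrame(mort_rows)
    prevalence = pd.DataFrame(prev_rows)
    case_fatality = pd.DataFrame(cf_rows)
    return mortality, prevalence, case_fatality


def generate_bundle(seed: int, scale: float = 1_000_000) -> Bundle:
    """Generate a complete input bundle (population + epidemiology + uptakes)."""
    pop = generate_population(seed, scale)
    mortality, prevalence, case_fatality = generate_epi_bundle(seed, pop)
    return Bundle(
        population=pop,
        mortality=mortality,
        prevalence=prevalence,
        case_fatality=case_fatality,
        uptakes=default_uptakes(),
    )


def write_fixture_bundle(path: str | Path, bundle: Bundle) -> None:
    """Write a bundle to five CSV files under ``path`` (must exist)."""
    bundle.to_dir(path)


def read_bundle(path: str | Path) -> Bundle:
    """Read a bundle previously written with :func:`write_fixture_bundle`."""
    return Bundle.from_dir(path)
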