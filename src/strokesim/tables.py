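"""Schemas and CSV I/O for the age-sex-stratified model input tables.

Every input is stratified by sex and 5-year age band from 35-39 through
90-94 (12 bands, 24 strata).  Tables are plain pandas DataFrames kept in a
canonical row order (male before female, bands ascending, ``minor`` before
``major``) so that serialisation is deterministic and tables can be compared
field-by-field after a round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

SEXES = ("male", "female")
AGE_BANDS = tuple(f"{lo}-{lo + 4}" for lo in range(35, 95, 5))
N_BANDS = len(AGE_BANDS)
AGE_MIN = 35
AGE_MAX = 94
N_AGES = AGE_MAX - AGE_MIN + 1
BAND_WIDTH = 5
SEVERITIES = ("minor", "major")

_SEX_INDEX = {s: i for i, s in enumerate(SEXES)}
_BAND_INDEX = {b: i for i, b in enumerate(AGE_BANDS)}
_SEVERITY_INDEX = {s: i for i, s in enumerate(SEVERITIES)}

POPULATION_COLUMNS = ("sex", "age_band", "count")
MORTALITY_COLUMNS = (
    "sex",
    "age_band",
    "all_cause_rate",
    "cvd_rate",
    "ihd_rate",
    "stroke_death_rate",
)
PREVALENCE_COLUMNS = ("sex", "age_band", "stroke_prevalence")
CASE_FATALITY_COLUMNS = ("sex", "age_band", "severity", "first_year_cf")
INCIDENCE_COLUMNS = ("sex", "age_band", "incidence_rate")

BUNDLE_FILES = {
    "population": "population.csv",
    "mortality": "mortality.csv",
    "prevalence": "prevalence.csv",
    "case_fatality": "case_fatality.csv",
    "uptakes": "uptakes.csv",
}


def sex_index(sex: str) -> int:
    try:
        return _SEX_INDEX[sex]
    except KeyError:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}") from None


def band_index(band: str) -> int:
    try:
        return _BAND_INDEX[band]
    except KeyError:
        raise ValueError(f"unknown age band {band!r}") from None


def band_of_age(age: int) -> str:
    """Return the 5-year band label containing a single year of age."""
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age {age} outside the modelled range {AGE_MIN}-{AGE_MAX}")
    return AGE_BANDS[(age - AGE_MIN) // BAND_WIDTH]


def band_midpoints() -> np.ndarray:
    """Midpoint age of every band (37, 42, ..., 92)."""
    return np.array([lo + 2 for lo in range(AGE_MIN, AGE_MAX, BAND_WIDTH)], dtype=float)


def canonical_order(df: pd.DataFrame) -> pd.DataFrame:
    """Sort a stratified table into the canonical row order."""
    keys = [df["sex"].map(_SEX_INDEX), df["age_band"].map(_BAND_INDEX)]
    if "severity" in df.columns:
        keys.append(df["severity"].map(_SEVERITY_INDEX))
    order = np.lexsort(tuple(reversed(keys)))
    return df.iloc[order].reset_index(drop=True)


def _check_strata(df: pd.DataFrame, name: str, with_severity: bool = False) -> None:
    expected = {(s, b) for s in SEXES for b in AGE_BANDS}
    if with_severity:
        expected = {(s, b, sv) for (s, b) in expected for sv in SEVERITIES}
        seen = set(zip(df["sex"], df["age_band"], df["severity"]))
    else:
        seen = set(zip(df["sex"], df["age_band"]))
    missing = expected - seen
    if missing:
        raise ValueError(f"{name}: missing strata {sorted(missing)[:4]}...")
    if len(df) != len(expected):
        raise ValueError(f"{name}: expected {len(expected)} rows, got {len(df)}")


def stratum_array(df: pd.DataFrame, value_col: str) -> np.ndarray:
    """Pivot a (sex, age_band) table into a (2, 12) array."""
    _check_strata(df, value_col)
    out = np.empty((len(SEXES), N_BANDS), dtype=float)
    si = df["sex"].map(_SEX_INDEX).to_numpy()
    bi = df["age_band"].map(_BAND_INDEX).to_numpy()
    out[si, bi] = df[value_col].to_numpy(dtype=float)
    return out


def case_fatality_array(df: pd.DataFrame) -> np.ndarray:
    """Pivot the case-fatality table into a (2, 12, 2) array (minor, major)."""
    _check_strata(df, "case_fatality", with_severity=True)
    out = np.empty((len(SEXES), N_BANDS, len(SEVERITIES)), dtype=float)
    si = df["sex"].map(_SEX_INDEX).to_numpy()
    bi = df["age_band"].map(_BAND_INDEX).to_numpy()
    vi = df["severity"].map(_SEVERITY_INDEX).to_numpy()
    out[si, bi, vi] = df["first_year_cf"].to_numpy(dtype=float)
    return out


def frame_from_array(values: np.ndarray, value_col: str) -> pd.DataFrame:
    """Inverse of :func:`stratum_array`: (2, 12) array -> canonical DataFrame."""
    rows = [
        {"sex": s, "age_band": b, value_col: values[i, j]}
        for i, s in enumerate(SEXES)
        for j, b in enumerate(AGE_BANDS)
    ]
    return pd.DataFrame(rows, columns=["sex", "age_band", value_col])


def read_table(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    """Read a stratified CSV, tolerating arbitrary column order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path)
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return canonical_order(df[list(columns)])


def write_table(df: pd.DataFrame, path: str | Path, columns: tuple[str, ...]) -> None:
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    canonical_order(df[list(columns)]).to_csv(path, index=False)


@dataclass
class Bundle:
    """A complete model input bundle.

    Attributes
    ----------
    population, mortality, prevalence, case_fatality :
        Stratified DataFrames following the documented CSV schemas.
    uptakes :
        Mapping treatment name -> baseline uptake proportion in 2012.
    """

    population: pd.DataFrame
    mortality: pd.DataFrame
    prevalence: pd.DataFrame
    case_fatality: pd.DataFrame
    uptakes: dict[str, float] = field(default_factory=dict)

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        if not path.is_dir():
            raise FileNotFoundError(f"bundle directory does not exist: {path}")
        write_table(self.population, path / BUNDLE_FILES["population"], POPULATION_COLUMNS)
        write_table(self.mortality, path / BUNDLE_FILES["mortality"], MORTALITY_COLUMNS)
        write_table(self.prevalence, path / BUNDLE_FILES["prevalence"], PREVALENCE_COLUMNS)
        write_table(
            self.case_fatality, path / BUNDLE_FILES["case_fatality"], CASE_FATALITY_COLUMNS
        )
        up = pd.DataFrame(
            sorted(self.uptakes.items()), columns=["treatment", "baseline_uptake"]
        )
        up.to_csv(path / BUNDLE_FILES["uptakes"], index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "Bundle":
        path = Path(path)
        up_path = path / BUNDLE_FILES["uptakes"]
        if not up_path.exists():
            raise FileNotFoundError(f"input table not found: {up_path}")
        up = pd.read_csv(up_path)
        return cls(
            population=read_table(path / BUNDLE_FILES["population"], POPULATION_COLUMNS),
            mortality=read_table(path / BUNDLE_FILES["mortality"], MORTALITY_COLUMNS),
            prevalence=read_table(path / BUNDLE_FILES["prevalence"], PREVALENCE_COLUMNS),
            case_fatality=read_table(
                path / BUNDLE_FILES["case_fatality"], CASE_FATALITY_COLUMNS
            ),
            uptakes=dict(zip(up["treatment"], up["baseline_uptake"].astype(float))),
        )
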