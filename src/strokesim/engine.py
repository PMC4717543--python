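"""Closed-cohort Markov engine over the ischemic stroke health-state graph.

The cohort is stroke-free at the 2012 start (prevalent cases are excluded
entirely) and moves between eight states in annual cycles:

    WELL -> TIA | ACUTE_MINOR | ACUTE_MAJOR | DEAD_IHD | DEAD_OTHER
    TIA  -> ACUTE_* (elevated risk) | DEAD_IHD | DEAD_OTHER
    ACUTE_* -> DEAD_STROKE (first-year case fatality) | DEAD_OTHER | POST_STROKE
    POST_STROKE -> ACUTE_* (recurrence) | DEAD_STROKE | DEAD_IHD | DEAD_OTHER

The three DEAD states are absorbing.  Transition probabilities are stratified
by sex and 5-year age band, but the engine tracks single-year-of-age cohorts
that look up their band's matrix, so cohorts age across band boundaries over
a 10- or 20-year horizon.  Persons who age past 94 leave the accounting as
"aged out".  No half-cycle correction is applied: outcomes are differences
between runs, which cancels most of that bias.

The exact arrow set of the published state diagram is not machine-readable
from the source text; this eight-state graph is a documented reconstruction
covering every state the model names (TIA, minor/major stroke, stroke death,
IHD death, other death).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (
    AGE_BANDS,
    AGE_MIN,
    BAND_WIDTH,
    N_AGES,
    N_BANDS,
    SEXES,
    case_fatality_array,
    stratum_array,
)

STATES = (
    "WELL",
    "TIA",
    "ACUTE_MINOR",
    "ACUTE_MAJOR",
    "POST_STROKE",
    "DEAD_STROKE",
    "DEAD_IHD",
    "DEAD_OTHER",
)
N_STATES = len(STATES)
S = {name: i for i, name in enumerate(STATES)}
LIVE_STATES = STATES[:5]
DEAD_STATES = STATES[5:]
_DEAD = slice(5, 8)
CAUSES = ("stroke", "ihd", "other")  # aligned with DEAD_STROKE, DEAD_IHD, DEAD_OTHER

_ROW_SUM_TOL = 1e-12


class TransitionError(ValueError):
    """A transition probability left [0, 1] or a row lost stochasticity."""


@dataclass
class EngineParams:
    """Tunable structural parameters of the state graph.

    The underlying sources do not quantify these; the defaults below are
    explicit modelling conventions, not published estimates.
    """

    severity_split_major: float = 0.5   # fraction of incident strokes that are major
    tia_incidence_ratio: float = 0.5    # TIA incidence as a multiple of stroke incidence
    tia_stroke_multiplier: float = 2.0  # stroke risk multiplier after TIA
    recurrence_multiplier: float = 2.0  # recurrent-stroke multiplier post stroke


@dataclass
class TransitionTables:
    """Per-stratum annual transition matrices, shape (2 sexes, 12 bands, 8, 8)."""

    probs: np.ndarray

    def matrix(self, sex: str, band: str) -> np.ndarray:
        return self.probs[SEXES.index(sex), AGE_BANDS.index(band)]

    def validate(self) -> None:
        p = self.probs
        if p.shape != (len(SEXES), N_BANDS, N_STATES, N_STATES):
            raise TransitionError(f"bad transition-table shape {p.shape}")
        if np.any(p < -1e-15) or np.any(p > 1 + 1e-15):
            raise TransitionError("transition probabilities outside [0, 1]")
        sums = p.sum(axis=3)
        if np.any(np.abs(sums - 1.0) > _ROW_SUM_TOL):
            si, bi, ri = np.unravel_index(np.argmax(np.abs(sums - 1.0)), sums.shape)
            raise TransitionError(
                f"row {STATES[ri]} of stratum ({SEXES[si]}, {AGE_BANDS[bi]}) "
                f"sums to {sums[si, bi, ri]!r}"
            )
        for d in range(5, 8):
            expected = np.zeros(N_STATES)
            expected[d] = 1.0
            if np.any(self.probs[:, :, d, :] != expected):
                raise TransitionError(f"{STATES[d]} must be absorbing")

    def copy(self) -> "TransitionTables":
        return TransitionTables(self.probs.copy())


def build_transition_tables(
    mortality: pd.DataFrame,
    incidence: pd.DataFrame,
    case_fatality: pd.DataFrame,
    params: EngineParams | None = None,
) -> TransitionTables:
    """Construct the per-stratum annual transition matrices.

    Row recipes (residual probability goes to the diagonal, so rows sum to
    one by construction):

    * WELL: exits to ACUTE_MINOR/MAJOR (incidence x severity split), TIA
      (``tia_incidence_ratio`` x incidence), DEAD_IHD (observed IHD rate) and
      DEAD_OTHER (all-cause minus CVD).
    * TIA: as WELL but stroke risk scaled by ``tia_stroke_multiplier`` and no
      further TIA exit.
    * ACUTE_*: DEAD_STROKE with the severity's first-year case fatality,
      DEAD_OTHER with the background non-CVD rate, remainder to POST_STROKE.
    * POST_STROKE: recurrence to ACUTE_* (``recurrence_multiplier`` x
      incidence), DEAD_STROKE (chronic excess = observed stroke death rate),
      DEAD_IHD, DEAD_OTHER.

    Letting WELL individuals die of IHD at the observed IHD rates is a
    deliberate choice: without it, IHD deaths (and hence IHD deaths averted
    by the dietary policies) would be structurally zero in this cohort.
    """
    params = params or EngineParams()
    all_cause = stratum_array(mortality, "all_cause_rate")
    cvd = stratum_array(mortality, "cvd_rate")
    ihd = stratum_array(mortality, "ihd_rate")
    stroke_death = stratum_array(mortality, "stroke_death_rate")
    inc = stratum_array(incidence, "incidence_rate")
    cf = case_fatality_array(case_fatality)  # (2, 12, [minor, major])

    non_cvd = all_cause - cvd
    if np.any(non_cvd < -1e-15):
        raise TransitionError("cvd_rate exceeds all_cause_rate in some stratum")
    non_cvd = np.clip(non_cvd, 0.0, None)

    split = params.severity_split_major
    if not 0.0 <= split <= 1.0:
        raise ValueError("severity_split_major must be in [0, 1]")

    probs = np.zeros((len(SEXES), N_BANDS, N_STATES, N_STATES))
    for si in range(len(SEXES)):
        for bi in range(N_BANDS):
            m = probs[si, bi]
            i0 = inc[si, bi]
            minor, major = i0 * (1 - split), i0 * split

            m[S["WELL"], S["TIA"]] = params.tia_incidence_ratio * i0
            m[S["WELL"], S["ACUTE_MINOR"]] = minor
            m[S["WELL"], S["ACUTE_MAJOR"]] = major
            m[S["WELL"], S["DEAD_IHD"]] = ihd[si, bi]
            m[S["WELL"], S["DEAD_OTHER"]] = non_cvd[si, bi]

            k = params.tia_stroke_multiplier
            m[S["TIA"], S["ACUTE_MINOR"]] = k * minor
            m[S["TIA"], S["ACUTE_MAJOR"]] = k * major
            m[S["TIA"], S["DEAD_IHD"]] = ihd[si, bi]
            m[S["TIA"], S["DEAD_OTHER"]] = non_cvd[si, bi]

            for state, sv in (("ACUTE_MINOR", 0), ("ACUTE_MAJOR", 1)):
                m[S[state], S["DEAD_STROKE"]] = cf[si, bi, sv]
                m[S[state], S["DEAD_OTHER"]] = non_cvd[si, bi]
                rest = 1.0 - m[S[state]].sum()
                m[S[state], S["POST_STROKE"]] = rest

            r = params.recurrence_multiplier
            m[S["POST_STROKE"], S["ACUTE_MINOR"]] = r * minor
            m[S["POST_STROKE"], S["ACUTE_MAJOR"]] = r * major
            m[S["POST_STROKE"], S["DEAD_STROKE"]] = stroke_death[si, bi]
            m[S["POST_STROKE"], S["DEAD_IHD"]] = ihd[si, bi]
            m[S["POST_STROKE"], S["DEAD_OTHER"]] = non_cvd[si, bi]

            for d in DEAD_STATES:
                m[S[d], S[d]] = 1.0

            for row in ("WELL", "TIA", "POST_STROKE"):
                ri = S[row]
                residual = 1.0 - m[ri].sum()
                if residual < -1e-12:
                    raise TransitionError(
                        f"exits from {row} exceed 1 by {-residual:.3e} in stratum "
                        f"({SEXES[si]}, {AGE_BANDS[bi]})"
                    )
                m[ri, ri] = max(residual, 0.0)
            for state in ("ACUTE_MINOR", "ACUTE_MAJOR"):
                if m[S[state], S["POST_STROKE"]] < -1e-12:
                    raise TransitionError(
                        f"exits from {state} exceed 1 in stratum "
                        f"({SEXES[si]}, {AGE_BANDS[bi]})"
                    )
                m[S[state], S["POST_STROKE"]] = max(m[S[state], S["POST_STROKE"]], 0.0)

    tts = TransitionTables(probs)
    tts.validate()
    return tts


def initialize_cohort(population: pd.DataFrame, prevalence: pd.DataFrame) -> np.ndarray:
    """Occupancy array (2 sexes, 60 ages, 8 states) for the stroke-free cohort.

    Per stratum, ``count x (1 - prevalence)`` persons start in WELL; the
    prevalent cases are excluded from the cohort entirely.  Band counts are
    spread uniformly across the band's five single years of age.
    """
    counts = stratum_array(population, "count")
    if np.any(counts < 0):
        raise ValueError("population counts must be non-negative")
    prev = stratum_array(prevalence, "stroke_prevalence")
    if np.any(prev < 0) or np.any(prev > 1):
        raise ValueError("prevalence must lie in [0, 1]")
    occ = np.zeros((len(SEXES), N_AGES, N_STATES))
    well = counts * (1.0 - prev) / BAND_WIDTH  # persons per single year of age
    band_of = np.arange(N_AGES) // BAND_WIDTH
    occ[:, :, S["WELL"]] = well[:, band_of]
    return occ


def step(occupancy: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """One annual transition of a single cohort's occupancy vector."""
    occupancy = np.asarray(occupancy, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if occupancy.shape != (N_STATES,) or matrix.shape != (N_STATES, N_STATES):
        raise ValueError("occupancy must be (8,), matrix (8, 8)")
    if np.any(occupancy < 0):
        raise ValueError("occupancy must be non-negative")
    if np.any(matrix < 0) or np.any(matrix > 1) or np.any(
        np.abs(matrix.sum(axis=1) - 1.0) > 1e-9
    ):
        raise TransitionError("matrix is not row-stochastic")
    return occupancy @ matrix


@dataclass
class CohortRun:
    """Result of simulating the closed cohort over a fixed horizon.

    ``deaths`` has shape (horizon, 2 sexes, 12 bands, 3 causes) with causes
    ordered (stroke, ihd, other); index ``t`` holds the deaths that occurred
    during calendar year ``start_year + t`` -> ``start_year + t + 1``.
    """

    start_year: int
    horizon: int
    deaths: np.ndarray
    aged_out: np.ndarray          # per sex
    initial_total: float
    final_occupancy: np.ndarray   # (2, 60, 8); dead states zeroed
    conservation_gap: np.ndarray  # per cycle |occupancy + deaths + aged_out - initial|

    def cumulative_deaths(
        self,
        causes: tuple[str, ...] = ("stroke", "ihd"),
        sex: str | None = None,
        through: int | None = None,
    ) -> float:
        """Total deaths from the given causes over the first ``through`` cycles."""
        ci = [CAUSES.index(c) for c in causes]
        t = self.horizon if through is None else through
        d = self.deaths[:t][..., ci]
        if sex is not None:
            d = d[:, SEXES.index(sex)]
        return float(d.sum())

    def deaths_frame(self) -> pd.DataFrame:
        """Tidy deaths table: year, sex, age_band, cause, deaths."""
        rows = []
        for t in range(self.horizon):
            for si, sex in enumerate(SEXES):
                for bi, band in enumerate(AGE_BANDS):
                    for ci, cause in enumerate(CAUSES):
                        rows.append(
                            {
                                "year": self.start_year + t + 1,
                                "sex": sex,
                                "age_band": band,
                                "cause": cause,
                                "deaths": self.deaths[t, si, bi, ci],
                            }
                        )
        return pd.DataFrame(rows, columns=["year", "sex", "age_band", "cause", "deaths"])

    def occupancy_frame(self) -> pd.DataFrame:
        rows = []
        for si, sex in enumerate(SEXES):
            for a in range(N_AGES):
                for st, state in enumerate(STATES):
                    v = self.final_occupancy[si, a, st]
                    if v != 0.0:
                        rows.append(
                            {"sex": sex, "age": AGE_MIN + a, "state": state, "persons": v}
                        )
        return pd.DataFrame(rows, columns=["sex", "age", "state", "persons"])


def run(
    occupancy0: np.ndarray,
    tts: TransitionTables,
    horizon: int,
    start_year: int = 2012,
) -> CohortRun:
    """Iterate annual transitions over all single-year-of-age cohorts.

    Each cycle: every cohort transitions through its band's matrix, inflows
    to the DEAD states are tallied by (year, sex, band, cause) and removed,
    then everyone ages one year; survivors passing age 94 exit as aged-out.
    """
    if horizon < 0:
        raise ValueError(f"horizon must be non-negative, got {horizon}")
    occ = np.asarray(occupancy0, dtype=float).copy()
    if occ.shape != (len(SEXES), N_AGES, N_STATES):
        raise ValueError(f"occupancy must have shape (2, {N_AGES}, {N_STATES})")
    if np.any(occ[:, :, _DEAD] != 0.0):
        raise ValueError("initial occupancy must be empty in the DEAD states")
    tts.validate()

    band_of = np.arange(N_AGES) // BAND_WIDTH
    mats = tts.probs[:, band_of]  # (2, 60, 8, 8)
    deaths = np.zeros((horizon, len(SEXES), N_BANDS, len(CAUSES)))
    aged_out = np.zeros(len(SEXES))
    gaps = np.zeros(horizon)
    initial_total = occ.sum()

    for t in range(horizon):
        new = np.einsum("sai,saij->saj", occ, mats)
        dead_inflow = new[:, :, _DEAD]  # (2, 60, 3); old dead occupancy is zero
        deaths[t] = dead_inflow.reshape(len(SEXES), N_BANDS, BAND_WIDTH, len(CAUSES)).sum(
            axis=2
        )
        new[:, :, _DEAD] = 0.0
        aged_out += new[:, -1, :].sum(axis=1)
        shifted = np.zeros_like(new)
        shifted[:, 1:, :] = new[:, :-1, :]
        occ = shifted
        gaps[t] = abs(occ.sum() + deaths[: t + 1].sum() + aged_out.sum() - initial_total)

    return CohortRun(
        start_year=start_year,
        horizon=horizon,
        deaths=deaths,
        aged_out=aged_out,
        initial_total=initial_total,
        final_occupancy=occ,
        conservation_gap=gaps,
    )
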