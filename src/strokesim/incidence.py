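"""Back-calculation of first-ever stroke incidence from prevalence and mortality.

A discrete illness-death model with zero remission links the observed
age profile of stroke prevalence to the incidence among the stroke-free:
within each 5-year band, susceptibles leave by incidence ``i`` or background
mortality ``m``, and the diseased die at ``m + e`` where ``e`` is the excess
(cause-related) hazard.  With rates held constant over a band the system has
a closed form, so prevalence at the start of band ``b+1`` is an explicit,
strictly increasing function of the band-``b`` incidence.  Inverting that
function band by band with 1-D root finding recovers the incidence profile
that exactly reproduces the observed prevalence — the same inputs and zero
remission assumption as the classic epidemiological back-calculation tools,
without an external incidence prior.

Remission is structurally zero: no function here accepts a remission rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .tables import (
    AGE_BANDS,
    BAND_WIDTH,
    N_BANDS,
    SEXES,
    case_fatality_array,
    frame_from_array,
    stratum_array,
)

_RESIDUAL_TOL = 1e-8
_MAX_INCIDENCE = 1e3  # upper bracket for root expansion; far above any plausible rate


def excess_mortality(
    case_fatality: pd.DataFrame, severity_split_major: float = 0.5
) -> pd.DataFrame:
    """Annual excess mortality hazard of the diseased, from first-year case fatality.

    The severity-mixed first-year case fatality ``cf`` is converted to a
    hazard via ``e = -ln(1 - cf)`` (constant-hazard convention over one year).

    Parameters
    ----------
    severity_split_major :
        Fraction of incident strokes that are major (the published sources do
        not state this split; 0.5 by default).
    """
    if not 0.0 <= severity_split_major <= 1.0:
        raise ValueError("severity_split_major must be in [0, 1]")
    cf = case_fatality_array(case_fatality)  # (2, 12, [minor, major])
    mixed = (1.0 - severity_split_major) * cf[..., 0] + severity_split_major * cf[..., 1]
    if np.any(mixed < 0) or np.any(mixed >= 1):
        raise ValueError("case fatality must lie in [0, 1)")
    return frame_from_array(-np.log1p(-mixed), "excess_rate")


def _band_forward(p0: float, i: float, m: float, e: float, width: float = BAND_WIDTH) -> float:
    """Prevalence at the end of one band given start prevalence and rates."""
    s0, c0 = 1.0 - p0, p0
    k1 = i + m            # susceptible exit rate
    k2 = m + e            # diseased exit rate
    s1 = s0 * np.exp(-k1 * width)
    if abs(k2 - k1) < 1e-12:
        transfer = i * s0 * width * np.exp(-k1 * width)
    else:
        transfer = i * s0 * (np.exp(-k1 * width) - np.exp(-k2 * width)) / (k2 - k1)
    c1 = c0 * np.exp(-k2 * width) + transfer
    total = s1 + c1
    if total <= 0:
        return 1.0
    return c1 / total


def forward_prevalence(
    incidence: pd.DataFrame,
    mortality: pd.DataFrame,
    excess: pd.DataFrame,
    boundary_prevalence: dict[str, float] | float = 0.0,
) -> pd.DataFrame:
    """Push an incidence table through the illness-death model.

    Returns the PrevalenceTable implied by the given incidence, background
    mortality (all-cause) and excess mortality of the diseased, with the
    prevalence of the first band fixed as a boundary condition.
    """
    inc = stratum_array(incidence, "incidence_rate")
    mort = stratum_array(mortality, "all_cause_rate")
    exc = stratum_array(excess, "excess_rate")
    for name, arr in (("incidence", inc), ("mortality", mort), ("excess", exc)):
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} rates must be finite and non-negative")
    out = np.empty((len(SEXES), N_BANDS))
    for si, sex in enumerate(SEXES):
        p = (
            boundary_prevalence.get(sex, 0.0)
            if isinstance(boundary_prevalence, dict)
            else float(boundary_prevalence)
        )
        if not 0.0 <= p < 1.0:
            raise ValueError(f"boundary prevalence for {sex} must be in [0, 1)")
        out[si, 0] = p
        for b in range(N_BANDS - 1):
            p = _band_forward(p, inc[si, b], mort[si, b], exc[si, b])
            out[si, b + 1] = p
    return frame_from_array(out, "stroke_prevalence")


def estimate_incidence(
    prevalence: pd.DataFrame,
    mortality: pd.DataFrame,
    excess: pd.DataFrame,
    initial_guess: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Recover the incidence table that reproduces an observed prevalence profile.

    Solved sequentially: the incidence of band ``b`` is the root of the
    band-``b`` forward map hitting the observed prevalence of band ``b+1``.
    When even zero incidence overshoots the target (prevalence falling faster
    than differential mortality explains), the rate is floored at zero and
    flagged in the ``floored`` column.  The last band's incidence is not
    identified by any prevalence transition and copies the preceding band.

    ``initial_guess`` is accepted for interface compatibility but carries no
    statistical weight: the root is bracketed and solved exactly regardless.

    Returns a DataFrame with columns sex, age_band, incidence_rate, floored.
    """
    prev = stratum_array(prevalence, "stroke_prevalence")
    mort = stratum_array(mortality, "all_cause_rate")
    exc = stratum_array(excess, "excess_rate")
    if np.any(prev < 0) or np.any(prev >= 1):
        raise ValueError("prevalence must lie in [0, 1)")
    if np.any(mort < 0) or np.any(exc < 0):
        raise ValueError("rates must be non-negative")

    inc = np.zeros((len(SEXES), N_BANDS))
    floored = np.zeros((len(SEXES), N_BANDS), dtype=bool)
    for si in range(len(SEXES)):
        for b in range(N_BANDS - 1):
            target = prev[si, b + 1]
            m, e, p0 = mort[si, b], exc[si, b], prev[si, b]

            def g(i: float) -> float:
                return _band_forward(p0, i, m, e) - target

            g0 = g(0.0)
            if g0 >= 0.0:
                # Zero incidence already meets or overshoots the target:
                # no non-negative solution (unless exactly at the root).
                inc[si, b] = 0.0
                floored[si, b] = abs(g0) > _RESIDUAL_TOL
                continue
            hi = 0.01
            while g(hi) < 0.0 and hi < _MAX_INCIDENCE:
                hi *= 2.0
            inc[si, b] = brentq(g, 0.0, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
            if abs(g(inc[si, b])) > _RESIDUAL_TOL:
                raise RuntimeError(
                    f"incidence inversion failed to converge for "
                    f"({SEXES[si]}, {AGE_BANDS[b]})"
                )
        inc[si, N_BANDS - 1] = inc[si, N_BANDS - 2]
    out = frame_from_array(inc, "incidence_rate")
    out["floored"] = floored.reshape(-1)
    return out


def estimate_from_bundle(bundle, severity_split_major: float = 0.5) -> pd.DataFrame:
    """Convenience: derive excess mortality from the bundle's case fatality
    and invert the bundle's prevalence profile."""
    exc = excess_mortality(bundle.case_fatality, severity_split_major)
    return estimate_incidence(bundle.prevalence, bundle.mortality, exc)
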