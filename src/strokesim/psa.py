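"""Probabilistic sensitivity analysis.

Model parameters are drawn independently from distributions fitted to their
central values and 95% confidence intervals — beta for proportions, lognormal
for risk ratios (the usual convention when the source reports an RRR with a
CI) — and the full baseline-versus-scenario pair is rerun for every draw.
The 95% uncertainty interval (UI) is the empirical 2.5th-97.5th percentile
range of the resulting deaths-prevented-or-postponed draws; the min-max range
over draws is reported alongside, labelled distinctly, because published
scenario tables sometimes print one and sometimes the other.

A printed CI that does not bracket its central value is normalised before
fitting (bounds sorted, then widened just enough to include the central
value) with a logged warning — the printed numbers are never silently
replaced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .engine import EngineParams, TransitionError
from .incidence import estimate_from_bundle
from .scenarios import (
    DPPResult,
    EffectSize,
    Scenario,
    build_scenario,
    compute_dpp,
    run_scenario,
)
from .tables import Bundle

logger = logging.getLogger(__name__)

_Z95 = 3.92  # width of a 95% interval in standard deviations


@dataclass(frozen=True)
class PointMass:
    """Degenerate distribution; used when a CI has zero width."""

    value: float

    def sample(self, rng: np.random.Generator) -> float:
        return self.value

    @property
    def mean(self) -> float:
        return self.value


@dataclass(frozen=True)
class BetaDistribution:
    alpha: float
    beta: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.alpha, self.beta))

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))


@dataclass(frozen=True)
class LogNormalRR:
    """Lognormal on a risk ratio; ``exp(mu)`` is the median risk ratio."""

    mu: float
    sigma: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.lognormal(self.mu, self.sigma))

    @property
    def median(self) -> float:
        return math.exp(self.mu)


def beta_from_mean_ci(mean: float, ci_low: float, ci_high: float):
    """Method-of-moments beta fit from a mean and 95% CI.

    The CI width is mapped to a standard deviation via sigma = width / 3.92.
    Returns a :class:`PointMass` when the width is zero.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    lo, hi = sorted((ci_low, ci_high))
    lo, hi = min(lo, mean), max(hi, mean)
    sigma = (hi - lo) / _Z95
    if sigma == 0.0:
        return PointMass(mean)
    var = sigma**2
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"no valid beta distribution: variance {var:.4g} >= "
            f"mean(1-mean) = {mean * (1 - mean):.4g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return BetaDistribution(alpha=mean * nu, beta=(1.0 - mean) * nu)


def normalize_rrr_ci(rrr: float, ci_low: float, ci_high: float, name: str = "") -> tuple[float, float]:
    """Sort printed CI bounds and widen them to include the central RRR."""
    lo, hi = sorted((ci_low, ci_high))
    if not lo <= rrr <= hi:
        logger.warning(
            "CI (%g, %g) for %s does not bracket central RRR %g; widening",
            ci_low, ci_high, name or "effect", rrr,
        )
        lo, hi = min(lo, rrr), max(hi, rrr)
    return lo, hi


def lognormal_from_rr_ci(rrr: float, ci_low: float, ci_high: float, name: str = ""):
    """Lognormal fit for the risk ratio implied by an RRR with 95% CI.

    The RRR bounds are converted to risk ratios (1 - RRR); the lognormal
    median equals the central risk ratio and the log-scale sigma spans the
    CI width over 3.92.  Returns a :class:`PointMass` at zero width.
    """
    lo, hi = normalize_rrr_ci(rrr, ci_low, ci_high, name)
    for v, label in ((rrr, "rrr"), (hi, "ci bound")):
        if 1.0 - v <= 0.0:
            raise ValueError(f"{label} {v} implies a non-positive risk ratio")
    mu = math.log1p(-rrr)
    sigma = (math.log1p(-lo) - math.log1p(-hi)) / _Z95
    if sigma == 0.0:
        return PointMass(1.0 - rrr)
    return LogNormalRR(mu=mu, sigma=sigma)


def default_effect_distributions(
    effects: Mapping[str, EffectSize],
) -> dict[str, object]:
    """Lognormal risk-ratio distribution per effect, from its printed CI."""
    return {
        name: lognormal_from_rr_ci(e.rrr, e.ci_low, e.ci_high, name)
        for name, e in effects.items()
    }


@dataclass
class PsaResult:
    """PSA summary for one scenario and horizon.

    ``ui_low``/``ui_high`` are the empirical 2.5/97.5 percentiles of the DPP
    draws (the 95% UI); ``minimum``/``maximum`` are the min-max range over
    draws, which is a different, wider summary.
    """

    scenario: str
    horizon: int
    point: DPPResult
    draws: np.ndarray            # (n_draws,) total DPP
    draws_by_sex: np.ndarray     # (n_draws, 2)
    ui_low: float
    ui_high: float
    minimum: float
    maximum: float
    n_draws: int
    seed: int
    n_rejected: int

    def contains_point(self) -> bool:
        return self.ui_low <= self.point.dpp["total"] <= self.ui_high


def _scenario_with_drawn_effects(
    scenario: Scenario, drawn_rrr: Mapping[str, float]
) -> Scenario:
    treatments = [
        replace(iv, effect=replace(iv.effect, rrr=drawn_rrr.get(iv.effect.name, iv.effect.rrr)))
        for iv in scenario.treatments
    ]
    policies = [
        replace(iv, effect=replace(iv.effect, rrr=drawn_rrr.get(iv.effect.name, iv.effect.rrr)))
        for iv in scenario.policies
    ]
    return Scenario(scenario.name, treatments=treatments, policies=policies)


def run_psa(
    bundle: Bundle,
    scenario: Scenario | str,
    horizon: int,
    n_draws: int = 1000,
    seed: int = 0,
    distributions: Mapping[str, object] | None = None,
    params: EngineParams | None = None,
    effects: Mapping[str, EffectSize] | None = None,
) -> PsaResult:
    """Propagate effect-size uncertainty through the full model.

    Per draw, every distributed parameter is redrawn independently, the
    baseline and scenario runs are both recomputed, and the DPP recorded.
    Draws whose parameters produce an invalid transition table are rejected
    and redrawn (logged); more than 10% rejections aborts with diagnostics.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    params = params or EngineParams()
    if isinstance(scenario, str):
        scenario = build_scenario(scenario, effects=effects)
    if distributions is None:
        used = {
            iv.effect.name: iv.effect for iv in scenario.interventions
        }
        distributions = default_effect_distributions(used)

    rng = np.random.default_rng(seed)
    inc = estimate_from_bundle(bundle, params.severity_split_major)
    base_run = run_scenario(bundle, Scenario("baseline"), horizon, params, inc)
    scen_run = run_scenario(bundle, scenario, horizon, params, inc)
    point = compute_dpp(base_run, scen_run, scenario.name)

    draws = np.empty(n_draws)
    draws_by_sex = np.empty((n_draws, 2))
    n_rejected = 0
    accepted = 0
    max_rejections = max(20, int(0.1 * n_draws))
    central_rrr = {iv.effect.name: iv.effect.rrr for iv in scenario.interventions}
    while accepted < n_draws:
        drawn_rrr = {}
        for name, dist in distributions.items():
            # A point mass at the central risk ratio is the degenerate case:
            # keep the central RRR bit-for-bit rather than round-tripping it
            # through 1 - (1 - rrr).
            if isinstance(dist, PointMass) and name in central_rrr and math.isclose(
                dist.value, 1.0 - central_rrr[name], rel_tol=1e-12
            ):
                continue
            drawn_rrr[name] = 1.0 - dist.sample(rng)
        try:
            scen_d = _scenario_with_drawn_effects(scenario, drawn_rrr)
            b = run_scenario(bundle, Scenario("baseline"), horizon, params, inc)
            s = run_scenario(bundle, scen_d, horizon, params, inc)
            d = compute_dpp(b, s, scenario.name)
        except (TransitionError, ValueError):
            n_rejected += 1
            if n_rejected > max_rejections:
                raise RuntimeError(
                    f"PSA aborted: {n_rejected} rejected draws against "
                    f"{accepted} accepted (>10% rejection rate); the drawn "
                    f"effect sizes repeatedly produced invalid transition tables"
                )
            continue
        draws[accepted] = d.dpp["total"]
        draws_by_sex[accepted, 0] = d.dpp["male"]
        draws_by_sex[accepted, 1] = d.dpp["female"]
        accepted += 1
    if n_rejected:
        logger.info("PSA rejected and redrew %d invalid draws", n_rejected)

    lo, hi = np.percentile(draws, [2.5, 97.5])
    return PsaResult(
        scenario=scenario.name,
        horizon=horizon,
        point=point,
        draws=draws,
        draws_by_sex=draws_by_sex,
        ui_low=float(lo),
        ui_high=float(hi),
        minimum=float(draws.min()),
        maximum=float(draws.max()),
        n_draws=n_draws,
        seed=seed,
        n_rejected=n_rejected,
    )
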