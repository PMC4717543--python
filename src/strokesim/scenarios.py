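"""Policy scenarios: effect sizes, transition-probability multipliers, DPPs.

Seven named scenarios are built in: a do-nothing baseline, three medical
treatment scenarios (conservative / feasible / optimal uptake targets for
twelve therapies) and three population-level policy scenarios (dose changes
in salt, trans-fat, saturated fat, fruit & vegetables and smoking
prevalence).  Each intervention becomes a multiplicative modification of
specific transition probabilities:

* a treatment with uptake rising from u0 to u1 scales its target
  transitions by ``1 - (u1 - u0) * eligible_fraction * RRR`` (the classic
  uptake-increment effectiveness calculation);
* a policy with dose change d scales them by ``exp((d / d_ref) * ln(1 - RRR))``
  — log-linear dose scaling, which stays positive at any dose and makes
  repeated doses multiply;
* effects quantified for coronary heart disease with "half effect" assumed
  for stroke halve the RRR (not the log risk ratio) on stroke-scoped
  transitions;
* independent interventions combine by multiplying their risk ratios.

Deaths prevented or postponed (DPP) are the difference in cumulative
stroke + IHD deaths between the baseline run and a scenario run over the
same cohort and horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .engine import (
    CohortRun,
    EngineParams,
    N_STATES,
    S,
    TransitionError,
    TransitionTables,
    build_transition_tables,
    initialize_cohort,
    run,
)
from .incidence import estimate_from_bundle
from .tables import AGE_BANDS, SEXES, Bundle

SCENARIO_NAMES = (
    "baseline",
    "treatment_conservative",
    "treatment_feasible",
    "treatment_optimal",
    "policy_conservative",
    "policy_feasible",
    "policy_optimal",
)
_LEVELS = ("conservative", "feasible", "optimal")
CATEGORIES = ("acute", "secondary", "primary")


@dataclass(frozen=True)
class EffectSize:
    """A relative risk reduction with its 95% CI and application rules."""

    name: str
    rrr: float
    ci_low: float
    ci_high: float
    scope: str = "stroke"            # stroke | ihd | both
    half_effect: bool = False        # halve RRR on stroke-scoped transitions
    reference_dose: float | None = None
    dose_unit: str = ""
    description: str = ""

    def applies_to(self, outcome: str) -> bool:
        return self.scope == "both" or self.scope == outcome


@dataclass(frozen=True)
class TreatmentIntervention:
    name: str
    category: str                    # acute | secondary | primary
    effect: EffectSize
    baseline_uptake: float
    scenario_uptake: float
    eligible_fraction: float = 1.0


@dataclass(frozen=True)
class PolicyIntervention:
    name: str
    effect: EffectSize
    dose_change: float


@dataclass
class Scenario:
    name: str
    treatments: list[TreatmentIntervention] = field(default_factory=list)
    policies: list[PolicyIntervention] = field(default_factory=list)

    @property
    def interventions(self) -> list:
        return list(self.treatments) + list(self.policies)


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("strokesim").joinpath("data", filename)))


def load_effects(path: str | Path | None = None) -> dict[str, EffectSize]:
    """Load effect sizes from YAML (the shipped defaults when no path given)."""
    path = _data_path("effects.yaml") if path is None else Path(path)
    raw = yaml.safe_load(path.read_text())
    effects = {}
    for entry in raw["effects"]:
        ci = entry.get("ci", [entry["rrr"], entry["rrr"]])
        effects[entry["name"]] = EffectSize(
            name=entry["name"],
            rrr=float(entry["rrr"]),
            ci_low=float(ci[0]),
            ci_high=float(ci[1]),
            scope=entry.get("scope", "stroke"),
            half_effect=bool(entry.get("half_effect", False)),
            reference_dose=(
                float(entry["reference_dose"]) if "reference_dose" in entry else None
            ),
            dose_unit=entry.get("dose_unit", ""),
            description=entry.get("description", "").strip(),
        )
    return effects


def load_scenario_config(path: str | Path | None = None) -> dict:
    """Load the scenario definition YAML (uptake targets and policy doses)."""
    path = _data_path("scenarios.yaml") if path is None else Path(path)
    return yaml.safe_load(path.read_text())


def build_scenario(
    name: str,
    effects: Mapping[str, EffectSize] | None = None,
    config: dict | None = None,
    eligible_fractions: Mapping[str, float] | None = None,
) -> Scenario:
    """Construct one of the named scenarios from the configuration tables."""
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    effects = effects or load_effects()
    config = config or load_scenario_config()
    eligible_fractions = eligible_fractions or {}
    if name == "baseline":
        return Scenario("baseline")
    family, level = name.split("_", 1)
    if family == "treatment":
        treatments = [
            TreatmentIntervention(
                name=tname,
                category=spec["category"],
                effect=effects[spec["effect"]],
                baseline_uptake=float(spec["uptake"]["baseline"]),
                scenario_uptake=float(spec["uptake"][level]),
                eligible_fraction=float(eligible_fractions.get(tname, 1.0)),
            )
            for tname, spec in config["treatments"].items()
        ]
        return Scenario(name, treatments=treatments)
    policies = [
        PolicyIntervention(
            name=pname,
            effect=effects[spec["effect"]],
            dose_change=float(spec["dose"][level]),
        )
        for pname, spec in config["policies"].items()
    ]
    return Scenario(name, policies=policies)


def scale_rr(effect: EffectSize, dose: float, outcome: str = "stroke") -> float:
    """Risk-ratio multiplier for a dose change, log-linear in the risk ratio.

    ``multiplier = exp((dose / reference_dose) * ln(1 - RRR))``; the RRR is
    halved first for stroke outcomes of half-effect interventions.  At the
    reference dose this returns exactly ``1 - RRR``.
    """
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    if effect.reference_dose is None or effect.reference_dose <= 0:
        raise ValueError(f"effect {effect.name!r} has no positive reference dose")
    rrr = effect.rrr
    if outcome == "stroke" and effect.half_effect:
        rrr = rrr / 2.0
    if rrr >= 1.0:
        raise ValueError(f"RRR must be < 1, got {rrr}")
    if dose == 0.0:
        return 1.0
    ratio = dose / effect.reference_dose
    if ratio == 1.0:  # reference dose: the multiplier is 1 - RRR by definition
        return 1.0 - rrr
    return math.exp(ratio * math.log1p(-rrr))


def treatment_multiplier(iv: TreatmentIntervention, rrr: float | None = None) -> float:
    """Risk multiplier from an uptake change: ``1 - (u1 - u0) * eligible * RRR``."""
    rrr = iv.effect.rrr if rrr is None else rrr
    m = 1.0 - (iv.scenario_uptake - iv.baseline_uptake) * iv.eligible_fraction * rrr
    if not 0.0 < m < 2.0:
        raise ValueError(
            f"implausible multiplier {m:.4f} for {iv.name}: "
            f"u0={iv.baseline_uptake}, u1={iv.scenario_uptake}, "
            f"eligible={iv.eligible_fraction}, rrr={rrr}"
        )
    return m


def combine(multipliers: Iterable[float]) -> float:
    """Joint multiplier of independent interventions (product of risk ratios)."""
    out = 1.0
    for m in multipliers:
        if m <= 0:
            raise ValueError(f"multipliers must be positive, got {m}")
        out *= m
    return out


_AM = ("ACUTE_MINOR", "ACUTE_MAJOR")


def transition_multipliers(scenario: Scenario) -> np.ndarray:
    """Joint (8, 8) multiplier grid over target transitions for a scenario.

    Target mapping:

    * acute treatments: ACUTE_* -> DEAD_STROKE;
    * secondary prevention: POST_STROKE -> ACUTE_* and -> DEAD_STROKE
      (stroke-scoped), POST_STROKE -> DEAD_IHD (IHD-scoped);
    * primary prevention: WELL -> ACUTE_* (stroke-scoped), WELL -> DEAD_IHD
      (IHD-scoped);
    * population policies: WELL/TIA -> ACUTE_* (stroke-scoped multiplier) and
      WELL/POST_STROKE -> DEAD_IHD (IHD-scoped multiplier).
    """
    mult = np.ones((N_STATES, N_STATES))

    def apply(targets: Sequence[tuple[str, str]], m: float) -> None:
        for a, b in targets:
            mult[S[a], S[b]] *= m

    for iv in scenario.treatments:
        m = treatment_multiplier(iv)
        if iv.category == "acute":
            apply([(a, "DEAD_STROKE") for a in _AM], m)
        elif iv.category == "secondary":
            if iv.effect.applies_to("stroke"):
                apply([("POST_STROKE", a) for a in _AM], m)
                apply([("POST_STROKE", "DEAD_STROKE")], m)
            if iv.effect.applies_to("ihd"):
                apply([("POST_STROKE", "DEAD_IHD")], m)
        elif iv.category == "primary":
            if iv.effect.applies_to("stroke"):
                apply([("WELL", a) for a in _AM], m)
            if iv.effect.applies_to("ihd"):
                apply([("WELL", "DEAD_IHD")], m)
        else:
            raise ValueError(f"unknown treatment category {iv.category!r}")

    for iv in scenario.policies:
        if iv.effect.applies_to("stroke"):
            ms = scale_rr(iv.effect, iv.dose_change, "stroke")
            apply([(a, b) for a in ("WELL", "TIA") for b in _AM], ms)
        if iv.effect.applies_to("ihd"):
            mi = scale_rr(iv.effect, iv.dose_change, "ihd")
            apply([("WELL", "DEAD_IHD"), ("POST_STROKE", "DEAD_IHD")], mi)

    return mult


def apply_scenario(tts: TransitionTables, scenario: Scenario) -> TransitionTables:
    """Scale target transitions and rebalance row diagonals.

    Rows whose off-diagonal multipliers are all exactly one are left
    untouched byte-for-byte, so a null scenario reproduces the baseline
    tables (and hence baseline deaths) bit-for-bit.
    """
    mult = transition_multipliers(scenario)
    out = tts.copy()
    p = out.probs
    offdiag = ~np.eye(N_STATES, dtype=bool)
    touched_rows = [r for r in range(N_STATES) if np.any(mult[r][offdiag[r]] != 1.0)]
    for r in touched_rows:
        for c in range(N_STATES):
            if c != r:
                p[:, :, r, c] *= mult[r, c]
        row_off = p[:, :, r, :].sum(axis=2) - p[:, :, r, r]
        diag = 1.0 - row_off
        if np.any(diag < -1e-12) or np.any(p[:, :, r, :] > 1 + 1e-12):
            si, bi = np.unravel_index(np.argmin(diag), diag.shape)
            raise TransitionError(
                f"scenario {scenario.name!r} drives row {list(S)[r]} of stratum "
                f"({SEXES[si]}, {AGE_BANDS[bi]}) outside [0, 1]"
            )
        p[:, :, r, r] = np.clip(diag, 0.0, 1.0)
    out.validate()
    return out


@dataclass
class DPPResult:
    """Deaths prevented or postponed versus baseline for one scenario run.

    Dictionaries are keyed 'total', 'male', 'female'.
    """

    scenario: str
    horizon: int
    dpp: dict[str, float]
    baseline_deaths: dict[str, float]
    percent_reduction: dict[str, float]


def compute_dpp(
    baseline_run: CohortRun, scenario_run: CohortRun, scenario: str = "scenario"
) -> DPPResult:
    """Cumulative stroke + IHD deaths averted by a scenario versus baseline."""
    if baseline_run.horizon != scenario_run.horizon:
        raise ValueError(
            f"horizon mismatch: baseline {baseline_run.horizon}, "
            f"scenario {scenario_run.horizon}"
        )
    dpp, base, pct = {}, {}, {}
    for key in ("total", *SEXES):
        sex = None if key == "total" else key
        b = baseline_run.cumulative_deaths(("stroke", "ihd"), sex=sex)
        s = scenario_run.cumulative_deaths(("stroke", "ihd"), sex=sex)
        dpp[key] = b - s
        base[key] = b
        pct[key] = 100.0 * (b - s) / b if b > 0 else float("nan")
    return DPPResult(scenario, baseline_run.horizon, dpp, base, pct)


def run_scenario(
    bundle: Bundle,
    scenario: Scenario | str,
    horizon: int,
    params: EngineParams | None = None,
    incidence_table=None,
    effects: Mapping[str, EffectSize] | None = None,
    start_year: int = 2012,
) -> CohortRun:
    """Build transition tables for the bundle, apply a scenario, and simulate."""
    params = params or EngineParams()
    if isinstance(scenario, str):
        scenario = build_scenario(scenario, effects=effects)
    if incidence_table is None:
        incidence_table = estimate_from_bundle(bundle, params.severity_split_major)
    tts = build_transition_tables(
        bundle.mortality, incidence_table, bundle.case_fatality, params
    )
    tts = apply_scenario(tts, scenario)
    occ0 = initialize_cohort(bundle.population, bundle.prevalence)
    return run(occ0, tts, horizon, start_year)


def compare_scenarios(
    bundle: Bundle,
    horizons: Sequence[int] = (10, 20),
    scenario_names: Sequence[str] = SCENARIO_NAMES,
    params: EngineParams | None = None,
    effects: Mapping[str, EffectSize] | None = None,
) -> list[DPPResult]:
    """DPPs of every named scenario against baseline, per horizon."""
    params = params or EngineParams()
    inc = estimate_from_bundle(bundle, params.severity_split_major)
    results = []
    for horizon in horizons:
        base = run_scenario(bundle, "baseline", horizon, params, inc, effects)
        for name in scenario_names:
            if name == "baseline":
                results.append(compute_dpp(base, base, "baseline"))
            else:
                srun = run_scenario(bundle, name, horizon, params, inc, effects)
                results.append(compute_dpp(base, srun, name))
    return results


def attribute(
    bundle: Bundle,
    scenario: Scenario | str,
    horizon: int,
    params: EngineParams | None = None,
    effects: Mapping[str, EffectSize] | None = None,
) -> dict[str, dict]:
    """Per-intervention attribution shares from one-at-a-time runs.

    Each intervention is run alone against baseline; its share is its solo
    DPP over the sum of all solo DPPs, normalised to 100%.  When every solo
    DPP is zero the shares are undefined and reported as NaN.
    """
    params = params or EngineParams()
    if isinstance(scenario, str):
        scenario = build_scenario(scenario, effects=effects)
    inc = estimate_from_bundle(bundle, params.severity_split_major)
    base = run_scenario(bundle, Scenario("baseline"), horizon, params, inc)
    solo: dict[str, DPPResult] = {}
    for iv in scenario.treatments:
        solo_run = run_scenario(
            bundle, Scenario(iv.name, treatments=[iv]), horizon, params, inc
        )
        solo[iv.name] = compute_dpp(base, solo_run, iv.name)
    for iv in scenario.policies:
        solo_run = run_scenario(
            bundle, Scenario(iv.name, policies=[iv]), horizon, params, inc
        )
        solo[iv.name] = compute_dpp(base, solo_run, iv.name)
    total = sum(r.dpp["total"] for r in solo.values())
    shares = {
        name: (100.0 * r.dpp["total"] / total if total > 0 else float("nan"))
        for name, r in solo.items()
    }
    return {
        name: {"dpp": r.dpp, "share_pct": shares[name]} for name, r in solo.items()
    }
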