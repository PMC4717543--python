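"""Input-bundle validation: every violated invariant, named by table and cell."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tables import AGE_BANDS, Bundle, N_BANDS, SEXES, SEVERITIES

_EPS = 1e-12


@dataclass(frozen=True)
class Violation:
    table: str
    stratum: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"[{self.table}/{self.rule}] {self.stratum}: {self.message}"


def _complete(df, table, out, with_severity=False):
    expected = {(s, b) for s in SEXES for b in AGE_BANDS}
    if with_severity:
        expected = {(s, b, sv) for (s, b) in expected for sv in SEVERITIES}
        seen = set(zip(df["sex"], df["age_band"], df["severity"]))
    else:
        seen = set(zip(df["sex"], df["age_band"]))
    for stratum in sorted(expected - seen):
        out.append(
            Violation(table, str(stratum), "missing_stratum", "stratum absent")
        )
    return expected <= seen


def validate_bundle(bundle: Bundle) -> list[Violation]:
    """Check every hard invariant of every input table.

    Returns an empty list iff the bundle is valid; monotone-in-age gradients
    are generator conventions, not validity requirements, and are not
    enforced here.
    """
    out: list[Violation] = []

    if _complete(bundle.population, "population", out):
        for _, r in bundle.population.iterrows():
            if not np.isfinite(r["count"]) or r["count"] < 0:
                out.append(
                    Violation(
                        "population",
                        f"({r['sex']}, {r['age_band']})",
                        "count_range",
                        f"count {r['count']} is negative or non-finite",
                    )
                )

    if _complete(bundle.mortality, "mortality", out):
        for _, r in bundle.mortality.iterrows():
            stratum = f"({r['sex']}, {r['age_band']})"
            rates = [r[c] for c in ("all_cause_rate", "cvd_rate", "ihd_rate", "stroke_death_rate")]
            if any(not np.isfinite(v) or v < 0 for v in rates):
                out.append(
                    Violation("mortality", stratum, "rate_range", f"negative or non-finite rate in {rates}")
                )
                continue
            if r["cvd_rate"] > r["all_cause_rate"] + _EPS:
                out.append(
                    Violation(
                        "mortality",
                        stratum,
                        "cvd_le_all_cause",
                        f"cvd_rate {r['cvd_rate']:.6g} > all_cause_rate {r['all_cause_rate']:.6g}",
                    )
                )
            if r["ihd_rate"] + r["stroke_death_rate"] > r["cvd_rate"] + _EPS:
                out.append(
                    Violation(
                        "mortality",
                        stratum,
                        "cause_split_le_cvd",
                        f"ihd + stroke deaths {r['ihd_rate'] + r['stroke_death_rate']:.6g} "
                        f"> cvd_rate {r['cvd_rate']:.6g}",
                    )
                )

    if _complete(bundle.prevalence, "prevalence", out):
        for _, r in bundle.prevalence.iterrows():
            p = r["stroke_prevalence"]
            if not np.isfinite(p) or p < 0 or p > 0.5:
                out.append(
                    Violation(
                        "prevalence",
                        f"({r['sex']}, {r['age_band']})",
                        "prevalence_range",
                        f"stroke_prevalence {p} outside [0, 0.5]",
                    )
                )

    if _complete(bundle.case_fatality, "case_fatality", out, with_severity=True):
        cf = bundle.case_fatality.set_index(["sex", "age_band", "severity"])["first_year_cf"]
        for (sex, band, sev), v in cf.items():
            if not np.isfinite(v) or v < 0 or v > 1:
                out.append(
                    Violation(
                        "case_fatality",
                        f"({sex}, {band}, {sev})",
                        "cf_range",
                        f"first_year_cf {v} outside [0, 1]",
                    )
                )
        for sex in SEXES:
            for band in AGE_BANDS:
                try:
                    minor, major = cf[(sex, band, "minor")], cf[(sex, band, "major")]
                except KeyError:
                    continue
                if minor > major + _EPS:
                    out.append(
                        Violation(
                            "case_fatality",
                            f"({sex}, {band})",
                            "major_ge_minor",
                            f"minor cf {minor:.4g} exceeds major cf {major:.4g}",
                        )
                    )

    for name, u in bundle.uptakes.items():
        if not np.isfinite(u) or not 0 <= u <= 1:
            out.append(
                Violation("uptakes", name, "uptake_range", f"uptake {u} outside [0, 1]")
            )

    return out


def validate_bundle_dir(path: str | Path) -> list[Violation]:
    """Validate a bundle on disk; unreadable files become violations, not errors."""
    try:
        bundle = Bundle.from_dir(path)
    except (OSError, ValueError) as exc:
        return [Violation("bundle", str(path), "unreadable", str(exc))]
    return validate_bundle(bundle)
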