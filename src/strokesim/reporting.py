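"""Report tables: scenario DPP summaries and per-intervention attribution."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scenarios import DPPResult
from .psa import PsaResult
from .tables import SEXES

DPP_COLUMNS = ("scenario", "horizon", "sex", "dpp", "percent_reduction")
REPORT_COLUMNS = ("intervention", "horizon", "sex", "dpp", "dpp_min", "dpp_max", "share_pct")
PSA_COLUMNS = (
    "scenario",
    "horizon",
    "sex",
    "dpp_point",
    "ui_low",
    "ui_high",
    "min",
    "max",
    "n_draws",
    "seed",
    "n_rejected",
)


def dpp_frame(results: Sequence[DPPResult]) -> pd.DataFrame:
    """Tidy DPP table: one row per scenario, horizon and sex (incl. total)."""
    rows = [
        {
            "scenario": r.scenario,
            "horizon": r.horizon,
            "sex": key,
            "dpp": r.dpp[key],
            "percent_reduction": r.percent_reduction[key],
        }
        for r in results
        for key in ("total", *SEXES)
    ]
    return pd.DataFrame(rows, columns=list(DPP_COLUMNS))


def attribution_report(
    per_intervention: Mapping[str, DPPResult],
    horizon: int | None = None,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-sex intervention report with a Total row.

    One row per intervention and sex plus a Total row per sex.  The Total row
    is the sum of the intervention rows (report additivity; the joint-model
    DPP is generally smaller because independent effects multiply).  Shares
    are normalised within each sex to sum to 100%.  ``ranges`` optionally
    supplies (min, max) DPP bounds per intervention (e.g. from a PSA).
    """
    ranges = ranges or {}
    rows: list[dict] = []
    if not per_intervention:
        return pd.DataFrame(columns=list(REPORT_COLUMNS))
    if horizon is None:
        horizon = next(iter(per_intervention.values())).horizon
    for sex_key in ("total", *SEXES):
        total = sum(r.dpp[sex_key] for r in per_intervention.values())
        for name, r in per_intervention.items():
            lo, hi = ranges.get(name, (float("nan"), float("nan")))
            rows.append(
                {
                    "intervention": name,
                    "horizon": horizon,
                    "sex": sex_key,
                    "dpp": r.dpp[sex_key],
                    "dpp_min": lo,
                    "dpp_max": hi,
                    "share_pct": 100.0 * r.dpp[sex_key] / total if total > 0 else float("nan"),
                }
            )
        rows.append(
            {
                "intervention": "Total",
                "horizon": horizon,
                "sex": sex_key,
                "dpp": total,
                "dpp_min": float("nan"),
                "dpp_max": float("nan"),
                "share_pct": 100.0 if total > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def psa_frame(results: Sequence[PsaResult]) -> pd.DataFrame:
    """Tidy PSA summary (total and per-sex rows per scenario/horizon)."""
    rows = []
    for r in results:
        for i, key in enumerate(("total", *SEXES)):
            if key == "total":
                draws = r.draws
            else:
                draws = r.draws_by_sex[:, i - 1]
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append(
                {
                    "scenario": r.scenario,
                    "horizon": r.horizon,
                    "sex": key,
                    "dpp_point": r.point.dpp[key],
                    "ui_low": float(lo),
                    "ui_high": float(hi),
                    "min": float(draws.min()),
                    "max": float(draws.max()),
                    "n_draws": r.n_draws,
                    "seed": r.seed,
                    "n_rejected": r.n_rejected,
                }
            )
    return pd.DataFrame(rows, columns=list(PSA_COLUMNS))


def format_report(df: pd.DataFrame) -> str:
    """Human-readable rendering of a report frame."""
    if df.empty:
        return "(no results)"
    return df.to_string(index=False, float_format=lambda v: f"{v:,.1f}")
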