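"""Median/IQR summaries stratified by cohort, ASCVD subtype and scenario.

Quartiles use linear interpolation between order statistics (position
``1 + (n − 1)·p``, numpy's default), fixed so rendered tables are stable.
Percentages are rendered rounded half-away-from-zero to integers, matching
the convention of epidemiological tables; raw fractions are kept in the
machine-readable output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStat",
    "median_iqr",
    "round_half_away",
    "QUANTITIES",
    "PERCENT_QUANTITIES",
    "build_report",
    "render_tables",
]


@dataclass(frozen=True)
class SummaryStat:
    """Median and quartiles of a simulated quantity."""

    median: float
    q1: float
    q3: float
    n: int


def median_iqr(values: Sequence[float]) -> SummaryStat:
    """Median and interquartile range by linear interpolation.

    Convention: quartile position = 1 + (n − 1)·p, so the median of
    {1..5} is 3 and the quartiles of {1,2,3,4} are (1.75, 3.25).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr requires a nonempty list")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return SummaryStat(median=float(med), q1=float(q1), q3=float(q3), n=int(arr.size))


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (2.5 → 3, −2.5 → −3)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


#: Simulated quantities summarized per stratum × scenario.
QUANTITIES: tuple[str, ...] = (
    "baseline_p120",
    "delta_ldl",
    "rel_reduction",
    "rrr",
    "arr",
    "residual_p120",
)
#: Quantities rendered as integer percentages in human-readable tables.
PERCENT_QUANTITIES = frozenset(
    {"baseline_p120", "rel_reduction", "rrr", "arr", "residual_p120"}
)

_STRATA = ("overall", "CAD", "CBD", "PAD")


def build_report(results: pd.DataFrame, cohort: Sequence) -> pd.DataFrame:
    """Summarize tidy simulation results per (stratum, scenario, quantity).

    ``results`` is the frame produced by ``simulate_scenario`` (possibly
    concatenated over scenarios); ``cohort`` supplies the subtype of every
    patient_id.  Every requested stratum × scenario × quantity cell is
    present; strata with no patients are explicitly empty (n = 0, NaN
    summaries).  The overall row pools all subtypes.
    """
    subtype_of = {r.patient_id: r.ascvd_subtype.value for r in cohort}
    unknown = set(results["patient_id"]) - set(subtype_of)
    if unknown:
        raise ValueError(f"results reference patient_ids absent from cohort: {sorted(unknown)[:5]}")
    frame = results.copy()
    frame["subtype"] = frame["patient_id"].map(subtype_of)
    rows = []
    for scenario in sorted(frame["scenario"].unique()):
        sc = frame[frame["scenario"] == scenario]
        for stratum in _STRATA:
            sub = sc if stratum == "overall" else sc[sc["subtype"] == stratum]
            for quantity in QUANTITIES:
                if len(sub):
                    stat = median_iqr(sub[quantity].to_numpy())
                    rows.append(
                        dict(stratum=stratum, scenario=scenario, quantity=quantity,
                             n=stat.n, q1=stat.q1, median=stat.median, q3=stat.q3)
                    )
                else:
                    rows.append(
                        dict(stratum=stratum, scenario=scenario, quantity=quantity,
                             n=0, q1=np.nan, median=np.nan, q3=np.nan)
                    )
    return pd.DataFrame(rows)


def _render_cell(quantity: str, q1: float, med: float, q3: float) -> str:
    if np.isnan(med):
        return "—"
    if quantity in PERCENT_QUANTITIES:
        fmt = lambda v: f"{round_half_away(100.0 * v):.0f}"
        return f"{fmt(med)}% ({fmt(q1)}–{fmt(q3)}%)"
    return f"{round_half_away(med):.0f} ({round_half_away(q1):.0f}–{round_half_away(q3):.0f}) mg/dl"


def render_tables(report: pd.DataFrame, path: str | Path) -> dict[str, Path]:
    """Write the summary as a tidy CSV plus a markdown table per stratum.

    Output is byte-stable for identical input reports.
    """
    if report.empty:
        raise ValueError("cannot render an empty report")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    csv_path = path / "summary.csv"
    report.to_csv(csv_path, index=False)
    out["summary_csv"] = csv_path

    lines = ["# Simulated risk reduction summary", ""]
    for stratum in _STRATA:
        sub = report[report["stratum"] == stratum]
        if sub.empty:
            continue
        lines.append(f"## Stratum: {stratum}")
        lines.append("")
        scenarios = sorted(sub["scenario"].unique())
        lines.append("| quantity | " + " | ".join(scenarios) + " |")
        lines.append("|---" * (len(scenarios) + 1) + "|")
        for quantity in QUANTITIES:
            cells = []
            for scenario in scenarios:
                row = sub[(sub["scenario"] == scenario) & (sub["quantity"] == quantity)]
                if row.empty:
                    cells.append("—")
                else:
                    r = row.iloc[0]
                    cells.append(_render_cell(quantity, r["q1"], r["median"], r["q3"]))
            lines.append(f"| {quantity} | " + " | ".join(cells) + " |")
        lines.append("")
    md_path = path / "report.md"
    md_path.write_text("\n".join(lines))
    out["report_md"] = md_path
    return out
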