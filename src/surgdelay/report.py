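"""CSV report writers.

Report styles mirror the published result layouts: per-1000 reference
cohorts by delay week ("table1"), national delay cohorts with totals
("table2"), scenario grids and simulation summaries. Values are written
at the published precisions (diameters 2 dp, mortalities 2 dp, RR 3 dp,
deaths as integers) with a full-precision companion column for each
rounded quantity.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["write_report"]

_ROUNDED = {
    "td_after_mm": 2,
    "mortality_base_pct": 2,
    "mortality_delayed_pct": 2,
    "rr": 3,
    "baseline_deaths": 0,
    "excess_deaths": 0,
}


def _format_cohort_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col, nd in _ROUNDED.items():
        if col in out.columns:
            full = out[col]
            out[col] = full.round(nd).astype(int) if nd == 0 else full.round(nd)
            out[f"{col}_full"] = full
    return out


def write_report(results, style: str, path) -> Path:
    """Write a results object to ``path`` as CSV (or JSON for simulations).

    ``style`` selects the layout: ``"table1"``/``"table2"`` take a
    :class:`~surgdelay.model.TreatmentDelayResults`; ``"scenario"`` takes
    the DataFrame from ``run_scenario_grid``; ``"simulation"`` takes the
    dict from ``simulate_excess_deaths``.
    """
    path = Path(path)
    if style in ("table1", "table2"):
        df = _format_cohort_frame(results.cohorts)
        if style == "table1":
            # wide per-1000 layout: one row per quantity per HR stratum
            df = df.pivot_table(
                index="hr_status",
                columns="delay_day",
                values=["td_after_mm", "mortality_delayed_pct", "rr", "excess_deaths"],
                sort=True,
            )
        df.to_csv(path)
    elif style == "scenario":
        results.round(6).to_csv(path, index=False)
    elif style == "simulation":
        path.write_text(json.dumps(results, indent=2, default=float))
    else:
        raise ValueError(f"unknown report style: {style!r}")
    return path
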