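"""Descriptive comparison of two hotspot-search methods.

Works on a long-format outcome table (subject, method, outcome, value) —
the shape any external mixed-model fitter consumes directly.  Implemented
here are the per-method descriptives (sample mean +/- SD) and the paired
mean difference mean(MHS) - mean(CHS), which in a balanced paired design
equals the fixed-effect estimate of the method contrast.  Mixed-effects
inference itself is deliberately left to off-the-shelf fitters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

OUTCOME_COLUMNS = ("subject", "method", "outcome", "value")


def make_outcome_table(records) -> pd.DataFrame:
    """Build/validate a long-format outcome table."""
    df = pd.DataFrame(records)
    missing = set(OUTCOME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"outcome table missing columns: {sorted(missing)}")
    return df[list(OUTCOME_COLUMNS)]


def _column(table: pd.DataFrame, outcome: str, method: str) -> pd.Series:
    sub = table[(table["outcome"] == outcome) & (table["method"] == method)]
    if sub.empty:
        raise ValueError(f"no rows for outcome {outcome!r}, method {method!r}")
    return sub.set_index("subject")["value"].astype(float)


def descriptives(table: pd.DataFrame, outcome: str) -> dict:
    """Per-method sample mean and SD (ddof=1) for one outcome.

    Requires at least two subjects per method.
    """
    out = {}
    for method in sorted(table.loc[table["outcome"] == outcome, "method"].unique()):
        vals = _column(table, outcome, method)
        if len(vals) < 2:
            raise ValueError(f"need >= 2 subjects for method {method!r}")
        out[method] = (float(vals.mean()), float(vals.std(ddof=1)))
    if not out:
        raise ValueError(f"no rows for outcome {outcome!r}")
    return out


def mean_difference(
    table: pd.DataFrame, outcome: str, method_a: str = "MHS", method_b: str = "CHS"
) -> float:
    """mean(method_a) - mean(method_b), paired over subjects.

    Every subject must contribute both methods (balanced paired design);
    the result then equals the fixed-effect method estimate.
    """
    a = _column(table, outcome, method_a)
    b = _column(table, outcome, method_b)
    if set(a.index) != set(b.index):
        raise ValueError("paired analysis requires both methods for every subject")
    return float(a.mean() - b.mean())


def session_report(
    chs_result,
    mhs_result,
    thresholds: dict,
    projections: dict | None,
    out_dir,
    subject_id: str = "S01",
) -> dict:
    """Collate one simulated subject's outputs into CSV + JSON files.

    ``thresholds`` maps method -> dict of outcome values (e.g. the output
    of the threshold pipeline); ``projections`` optionally maps method ->
    projected coordinate.  Returns the summary dict it wrote.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = {"CHS": chs_result, "MHS": mhs_result}
    rows = []
    for method, res in results.items():
        row = {
            "subject": subject_id,
            "method": method,
            "success": res.success,
            "x_mm": None if res.position is None else float(res.position[0]),
            "y_mm": None if res.position is None else float(res.position[1]),
            "z_mm": None if res.position is None else float(res.position[2]),
            "final_intensity_pct_mso": res.final_intensity,
            "pulse_count": res.pulse_count,
        }
        row.update({k: v for k, v in thresholds.get(method, {}).items()})
        if projections and method in projections:
            p = np.asarray(projections[method], float)
            row.update({"proj_x_mm": p[0], "proj_y_mm": p[1], "proj_z_mm": p[2]})
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(out_dir / f"{subject_id}_report.csv", index=False)
    summary = {"subject": subject_id, "rows": rows}
    with open(out_dir / f"{subject_id}_report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def group_report(tables: list[pd.DataFrame], out_dir) -> pd.DataFrame:
    """Concatenate per-subject outcome tables and write the group CSV."""
    if not tables:
        raise ValueError("empty group")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    group = pd.concat(tables, ignore_index=True)
    group.to_csv(out_dir / "group_outcomes.csv", index=False)
    return group
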