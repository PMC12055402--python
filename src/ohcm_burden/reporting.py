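"""Report tables: statistical disclosure suppression and NYHA distributions.

Counts of 1–4 are primary-suppressed, mirroring small-cell disclosure rules
for UK health data.  When a row or column with a shown total is left with
exactly one suppressed cell, that cell would be recoverable by subtraction,
so the smallest remaining shown cell is secondary-suppressed; the rule
iterates to a fixpoint.  Suppressed cells render as "NR".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import percent

SHOWN = "shown"
PRIMARY = "primary_suppressed"
SECONDARY = "secondary_suppressed"


def suppress_small_cells(table: pd.DataFrame, row_totals_shown: bool = True,
                         col_totals_shown: bool = True) -> pd.DataFrame:
    """Cell-state frame for a table of non-negative integer counts.

    Returns a same-shape DataFrame of states in {shown, primary_suppressed,
    secondary_suppressed}.
    """
    values = table.to_numpy()
    if (values < 0).any() or not np.issubdtype(values.dtype, np.integer):
        raise ValueError("table must contain non-negative integer counts")
    state = np.full(table.shape, SHOWN, dtype=object)
    state[(values >= 1) & (values <= 4)] = PRIMARY

    def pass_axis(axis: int) -> bool:
        changed = False
        n_lines = table.shape[axis]
        for i in range(n_lines):
            line_state = state[i, :] if axis == 0 else state[:, i]
            line_vals = values[i, :] if axis == 0 else values[:, i]
            suppressed = line_state != SHOWN
            if suppressed.sum() == 1 and (~suppressed).sum() > 0:
                shown_idx = np.flatnonzero(~suppressed)
                victim = shown_idx[np.argmin(line_vals[shown_idx])]
                line_state[victim] = SECONDARY
                changed = True
        return changed

    changed = True
    while changed:
        changed = False
        if row_totals_shown:
            changed |= pass_axis(0)
        if col_totals_shown:
            changed |= pass_axis(1)
    return pd.DataFrame(state, index=table.index, columns=table.columns)


def render_suppressed(table: pd.DataFrame, state: pd.DataFrame,
                      marker: str = "NR") -> pd.DataFrame:
    """Counts with suppressed cells replaced by the disclosure marker."""
    out = table.astype(object).copy()
    out[state != SHOWN] = marker
    return out


def nyha_distribution_report(baseline_counts: pd.Series, end_counts: pd.Series,
                             person_time: pd.Series | None = None) -> pd.DataFrame:
    """Class distribution at baseline and end of follow-up, with II+ pooled.

    Inputs are counts indexed by class 1–4; percentages are of the cohort
    total, half-up to 1 dp.  ``person_time`` (years per class) adds follow-up
    time shares.
    """
    idx = [1, 2, 3, 4]
    base = baseline_counts.reindex(idx, fill_value=0).astype(int)
    end = end_counts.reindex(idx, fill_value=0).astype(int)
    n = int(base.sum())
    n_end = int(end.sum())
    pt = person_time.reindex(idx, fill_value=0.0) if person_time is not None else None
    rows = []
    for cls in idx:
        rows.append({
            "stratum": f"class_{cls}",
            "n_baseline": int(base[cls]),
            "pct_baseline": percent(base[cls], n) if n else 0.0,
            "n_end": int(end[cls]),
            "pct_end": percent(end[cls], n_end) if n_end else 0.0,
            "person_years": float(pt[cls]) if pt is not None else pd.NA,
            "pct_person_years": percent(pt[cls], pt.sum())
            if pt is not None and pt.sum() > 0 else pd.NA,
        })
    plus = {
        "stratum": "class_II_plus",
        "n_baseline": int(base.loc[2:].sum()),
        "pct_baseline": percent(base.loc[2:].sum(), n) if n else 0.0,
        "n_end": int(end.loc[2:].sum()),
        "pct_end": percent(end.loc[2:].sum(), n_end) if n_end else 0.0,
        "person_years": float(pt.loc[2:].sum()) if pt is not None else pd.NA,
        "pct_person_years": percent(pt.loc[2:].sum(), pt.sum())
        if pt is not None and pt.sum() > 0 else pd.NA,
    }
    rows.append(plus)
    return pd.DataFrame(rows)
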