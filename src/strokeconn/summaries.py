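"""Descriptive cohort statistics: measure correlations and summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def clinical_correlations(
    table: pd.DataFrame, min_pairs: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise complete-case Pearson correlations between clinical measures.

    Returns (r, p, stars) DataFrames; cells with fewer than ``min_pairs``
    complete pairs are NaN.  Pairwise deletion is used because different
    measures can be missing for different subjects.
    """
    cols = list(table.columns)
    k = len(cols)
    R = np.full((k, k), np.nan)
    P = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            xi = table[cols[i]].to_numpy(dtype=float)
            xj = table[cols[j]].to_numpy(dtype=float)
            mask = np.isfinite(xi) & np.isfinite(xj)
            if mask.sum() < min_pairs:
                continue
            if i == j:
                R[i, i], P[i, i] = 1.0, 0.0
                continue
            if xi[mask].std() == 0 or xj[mask].std() == 0:
                continue
            r, p = stats.pearsonr(xi[mask], xj[mask])
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    r_df = pd.DataFrame(R, index=cols, columns=cols)
    p_df = pd.DataFrame(P, index=cols, columns=cols)
    star_df = p_df.map(lambda p: _stars(p) if np.isfinite(p) else "")
    return r_df, p_df, star_df


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) for numeric columns; category percentages for the rest."""
    rows = []
    for col in table.columns:
        series = table[col]
        if pd.api.types.is_numeric_dtype(series):
            vals = series.dropna()
            if len(vals) == 0:
                rows.append({"measure": col, "summary": "missing", "n": 0})
            else:
                rows.append({
                    "measure": col,
                    "summary": f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})"
                    if len(vals) > 1 else f"{vals.mean():.2f} (0.00)",
                    "n": int(len(vals)),
                })
        else:
            vals = series.dropna()
            if len(vals) == 0:
                rows.append({"measure": col, "summary": "missing", "n": 0})
            else:
                pct = (vals.value_counts(normalize=True) * 100).round(1)
                summary = "; ".join(f"{k}: {v:.1f}%" for k, v in pct.items())
                rows.append({"measure": col, "summary": summary, "n": int(len(vals))})
    return pd.DataFrame(rows)
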