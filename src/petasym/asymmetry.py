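"""Hemispheric laterality metrics.

Sign convention throughout: positive means right > left.

* asymmetry index       AI = (right - left) / (right + left)
* relative difference   100 * (right - left) / mean(left, right) = 200 * AI
* paired Cohen's d      mean(right - left) / sample SD of the differences

The relative difference is signed; its absolute value reproduces the
"absolute difference over the mean" reading.  Cohort-level relative
differences are computed from subject-level paired differences (mean of the
differences over the mean of the side means), not from the printed medians.
Quartiles use linear interpolation between order statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scipy import stats as sps

__all__ = [
    "DegenerateDataError",
    "asymmetry_index",
    "relative_difference",
    "paired_cohens_d",
    "percent_above_reference",
    "make_paired_table",
    "summarize_asymmetry",
]


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined (e.g. zero-variance differences)."""


def _as_arrays(left, right):
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right must have matching shapes")
    return left, right


def asymmetry_index(left, right):
    """(right - left) / (right + left); in (-1, 1) for positive inputs."""
    left, right = _as_arrays(left, right)
    total = left + right
    if np.any(total <= 0):
        raise ValueError("asymmetry index requires left + right > 0")
    out = (right - left) / total
    return float(out) if out.ndim == 0 else out

def relative_difference(left, right):
    """Signed percent difference relative to the bilateral mean (= 200 * AI)."""
    left, right = _as_arrays(left, right)
    mean = 0.5 * (left + right)
    if np.any(mean <= 0):
        raise ValueError("relative difference requires a positive bilateral mean")
    out = 100.0 * (right - left) / mean
    return float(out) if out.ndim == 0 else out


def paired_cohens_d(left, right) -> float:
    """Mean of paired differences over their sample SD (n - 1 denominator)."""
    left, right = _as_arrays(left, right)
    if left.ndim != 1 or left.size < 2:
        raise ValueError("paired Cohen's d needs vectors of length >= 2")
    diff = right - left
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("paired differences have zero variance")
    return float(np.mean(diff) / sd)


def percent_above_reference(value, reference):
    """Percent elevation of a value over a reference value."""
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference must be positive")
    out = 100.0 * (np.asarray(value, dtype=float) - reference) / reference
    return float(out) if out.ndim == 0 else out


def make_paired_table(measurements: pd.DataFrame, value: str = "DVR") -> pd.DataFrame:
    """Pivot a long (subject_id, region, side, value) table into paired rows.

    Returns one row per subject x region with ``{value}_left`` and
    ``{value}_right`` columns; a subject missing one side is an error naming
    the subject and region.
    """
    required = {"subject_id", "region", "side", value}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")
    wide = measurements.pivot_table(
        index=["subject_id", "region"], columns="side", values=value, aggfunc="first"
    )
    for side in ("left", "right"):
        if side not in wide.columns:
            raise ValueError(f"no {side!r}-side measurements present")
    incomplete = wide[wide[["left", "right"]].isna().any(axis=1)]
    if not incomplete.empty:
        sid, region = incomplete.index[0]
        raise ValueError(f"subject {sid!r} is missing a side for region {region!r}")
    out = wide.reset_index()[["subject_id", "region", "left", "right"]]
    return out.rename(columns={"left": f"{value}_left", "right": f"{value}_right"})


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return float(med), float(q1), float(q3)


def summarize_asymmetry(
    table: pd.DataFrame, value: str = "DVR"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region asymmetry summary from a paired table.

    ``table`` needs columns subject_id, region, ``{value}_left``,
    ``{value}_right``.  Returns ``(summary, per_subject_ai)``: the summary has
    per-side median (IQR), the cohort relative difference, Cohen's d and the
    Shapiro-Wilk p of the right-minus-left differences; p-values from
    hypothesis tests are attached separately by the stats layer.
    """
    lcol, rcol = f"{value}_left", f"{value}_right"
    for col in ("subject_id", "region", lcol, rcol):
        if col not in table.columns:
            raise ValueError(f"paired table lacks column {col!r}")
    if table["subject_id"].nunique() < 2:
        raise ValueError("need at least two subjects to summarise asymmetry")
    summaries = []
    ai_rows = []
    for region, grp in table.groupby("region", sort=False):
        left = grp[lcol].to_numpy(dtype=float)
        right = grp[rcol].to_numpy(dtype=float)
        diff = right - left
        ai = asymmetry_index(left, right)
        ai = np.atleast_1d(ai)
        for sid, a in zip(grp["subject_id"], ai):
            ai_rows.append({"subject_id": sid, "region": region, "AI": float(a)})
        med_l, q1_l, q3_l = _median_iqr(left)
        med_r, q1_r, q3_r = _median_iqr(right)
        rel_diff = 100.0 * float(np.mean(diff)) / float(
            0.5 * (np.mean(left) + np.mean(right))
        )
        try:
            d = paired_cohens_d(left, right)
        except DegenerateDataError:
            d = np.nan
        if left.size >= 3 and np.ptp(diff) > 0:
            shapiro_p = float(sps.shapiro(diff).pvalue)
        else:
            shapiro_p = np.nan
        summaries.append(
            {
                "region": region,
                "n": int(left.size),
                "median_left": med_l,
                "q1_left": q1_l,
                "q3_left": q3_l,
                "median_right": med_r,
                "q1_right": q1_r,
                "q3_right": q3_r,
                "rel_diff_pct": rel_diff,
                "cohens_d": d,
                "shapiro_p_diff": shapiro_p,
                "ai_mean": float(np.mean(ai)),
                "ai_median": float(np.median(ai)),
            }
        )
    return pd.DataFrame(summaries), pd.DataFrame(ai_rows)
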