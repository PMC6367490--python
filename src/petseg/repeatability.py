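"""Test-retest repeatability statistics for whole-body tumour-load metrics.

For a metric measured on two days under one condition (uptake interval,
reconstruction, delineation method):

    TRT  = day2 - day1
    TRT% = 100 * (day2 - day1) / ((day1 + day2) / 2)

with their absolute variants aTRT and aTRT%.  The repeatability
coefficient is RC = 1.96 * SD over patients of TRT (or TRT%), the
half-width of the 95% band in which a repeat measurement is expected to
fall.  Between-day agreement is additionally summarised by the intraclass
correlation coefficient of the two-way mixed model, consistency type,
single measures — ICC(3,1) — which is blind to a fixed between-day shift.

SD uses the n-1 (sample) denominator, the convention of the test-retest
repeatability literature.  Pairs with a missing day are dropped listwise
within a condition for SD/RC/ICC but kept (with missing cells) in the
long-format export intended for external GEE-style modelling.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "trt",
    "repeatability_coefficient",
    "icc_consistency",
    "build_pairs",
    "summarize",
    "export_long_table",
    "RC_FACTOR",
    "CONDITION_KEYS",
    "METRIC_COLUMNS",
]

RC_FACTOR = 1.96
CONDITION_KEYS = ["uptake", "reconstruction", "method"]
METRIC_COLUMNS = {"TMATV": "tmatv_ml", "TTB": "ttb_g"}


def trt(day1: float, day2: float) -> tuple[float, float]:
    """Test-retest difference and percent difference of the pair mean.

    Returns ``(TRT, TRT%)``; for ``day1 = day2 = 0`` the difference is 0 and
    the percent difference undefined (NaN).  For positive values TRT% is
    bounded in (-200, 200).
    """
    d1, d2 = float(day1), float(day2)
    if d1 < 0 or d2 < 0:
        raise ValueError("metric values must be non-negative")
    diff = d2 - d1
    mean = (d1 + d2) / 2.0
    if mean == 0:
        return 0.0, float("nan")
    return diff, 100.0 * diff / mean


def repeatability_coefficient(values: Sequence[float]) -> tuple[float, float]:
    """Sample SD (n-1 denominator) and RC = 1.96 x SD of a TRT sample."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("repeatability coefficient needs at least two values")
    sd = float(np.std(arr, ddof=1))
    return sd, RC_FACTOR * sd


def icc_consistency(day1: Sequence[float], day2: Sequence[float]) -> float:
    """ICC(3,1): two-way mixed model, consistency type, single measures.

    From the two-way ANOVA (subjects x days, no interaction) mean squares:
    ICC = (MS_rows - MS_err) / (MS_rows + (k - 1) MS_err) with k = 2 raters
    (days).  A constant between-day offset does not lower the value.  With
    zero between-subject variance the coefficient is undefined and NaN is
    returned with a warning; a perfectly consistent sample (MS_err = 0 with
    subject variance present) gives exactly 1.0.
    """
    y1 = np.asarray(day1, dtype=float)
    y2 = np.asarray(day2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError("day1/day2 must be equal-length 1-D sequences")
    n = y1.size
    if n < 2:
        raise ValueError("ICC needs at least two subjects")
    data = np.stack([y1, y2], axis=1)      # n subjects x k=2 days
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = max(ss_err / ((n - 1) * (k - 1)), 0.0)   # guard tiny negative round-off
    if ms_rows == 0:
        warnings.warn("zero between-subject variance: ICC undefined", stacklevel=2)
        return float("nan")
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


def build_pairs(measurements: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long measurements table into day1/day2 pairs.

    Input columns: patient, day, uptake, reconstruction, method plus the
    metric value columns (tmatv_ml, ttb_g).  Output: one row per patient x
    condition x metric with ``day1``/``day2`` columns; a scan missing on one
    day leaves that cell NaN rather than dropping the row.
    """
    long = measurements.melt(
        id_vars=["patient", "day"] + CONDITION_KEYS,
        value_vars=[c for c in METRIC_COLUMNS.values() if c in measurements.columns],
        var_name="metric_col",
        value_name="value",
    )
    inv = {v: k for k, v in METRIC_COLUMNS.items()}
    long["metric"] = long["metric_col"].map(inv)
    wide = long.pivot_table(
        index=["patient"] + CONDITION_KEYS + ["metric"],
        columns="day",
        values="value",
        aggfunc="first",
        dropna=False,
    ).rename(columns={1: "day1", 2: "day2"})
    for col in ("day1", "day2"):
        if col not in wide.columns:
            wide[col] = np.nan
    pairs = wide.reset_index()[
        ["patient"] + CONDITION_KEYS + ["metric", "day1", "day2"]
    ]
    pairs.columns.name = None
    both = pairs["day1"].notna() & pairs["day2"].notna()
    t = pairs.loc[both].apply(lambda r: trt(r["day1"], r["day2"]), axis=1)
    pairs["trt"] = np.nan
    pairs["trt_pct"] = np.nan
    if both.any():
        pairs.loc[both, "trt"] = [v[0] for v in t]
        pairs.loc[both, "trt_pct"] = [v[1] for v in t]
    return pairs


def summarize(pairs: pd.DataFrame) -> pd.DataFrame:
    """Cohort repeatability per condition x metric.

    Emits mean TRT and TRT% with SD and RC = 1.96 SD, the absolute-variant
    means (aTRT, aTRT%), the ICC and the number of complete pairs; a group
    with fewer than two complete pairs is reported with the statistics
    missing rather than dropped.
    """
    out = []
    for keys, grp in pairs.groupby(CONDITION_KEYS + ["metric"], sort=True):
        complete = grp.dropna(subset=["day1", "day2"])
        row = dict(zip(CONDITION_KEYS + ["metric"], keys))
        row["n_pairs"] = len(complete)
        if len(complete) >= 2:
            trt_vals = complete["trt"].to_numpy()
            pct_vals = complete["trt_pct"].dropna().to_numpy()
            sd, rc = repeatability_coefficient(trt_vals)
            row.update(mean_trt=trt_vals.mean(), sd_trt=sd, rc=rc,
                       mean_atrt=np.abs(trt_vals).mean())
            if pct_vals.size >= 2:
                sd_p, rc_p = repeatability_coefficient(pct_vals)
                row.update(mean_trt_pct=pct_vals.mean(), sd_trt_pct=sd_p,
                           rc_pct=rc_p, mean_atrt_pct=np.abs(pct_vals).mean())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row["icc"] = icc_consistency(
                    complete["day1"].to_numpy(), complete["day2"].to_numpy()
                )
        out.append(row)
    columns = CONDITION_KEYS + [
        "metric", "n_pairs", "mean_trt", "sd_trt", "rc", "mean_atrt",
        "mean_trt_pct", "sd_trt_pct", "rc_pct", "mean_atrt_pct", "icc",
    ]
    return pd.DataFrame(out, columns=columns)


def export_long_table(pairs: pd.DataFrame, path) -> pd.DataFrame:
    """Write the GEE-ready long table: TRT% as the dependent variable with
    patient, uptake, reconstruction and method as predictors.

    Rows with a missing day are kept with missing cells so external
    software can model the missingness via the patient term.
    """
    cols = ["patient"] + CONDITION_KEYS + ["metric", "day1", "day2", "trt", "trt_pct"]
    table = pairs[cols].copy()
    table.to_csv(path, index=False, float_format="%.10g")
    return table
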