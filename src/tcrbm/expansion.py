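"""Transgene qPCR cell-kinetics summaries.

Peak expansion (Cmax, copies of transgene per microgram genomic DNA),
trapezoidal area under the expansion curve from day 0 to day 28, and
week-4 persistence read off the sampled grid.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .types import ExpansionSeries, ExpansionSummary


def compute_cmax(series: ExpansionSeries) -> tuple[float, float]:
    """Peak post-infusion transgene level and its day.

    The maximum is taken over all post-infusion points (day > 0), with ties
    broken by the earliest day. The search window is unbounded: the study
    never caps the Cmax day.
    """
    post = series.days > 0
    if not np.any(post):
        raise ValueError(f"{series.patient_id}: no post-infusion points")
    days = series.days[post]
    copies = series.copies_per_ug[post]
    best = int(np.argmax(copies))  # argmax returns the first (earliest) maximum
    return float(copies[best]), float(days[best])


def compute_auc_0_28(series: ExpansionSeries) -> float:
    """Trapezoidal AUC of copies/ug over days [0, 28], linear scale.

    No extrapolation: if there is no day-0 observation the curve starts at
    the first observed day, and integration stops at the last observation
    below day 28. With fewer than 2 usable points the AUC is missing (NaN)
    with a warning.
    """
    keep = series.days <= 28
    days = series.days[keep]
    copies = series.copies_per_ug[keep]
    if len(days) < 2:
        warnings.warn(
            f"{series.patient_id}: fewer than 2 points by day 28; AUC missing",
            stacklevel=2,
        )
        return math.nan
    return float(np.trapezoid(copies, days))


def persistence_at_week(
    series: ExpansionSeries, week: int = 4, window_days: float = 3.0
) -> float:
    """Transgene level at the sampled day nearest 7*week, within +/- window.

    Returns NaN when no observation falls inside the window. Ties in
    distance resolve to the earlier day.
    """
    target = 7.0 * week
    dist = np.abs(series.days - target)
    if len(dist) == 0 or np.min(dist) > window_days:
        return math.nan
    return float(series.copies_per_ug[int(np.argmin(dist))])


def summarize_expansion(expansion: pd.DataFrame) -> pd.DataFrame:
    """Per-patient ExpansionSummary table from the long expansion.csv format."""
    rows = []
    for pid, grp in expansion.groupby("patient_id", sort=False):
        grp = grp.sort_values("day")
        series = ExpansionSeries(
            str(pid), grp["day"].to_numpy(), grp["copies_per_ug"].to_numpy()
        )
        cmax, tmax = compute_cmax(series)
        summary = ExpansionSummary(
            patient_id=str(pid),
            cmax=cmax,
            tmax_day=tmax,
            auc_0_28=compute_auc_0_28(series),
            persistence_wk4=persistence_at_week(series, week=4),
        )
        rows.append(vars(summary))
    return pd.DataFrame(rows)
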