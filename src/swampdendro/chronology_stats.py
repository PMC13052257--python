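"""Chronology quality statistics: mean sensitivity, rbar, EPS.

Mean sensitivity (MS) measures year-to-year variability on a 0..2 scale;
series intercorrelation (rbar, often written r_xy) is the average Pearson
correlation of each series with the master chronology built from the other
series; the expressed population signal EPS = n*rbar / (n*rbar + 1 - rbar)
estimates how much of the hypothetical population signal the sampled n
series capture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from swampdendro.detrending import DetrendedSeries, biweight_mean

__all__ = [
    "ChronologyQuality",
    "mean_sensitivity",
    "series_intercorrelation",
    "eps",
    "classify_sensitivity",
    "chronology_quality",
]

MIN_OVERLAP = 10


@dataclass
class ChronologyQuality:
    mean_sensitivity: float
    rbar: float
    eps: float
    n_series: int

    @property
    def sensitivity_class(self) -> str:
        return classify_sensitivity(self.mean_sensitivity)


def mean_sensitivity(series_values) -> float:
    """Mean sensitivity of one series.

    MS = (1/(n-1)) * sum_t |2 (x_t - x_{t-1}) / (x_t + x_{t-1})|; adjacent
    pairs summing to zero (two absent rings) are skipped with a warning.
    Bounded by [0, 2]; scale invariant.
    """
    x = np.asarray(series_values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("mean sensitivity needs at least 2 values")
    if np.all(x == 0):
        raise ValueError("mean sensitivity undefined for an all-zero series")
    s = x[1:] + x[:-1]
    d = x[1:] - x[:-1]
    ok = s != 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} adjacent pair(s) sum to zero; skipped",
            stacklevel=2,
        )
    return float(np.sum(np.abs(2.0 * d[ok] / s[ok])) / (n - 1))


def series_intercorrelation(detrended_series_list, flavor: str = "standard") -> float:
    """Average correlation of each series with the leave-one-out master.

    For each series the master is the per-year Tukey biweight mean of all
    *other* series (avoiding self-correlation inflation); the Pearson r is
    computed over their overlap, requiring at least 10 common years.  Series
    with insufficient overlap are skipped with a warning; if all are
    skipped an error is raised.

    Accepts ``DetrendedSeries`` objects or a mapping/DataFrame of
    year-indexed value series.
    """
    if isinstance(detrended_series_list, pd.DataFrame):
        table = detrended_series_list
    else:
        table = pd.DataFrame({
            (d.series_id if isinstance(d, DetrendedSeries) else str(i)):
            (d.values(flavor) if isinstance(d, DetrendedSeries) else pd.Series(d))
            for i, d in enumerate(detrended_series_list)
        })
    if table.shape[1] < 2:
        raise ValueError("need at least 2 series")
    rs = []
    for col in table.columns:
        others = table.drop(columns=col)
        master = others.apply(
            lambda row: biweight_mean(row.dropna().to_numpy())
            if row.notna().any() else np.nan,
            axis=1,
        )
        pair = pd.DataFrame({"x": table[col], "y": master}).dropna()
        if len(pair) < MIN_OVERLAP or pair["x"].std() == 0 or pair["y"].std() == 0:
            warnings.warn(f"series {col!r} skipped (insufficient overlap)",
                          stacklevel=2)
            continue
        rs.append(float(np.corrcoef(pair["x"], pair["y"])[0, 1]))
    if not rs:
        raise ValueError("no series had sufficient overlap with the master")
    return float(np.mean(rs))


def eps(rbar: float, n_series: int) -> float:
    """Expressed population signal, EPS = n*rbar / (n*rbar + (1 - rbar)).

    Defined for rbar in (-1, 1]; non-positive rbar gives a value clipped to
    [0, 1] with a warning since the chronology then carries no shared
    signal.
    """
    if n_series < 1:
        raise ValueError("n_series must be >= 1")
    if not -1 < rbar <= 1:
        raise ValueError("rbar must be in (-1, 1]")
    if rbar == 1.0:
        return 1.0
    val = n_series * rbar / (n_series * rbar + (1.0 - rbar))
    if rbar <= 0:
        warnings.warn("rbar <= 0: EPS clipped into [0, 1]", stacklevel=2)
        val = min(max(val, 0.0), 1.0)
    return float(val)


def classify_sensitivity(ms: float) -> str:
    """Interpret a mean-sensitivity value for climate reconstruction.

    Below 0.2 the series varies too little ("low"), 0.2-0.6 is "ideal",
    above 0.6 variability is excessive for reliable crossdating.
    """
    if ms < 0.2:
        return "low"
    if ms <= 0.6:
        return "ideal"
    return "excessive"


def chronology_quality(detrended_series_list, flavor: str = "standard") -> ChronologyQuality:
    """MS (mean across series), rbar and EPS for a set of detrended series.

    MS is computed on the detrended RWI series (the convention of
    crossdating software, which operates on filtered series); pass raw
    widths to :func:`mean_sensitivity` directly for the raw-series variant.
    """
    ms = float(np.mean([
        mean_sensitivity(d.values(flavor).dropna().to_numpy())
        for d in detrended_series_list
    ]))
    rbar = series_intercorrelation(detrended_series_list, flavor=flavor)
    n = len(detrended_series_list)
    return ChronologyQuality(mean_sensitivity=ms, rbar=rbar,
                             eps=eps(rbar, n), n_series=n)
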