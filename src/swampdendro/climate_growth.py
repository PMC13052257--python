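"""Climate/hydrology-growth correlation functions with stationary-bootstrap CIs.

For each environmental variable, 24 monthly predictors (previous-year and
current-year January..December) and 4 seasonal predictors (previous/current
winter January-March and summer June-September) are correlated with the
chronology.  Seasonal windows are sums for precipitation and means for
temperature, VPD and water depth.  Significance comes from a paired
stationary bootstrap (Politis-Romano): geometric block lengths with mean
block ``ceil(n^(1/3))``, resampling (x, y) years jointly, with 2.5/97.5
percentile confidence intervals.  No multiple-testing correction is applied,
matching common dendroclimatology practice; interpret the table accordingly.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from swampdendro.detrending import Chronology
from swampdendro.ringio import MonthlyEnvironment

__all__ = [
    "CorrelationResult",
    "monthly_predictors",
    "stationary_bootstrap_indices",
    "bootstrap_correlation",
    "correlation_function",
]

SEASONS = {"winter": (1, 2, 3), "summer": (6, 7, 8, 9)}
MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
              "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]
MIN_YEARS = 20
MISSING_TOLERANCE = 0.2


@dataclass
class CorrelationResult:
    """Bootstrap correlation of a chronology with one predictor window."""

    variable_name: str
    window: str            # e.g. "prev:Jun", "curr:summer"
    r: float
    ci_low: float
    ci_high: float
    significant: bool
    n_years: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


def _window_label(lag: str, key) -> str:
    if isinstance(key, int):
        return f"{lag}:{MONTH_ABBR[key - 1]}"
    return f"{lag}:{key}"


def monthly_predictors(
    env: MonthlyEnvironment, target_years
) -> pd.DataFrame:
    """Predictor matrix for one variable over the chronology's years.

    Columns are ``"<var>|prev:Jan" .. "<var>|curr:Dec"`` plus the four
    seasonal windows.  A column whose missing fraction over the target
    years exceeds 20% is dropped with a warning; remaining NaN years are
    handled pairwise downstream.
    """
    years = pd.Index(np.asarray(target_years, dtype=int), name="year")
    cols: dict[str, pd.Series] = {}
    for lag, shift in (("prev", 1), ("curr", 0)):
        for month in range(1, 13):
            s = env.monthly(month)
            s = s.reindex(years - shift)
            s.index = years
            cols[f"{env.variable_name}|{_window_label(lag, month)}"] = s
        for season, months in SEASONS.items():
            s = env.seasonal(months)
            s = s.reindex(years - shift)
            s.index = years
            cols[f"{env.variable_name}|{_window_label(lag, season)}"] = s
    out = pd.DataFrame(cols, index=years)
    keep = []
    for c in out.columns:
        if out[c].isna().mean() > MISSING_TOLERANCE:
            warnings.warn(f"predictor {c!r} dropped: >20% missing years",
                          stacklevel=2)
        else:
            keep.append(c)
    return out[keep]


def stationary_bootstrap_indices(
    n: int, n_boot: int, rng: np.random.Generator,
    mean_block: float | None = None,
) -> np.ndarray:
    """(n_boot, n) index matrix of stationary-bootstrap resamples.

    Blocks restart at a uniform position with probability 1/L each step
    (geometric block lengths with mean L, circular wrap), following
    Politis & Romano.  Default L = ceil(n^(1/3)).
    """
    if mean_block is None:
        mean_block = float(np.ceil(n ** (1.0 / 3.0)))
    p = 1.0 / mean_block
    idx = np.empty((n_boot, n), dtype=np.intp)
    idx[:, 0] = rng.integers(0, n, size=n_boot)
    for t in range(1, n):
        restart = rng.random(n_boot) < p
        idx[:, t] = np.where(restart,
                             rng.integers(0, n, size=n_boot),
                             (idx[:, t - 1] + 1) % n)
    return idx


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc * yc).sum(axis=1) / denom


def bootstrap_correlation(
    chronology_values,
    predictor_column,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    variable_name: str = "",
    window: str = "",
) -> CorrelationResult:
    """Pearson correlation with a stationary-bootstrap percentile CI.

    Inputs are aligned on their common (finite) years when passed as
    pandas Series; at least 20 paired years are required.  Deterministic
    under a fixed seed.
    """
    if isinstance(chronology_values, pd.Series) and isinstance(predictor_column, pd.Series):
        pair = pd.DataFrame({"x": chronology_values, "y": predictor_column}).dropna()
        x = pair["x"].to_numpy(float)
        y = pair["y"].to_numpy(float)
    else:
        x = np.asarray(chronology_values, dtype=float)
        y = np.asarray(predictor_column, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
    n = x.size
    if n < MIN_YEARS:
        raise ValueError(f"need at least {MIN_YEARS} paired years, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in chronology or predictor")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = float(_pearson_rows(x[None, :], y[None, :])[0])
    idx = stationary_bootstrap_indices(n, n_boot, rng)
    rb = _pearson_rows(x[idx], y[idx])
    rb = rb[np.isfinite(rb)]
    lo, hi = np.percentile(rb, [2.5, 97.5])
    return CorrelationResult(
        variable_name=variable_name,
        window=window,
        r=r,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0 or hi < 0),
        n_years=n,
    )


def correlation_function(
    chronology: Chronology | pd.Series,
    env_list,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full correlation table over all variables x windows.

    ``env_list`` is an iterable of :class:`MonthlyEnvironment`.  Constant or
    too-short predictor columns are skipped with a warning.  Returns a
    DataFrame with columns variable, window, r, ci_low, ci_high,
    significant, n.  The same seed yields an identical table, and each
    column's bootstrap stream is keyed by its name so results do not
    depend on column order.
    """
    chron = chronology.series if isinstance(chronology, Chronology) else chronology
    rows = []
    for env in env_list:
        pred = monthly_predictors(env, chron.index)
        for col in pred.columns:
            var, window = col.split("|", 1)
            rng = np.random.default_rng(
                [int(seed), zlib.crc32(col.encode("utf8"))]
            )
            try:
                res = bootstrap_correlation(
                    chron, pred[col], n_boot=n_boot, seed=rng,
                    variable_name=var, window=window,
                )
            except ValueError as exc:
                warnings.warn(f"column {col!r} skipped: {exc}", stacklevel=2)
                continue
            rows.append({
                "variable": res.variable_name, "window": res.window,
                "r": res.r, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "significant": res.significant, "n": res.n_years,
            })
    return pd.DataFrame(
        rows, columns=["variable", "window", "r", "ci_low", "ci_high",
                       "significant", "n"]
    )
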