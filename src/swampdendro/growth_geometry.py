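"""Basal area increments, age-class-isolation trends and spatial regressions.

Basal area increment (BAI) converts a one-dimensional ring width into the
annual cross-sectional area added, ``BAI_t = pi r_t^2 - pi r_{t-1}^2`` with
``r_t`` the cumulative radius at the end of year t.  Age Class Isolation
compares the BAI of trees while they pass through the same cambial-age
window (5-year classes centred every 10 years) against calendar time,
separating ontogeny from temporal change.  Spatial regressions relate each
tree's mean age-detrended BAI residual to a landscape distance covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from swampdendro.detrending import age_dependent_spline, MIN_SERIES_LENGTH
from swampdendro.ringio import RingSeries

__all__ = [
    "BAISeries",
    "AgeClassTable",
    "widths_to_bai",
    "age_class_isolation",
    "species_bai_curve",
    "spatial_regression",
    "RegressionSummary",
]

DEFAULT_CLASS_CENTERS = tuple(range(10, 121, 10))
CLASS_HALF_WIDTH = 2.5
MIN_CLASS_YEARS = 3


@dataclass
class BAISeries:
    """Annual basal area increments for one tree (mm^2/year)."""

    series_id: str
    species_code: str
    years: np.ndarray
    bai: np.ndarray
    cumulative_radius: np.ndarray
    cambial_ages: np.ndarray
    distance_covariates: dict


@dataclass
class RegressionSummary:
    """Slope/R^2/p of a simple OLS fit with classical t-test inference."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    stderr: float


@dataclass
class AgeClassTable:
    """Age-class mean BAI through calendar time plus per-class trend fits.

    ``class_means`` has one row per (class_center, year) with the mean BAI
    of trees occupying that cambial-age window that year and the number of
    contributing trees; ``regressions`` maps class center to the OLS of
    class-mean BAI on calendar year.
    """

    class_means: pd.DataFrame
    regressions: dict[int, RegressionSummary]
    excluded_classes: list[int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class_center": c, "slope": r.slope, "intercept": r.intercept,
             "r_squared": r.r_squared, "p_value": r.p_value, "n_years": r.n}
            for c, r in sorted(self.regressions.items())
        ]
        return pd.DataFrame(rows)


def _ols(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None) -> RegressionSummary:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0:
        raise ValueError("regressor has zero variance")
    if weights is None:
        res = stats.linregress(x, y)
        return RegressionSummary(
            slope=float(res.slope), intercept=float(res.intercept),
            r_squared=float(res.rvalue ** 2), p_value=float(res.pvalue),
            n=x.size, stderr=float(res.stderr),
        )
    w = np.asarray(weights, float)
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    sxy = np.sum(w * (x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    dof = x.size - 2
    s2 = np.sum(w * resid ** 2) / dof
    se = np.sqrt(s2 / sxx)
    t = slope / se
    p = 2 * stats.t.sf(abs(t), dof)
    syy = np.sum(w * (y - ym) ** 2)
    return RegressionSummary(
        slope=float(slope), intercept=float(intercept),
        r_squared=float(1 - np.sum(w * resid ** 2) / syy),
        p_value=float(p), n=x.size, stderr=float(se),
    )


def widths_to_bai(series: RingSeries, r0: float | None = None) -> BAISeries:
    """Convert ring widths to basal area increments.

    ``r_t = r_{t-1} + width_t`` with the initial radius ``r0`` defaulting to
    0 (no pith offset); pass an estimated missed-radius to seed it.  The
    arithmetic is exact -- no smoothing -- so with ``r0 = 0`` the increments
    telescope to ``sum(bai) = pi * (sum(widths))^2``.
    """
    if r0 is None:
        r0 = 0.0
    if r0 < 0:
        raise ValueError("r0 must be >= 0")
    radius = r0 + np.cumsum(series.widths)
    prev = np.concatenate([[r0], radius[:-1]])
    bai = np.pi * (radius ** 2 - prev ** 2)
    return BAISeries(
        series_id=series.series_id,
        species_code=series.species_code,
        years=series.years,
        bai=bai,
        cumulative_radius=radius,
        cambial_ages=series.cambial_ages,
        distance_covariates=dict(series.distance_covariates),
    )


def age_class_isolation(
    bai_series_list,
    class_centers=DEFAULT_CLASS_CENTERS,
    half_width: float = CLASS_HALF_WIDTH,
    weighted: bool = False,
) -> AgeClassTable:
    """Age Class Isolation trend analysis.

    Tree-years are assigned to the class whose half-open window
    ``[center - half_width, center + half_width)`` contains their cambial
    age (the windows partition ages, so each tree contributes to a class
    for exactly ``2*half_width`` years).  Per class and calendar year the
    mean BAI across occupying trees is computed, then regressed on calendar
    year by OLS (optionally weighted by the number of contributing trees).
    Classes observed in fewer than 3 distinct calendar years are excluded
    with a warning.
    """
    rows = []
    for b in bai_series_list:
        rows.append(pd.DataFrame({
            "tree": b.series_id, "year": b.years,
            "age": b.cambial_ages, "bai": b.bai,
        }))
    if not rows:
        raise ValueError("no BAI series given")
    long = pd.concat(rows, ignore_index=True)

    means_rows = []
    regressions: dict[int, RegressionSummary] = {}
    excluded: list[int] = []
    for center in class_centers:
        sel = long[(long["age"] >= center - half_width) &
                   (long["age"] < center + half_width)]
        if sel.empty:
            excluded.append(center)
            continue
        per_year = sel.groupby("year").agg(
            mean_bai=("bai", "mean"), n_trees=("tree", "nunique")
        ).reset_index()
        per_year.insert(0, "class_center", center)
        means_rows.append(per_year)
        # a trend needs temporal spread *and* tree replication: one tree
        # walking through a class traces its own 5 years, not a cohort
        if (len(per_year) < MIN_CLASS_YEARS or len(sel) < MIN_CLASS_YEARS
                or sel["tree"].nunique() < 2):
            warnings.warn(
                f"age class {center}: fewer than {MIN_CLASS_YEARS} "
                "calendar years or fewer than 2 trees; regression excluded",
                stacklevel=2,
            )
            excluded.append(center)
            continue
        w = per_year["n_trees"].to_numpy(float) if weighted else None
        try:
            regressions[center] = _ols(
                per_year["year"].to_numpy(float),
                per_year["mean_bai"].to_numpy(float),
                weights=w,
            )
        except ValueError:
            excluded.append(center)
    class_means = (pd.concat(means_rows, ignore_index=True)
                   if means_rows else
                   pd.DataFrame(columns=["class_center", "year",
                                         "mean_bai", "n_trees"]))
    return AgeClassTable(class_means=class_means, regressions=regressions,
                         excluded_classes=excluded)


def species_bai_curve(bai_series_list, initial_stiffness: float = 20.0) -> pd.Series:
    """Species-level ontogenetic BAI curve over cambial age.

    Tree-years are pooled by cambial age, averaged, and the mean-BAI-vs-age
    series is smoothed with the age-dependent spline (initial 20-year
    kernel).  Indexed by cambial age.
    """
    long = pd.concat(
        [pd.DataFrame({"age": b.cambial_ages, "bai": b.bai})
         for b in bai_series_list],
        ignore_index=True,
    )
    mean_by_age = long.groupby("age")["bai"].mean()
    ages = mean_by_age.index.to_numpy(float)
    fit = age_dependent_spline(mean_by_age.to_numpy(), ages,
                               initial_stiffness=initial_stiffness)
    return pd.Series(fit, index=mean_by_age.index)


def spatial_regression(
    bai_series_list,
    covariate_name: str,
    initial_stiffness: float = 20.0,
) -> RegressionSummary:
    """Regress per-tree mean age-detrended BAI residuals on a distance.

    The ontogenetic reference is the species-level age-dependent-spline
    curve of mean BAI versus cambial age (so a tree that persistently
    outgrows same-aged neighbours has positive residuals); the response is
    each tree's mean residual (BAI - curve at its age, mm^2).  Trees
    missing the covariate are dropped with a warning; at least 5 trees
    with a non-constant covariate are required.
    """
    usable = [b for b in bai_series_list if b.bai.size >= MIN_SERIES_LENGTH]
    if len(usable) < 2:
        raise ValueError("need at least 2 usable BAI series")
    curve = species_bai_curve(usable, initial_stiffness=initial_stiffness)
    resp, cov, dropped = [], [], []
    for b in usable:
        d = b.distance_covariates.get(covariate_name)
        if d is None or not np.isfinite(d):
            dropped.append(b.series_id)
            continue
        expected = curve.reindex(b.cambial_ages).to_numpy()
        resid = b.bai - expected
        resp.append(float(np.nanmean(resid)))
        cov.append(float(d))
    if dropped:
        warnings.warn(
            f"{len(dropped)} tree(s) dropped (missing covariate or too "
            f"short): {dropped}",
            stacklevel=2,
        )
    if len(resp) < 5:
        raise ValueError(
            f"covariate {covariate_name!r} present for only {len(resp)} trees"
        )
    x = np.asarray(cov)
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate_name!r} has zero variance")
    return _ols(x, np.asarray(resp))
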