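"""Carbon-isotope discrimination chain: wood delta13C -> Delta13C -> Ci -> iWUE.

The chain follows the Farquhar "simple" discrimination model for C3 leaves.
Bulk-wood delta13C is first corrected for post-photosynthetic fractionation
by subtracting d (2 per-mil by convention; wood is enriched relative to
leaf).  Discrimination against 13C is

    Delta13C = (delta13Ca - delta13C_leaf) / (1 + delta13C_leaf / 1000)

with delta13Ca the isotopic composition of atmospheric CO2 in the year of
wood formation.  Intercellular CO2 follows from

    Delta13C ~= a + (b - a) * Ci / Ca

with a = 4.4 per-mil (slower diffusion of 13CO2 through stomata) and
b = 27 per-mil (Rubisco carboxylation), and the intrinsic water-use
efficiency -- the ratio of assimilation to stomatal conductance -- is

    iWUE = A / gs = (Ca - Ci) / 1.6        [umol CO2 per mol H2O]

where 1.6 is the ratio of the diffusivities of water vapour and CO2 in air.
The chain is algebraically invertible, which the synthetic-data generator
exploits to prescribe iWUE exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from swampdendro.growth_geometry import RegressionSummary, _ols

__all__ = [
    "A_DIFFUSION",
    "B_RUBISCO",
    "GS_RATIO",
    "WOOD_CORRECTION",
    "IWUERecord",
    "delta13c_from_ratios",
    "discrimination",
    "ci_from_discrimination",
    "iwue",
    "iwue_pipeline",
    "delta13c_wood_from_iwue",
    "age_detrend_iwue",
    "iwue_covariate_regressions",
    "default_atmosphere",
]

A_DIFFUSION = 4.4     # per-mil, stomatal diffusion fractionation
B_RUBISCO = 27.0      # per-mil, Rubisco carboxylation fractionation
GS_RATIO = 1.6        # H2O/CO2 diffusivity ratio
WOOD_CORRECTION = 2.0  # per-mil, bulk wood minus leaf tissue


@dataclass
class IWUERecord:
    """One ring's full isotope-derivation record."""

    tree_id: str
    calendar_year: int
    cambial_age: float
    delta13c_wood: float
    delta13c_leaf: float
    big_delta: float
    ci: float
    ca: float
    iwue: float
    nonphysical: bool
    iwue_age_residual: float = np.nan


def delta13c_from_ratios(r_sample: float, r_standard: float) -> float:
    """delta13C (per-mil) from raw 13C/12C ratios: (Rs/Rstd - 1) * 1000."""
    r_sample = np.asarray(r_sample, dtype=float)
    r_standard = np.asarray(r_standard, dtype=float)
    if np.any(r_sample <= 0) or np.any(r_standard <= 0):
        raise ValueError("isotope ratios must be positive")
    out = (r_sample / r_standard - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def discrimination(delta13ca, delta13c_sample):
    """Discrimination Delta13C = (d13Ca - d13Cs) / (1 + d13Cs/1000), per-mil."""
    da = np.asarray(delta13ca, dtype=float)
    ds = np.asarray(delta13c_sample, dtype=float)
    if np.any(ds <= -1000.0):
        raise ValueError("delta13C_sample must exceed -1000 per-mil")
    out = (da - ds) / (1.0 + ds / 1000.0)
    return float(out) if out.ndim == 0 else out


def ci_from_discrimination(big_delta, ca, a: float = A_DIFFUSION,
                           b: float = B_RUBISCO):
    """Intercellular CO2 from discrimination: Ci = Ca (Delta - a)/(b - a).

    Values outside [0, Ca] are physically impossible for the simple model
    but are returned as-is (callers flag them) to preserve the sample
    census for audit.
    """
    if b == a:
        raise ValueError("b must differ from a")
    big_delta = np.asarray(big_delta, dtype=float)
    ca_arr = np.asarray(ca, dtype=float)
    if np.any(ca_arr <= 0):
        raise ValueError("ca must be positive")
    out = ca_arr * (big_delta - a) / (b - a)
    return float(out) if out.ndim == 0 else out


def iwue(ca, ci):
    """Intrinsic water-use efficiency (Ca - Ci)/1.6, umol CO2 / mol H2O."""
    out = (np.asarray(ca, dtype=float) - np.asarray(ci, dtype=float)) / GS_RATIO
    return float(out) if out.ndim == 0 else out


def delta13c_wood_from_iwue(iwue_value, ca, delta13ca,
                            wood_correction_d: float = WOOD_CORRECTION,
                            a: float = A_DIFFUSION, b: float = B_RUBISCO):
    """Exact inverse of the isotope chain: prescribed iWUE -> wood delta13C.

    Used by the synthetic-data generator and for round-trip verification.
    Raises if the implied Ci falls outside (0, Ca), i.e. if the prescribed
    iWUE is outside (0, Ca/1.6).
    """
    iw = np.asarray(iwue_value, dtype=float)
    ca = np.asarray(ca, dtype=float)
    da = np.asarray(delta13ca, dtype=float)
    ci = ca - GS_RATIO * iw
    if np.any(ci <= 0) or np.any(ci >= ca):
        raise ValueError("prescribed iWUE outside the invertible domain (0, Ca/1.6)")
    big_delta = a + (b - a) * ci / ca
    d_leaf = (da - big_delta) / (1.0 + big_delta / 1000.0)
    out = d_leaf + wood_correction_d
    return float(out) if out.ndim == 0 else out


def iwue_pipeline(
    samples: pd.DataFrame,
    atm_history: pd.DataFrame,
    wood_correction_d: float = WOOD_CORRECTION,
    a: float = A_DIFFUSION,
    b: float = B_RUBISCO,
) -> list[IWUERecord]:
    """Run the full delta13C -> iWUE chain on a sample table.

    ``samples`` needs columns ``tree_id, year, cambial_age, d13c``;
    ``atm_history`` is indexed by year with columns ``ca`` (ppm) and
    ``delta13ca`` (per-mil).  Every sample year must be present in the
    history.  Nonphysical Ci (outside [0, Ca]) is flagged, not dropped.
    """
    missing = sorted(set(samples["year"].astype(int)) - set(atm_history.index))
    if missing:
        raise ValueError(f"years missing from atmospheric history: {missing}")
    records = []
    n_nonphys = 0
    for row in samples.itertuples(index=False):
        year = int(row.year)
        ca = float(atm_history.loc[year, "ca"])
        da = float(atm_history.loc[year, "delta13ca"])
        d_leaf = float(row.d13c) - wood_correction_d
        bd = discrimination(da, d_leaf)
        ci = ci_from_discrimination(bd, ca, a=a, b=b)
        nonphys = not (0.0 <= ci <= ca)
        n_nonphys += nonphys
        records.append(IWUERecord(
            tree_id=str(row.tree_id), calendar_year=year,
            cambial_age=float(row.cambial_age),
            delta13c_wood=float(row.d13c), delta13c_leaf=d_leaf,
            big_delta=bd, ci=ci, ca=ca, iwue=iwue(ca, ci),
            nonphysical=nonphys,
        ))
    if n_nonphys:
        warnings.warn(f"{n_nonphys} sample(s) yield nonphysical Ci "
                      "(outside [0, Ca]); flagged, not dropped", stacklevel=2)
    return records


def records_to_frame(records: list[IWUERecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def age_detrend_iwue(
    records: list[IWUERecord], species_map: dict[str, str] | None = None
) -> dict[str, RegressionSummary]:
    """Remove the ontogenetic iWUE trend per species by linear regression.

    Per species (grouped via ``species_map`` from tree_id, or all trees
    together when omitted), iWUE is regressed on cambial age by OLS and the
    residuals are stored on each record's ``iwue_age_residual``.  Requires
    at least 10 records spanning at least 20 years of cambial age per
    species.  Returns the per-species age fits.
    """
    groups: dict[str, list[IWUERecord]] = {}
    for r in records:
        sp = species_map.get(r.tree_id, "all") if species_map else "all"
        groups.setdefault(sp, []).append(r)
    fits: dict[str, RegressionSummary] = {}
    for sp, recs in groups.items():
        ages = np.array([r.cambial_age for r in recs], float)
        vals = np.array([r.iwue for r in recs], float)
        if len(recs) < 10 or np.ptp(ages) < 20:
            raise ValueError(
                f"species {sp!r}: need >= 10 records spanning >= 20 years "
                "of cambial age"
            )
        fit = _ols(ages, vals)
        fits[sp] = fit
        for r in recs:
            r.iwue_age_residual = r.iwue - (fit.intercept + fit.slope * r.cambial_age)
    return fits


def iwue_covariate_regressions(
    records: list[IWUERecord],
    annual_covariates: pd.DataFrame,
    species_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """OLS of iWUE age residuals on annual covariates, per species.

    ``annual_covariates`` is indexed by calendar year with one column per
    covariate (mean annual temperature, total annual precipitation,
    min/max water depth, min/max VPD, Ca, chronology RWI ...).  Species x
    covariate combinations with fewer than 10 joined records are skipped
    with a warning.  Records must have been age-detrended first.
    """
    df = records_to_frame(records)
    if df["iwue_age_residual"].isna().all():
        raise ValueError("run age_detrend_iwue before covariate regressions")
    df["species"] = (
        df["tree_id"].map(species_map).fillna("all") if species_map else "all"
    )
    rows = []
    for sp, grp in df.groupby("species"):
        joined = grp.join(annual_covariates, on="calendar_year")
        for cov in annual_covariates.columns:
            sub = joined[["iwue_age_residual", cov]].dropna()
            if len(sub) < 10:
                warnings.warn(
                    f"{sp} x {cov}: fewer than 10 joined records; skipped",
                    stacklevel=2,
                )
                continue
            if np.ptp(sub[cov].to_numpy()) == 0:
                warnings.warn(f"{sp} x {cov}: constant covariate; skipped",
                              stacklevel=2)
                continue
            fit = _ols(sub[cov].to_numpy(), sub["iwue_age_residual"].to_numpy())
            rows.append({
                "species": sp, "covariate": cov, "slope": fit.slope,
                "r_squared": fit.r_squared, "p_value": fit.p_value,
                "n": fit.n,
            })
    return pd.DataFrame(rows, columns=["species", "covariate", "slope",
                                       "r_squared", "p_value", "n"])


# ---------------------------------------------------------------------------
# atmospheric history
# ---------------------------------------------------------------------------

# Anchor decades for atmospheric CO2 (ppm) and its delta13C (per-mil VPDB).
# Synthetic compilation: smooth annual interpolation through round-number
# anchors that approximate ice-core and flask records (Ca rising from the
# pre-industrial ~277 ppm to ~419 ppm in 2022; the Suess-effect decline of
# delta13Ca from ~-6.4 to ~-8.7 per-mil).  Adequate for method development
# and synthetic studies; substitute a measured compilation for real data.
_ATM_ANCHORS = [
    # year,  ca_ppm, d13ca
    (1700, 276.4, -6.40),
    (1750, 277.8, -6.41),
    (1800, 283.0, -6.44),
    (1850, 285.2, -6.48),
    (1900, 295.7, -6.62),
    (1930, 306.0, -6.70),
    (1950, 311.3, -6.91),
    (1960, 316.9, -6.98),
    (1970, 325.7, -7.15),
    (1980, 338.8, -7.50),
    (1990, 354.4, -7.80),
    (2000, 369.6, -8.02),
    (2010, 389.9, -8.33),
    (2020, 414.2, -8.61),
    (2022, 418.6, -8.67),
]


def default_atmosphere(first_year: int = 1700, last_year: int = 2022) -> pd.DataFrame:
    """Annual atmospheric CO2 history (``ca`` ppm, ``delta13ca`` per-mil).

    A synthetic stand-in built by monotone (PCHIP) interpolation of the
    anchor table above; see the module data for provenance.  Indexed by
    calendar year.
    """
    anchors = np.array(_ATM_ANCHORS, dtype=float)
    years = np.arange(first_year, last_year + 1)
    ca = PchipInterpolator(anchors[:, 0], anchors[:, 1])(years)
    d13 = PchipInterpolator(anchors[:, 0], anchors[:, 2])(years)
    return pd.DataFrame({"ca": ca, "delta13ca": d13},
                        index=pd.Index(years, name="year"))
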