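"""Synthetic ring-width, climate, water-level and isotope data generator.

The generator emulates the statistical structure of a subtropical
seasonally-flooded forest study so every analysis stage is testable without
field data:

* monthly climate (1895-2022) with the Big Cypress-like climatology --
  hot wet summers (~27 C, ~250 mm/month, April-October) and cool dry
  winters (~19 C, ~40 mm/month), a ~0.025 C/yr warming trend since the
  late 1970s, AR(1) interannual anomalies;
* monthly water depth loosely coupled to precipitation (precipitation
  explains only ~5% of depth variance, the rest is independent
  hydrological noise);
* per-tree ring widths: a negative-exponential ontogenetic curve times a
  log-linear climate response ``exp(sum_v beta_v z_v(t))`` times a shared
  year effect and lognormal tree-level noise -- multiplicative so widths
  stay positive and correlation signs are unambiguous;
* decadally subsampled delta13C series obtained by *exactly* inverting the
  discrimination chain from a prescribed iWUE(year, age) trajectory under
  the packaged atmospheric history.

Ground truth (signals, betas, prescribed iWUE) is always returned next to
the generated data so tests can assert recovery.  All outputs are
byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from swampdendro.ringio import MonthlyEnvironment, RingSeries
from swampdendro.isotopes import default_atmosphere, delta13c_wood_from_iwue

__all__ = [
    "SpeciesConfig",
    "SimulationConfig",
    "gen_environment",
    "gen_ring_series",
    "gen_isotope_series",
    "study_config",
    "isotope_sampling_years",
    "calibrate_birth_years",
]

# mean monthly climatology (index 0 = January)
_PROFILES = {
    "tmean": np.array([19.0, 20.0, 22.0, 24.0, 26.0, 27.0,
                       27.5, 27.5, 27.0, 25.0, 22.0, 20.0]),   # degC
    "ppt": np.array([35.0, 40.0, 50.0, 80.0, 160.0, 230.0,
                     245.0, 240.0, 230.0, 140.0, 50.0, 40.0]),  # mm
    "vpdmin": np.array([2.0, 2.0, 3.0, 4.0, 5.0, 6.0,
                        6.0, 6.0, 6.0, 5.0, 3.0, 2.0]),         # hPa
    "vpdmax": np.array([18.0, 20.0, 24.0, 28.0, 30.0, 26.0,
                        24.0, 23.0, 22.0, 21.0, 19.0, 18.0]),   # hPa
    "water_depth": np.array([220.0, 205.0, 190.0, 170.0, 165.0, 180.0,
                             210.0, 240.0, 270.0, 280.0, 260.0, 240.0]),  # cm
}
_TEMP_OFFSETS = {"tmin": -6.0, "tmax": +6.0}

#: month-to-month AR(1) persistence and stationary sd of monthly anomalies
#: (hydrology carries much more memory than the atmosphere)
_MONTH_PHI = {"tmean": 0.5, "ppt": 0.2, "vpdmin": 0.5, "vpdmax": 0.5,
              "water_depth": 0.85}
_MONTH_SD = {"tmean": 0.8,          # degC
             "ppt": 0.35,           # multiplicative fraction
             "vpdmin": 0.6, "vpdmax": 2.0,   # hPa
             "water_depth": 30.0}   # cm
_TMINMAX_EXTRA_SD = 0.3      # degC, independent tmin/tmax wiggle
_WATER_PPT_COUPLING = 5.7    # cm per sd of annual precipitation anomaly

ISOTOPE_DECADAL = tuple(range(2020, 1879, -10)) + (1860, 1840, 1820, 1800)


@dataclass
class SpeciesConfig:
    """Simulation settings for one species.

    ``sensitivity`` maps predictor windows to log-growth coefficients; a
    key is ``"<variable>:<m1>-<m2>"`` for a current-year seasonal window
    (mean for temperature/VPD/water depth, sum for precipitation, months
    inclusive), optionally prefixed ``prev:`` for the previous year.  The
    window aggregate is standardized over the simulation period before the
    coefficient is applied.

    The iWUE trajectory is ``iwue_base`` (at the reference year 1930) plus
    ``iwue_year_trend`` per year after 1930, plus ``iwue_age_slope`` per
    year of cambial age, plus ``iwue_temp_effect`` per degC of annual
    temperature anomaly, plus Gaussian noise.
    """

    code: str
    n_trees: int
    birth_range: tuple[int, int]
    birth_years: list[int] | None = None  # explicit births override the range
    w0: float = 2.0            # mm, juvenile increment above asymptote
    decay: float = 40.0        # yr, ontogenetic e-folding time
    asymptote: float = 0.5     # mm, mature increment
    sensitivity: dict[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.3   # lognormal sigma, tree-year noise
    common_sigma: float = 0.2  # shared year-effect sigma (log scale)
    cohort_effect: float = 0.0  # log-growth shift per century of birth year
    spatial_effect: dict[str, float] = field(default_factory=dict)
    iwue_base: float = 58.0
    iwue_year_trend: float = 0.22
    iwue_age_slope: float = -0.05
    iwue_temp_effect: float = 0.0
    iwue_noise_sigma: float = 3.0
    n_isotope_trees: int = 16
    isotope_census: int | None = None


@dataclass
class SimulationConfig:
    """Whole-simulation settings; defaults are the study conditions."""

    seed: int = 0
    first_year: int = 1895
    last_year: int = 2022
    species: list[SpeciesConfig] = field(default_factory=list)
    climate_noise: float = 1.0       # scale on all interannual/monthly noise
    warming_rate: float = 0.025      # degC/yr applied to t* after trend_start
    trend_start: int = 1978
    vpd_trend: float = 0.02          # hPa/yr on vpdmax after trend_start

    def to_dict(self) -> dict:
        return asdict(self)


def study_config(seed: int = 0) -> SimulationConfig:
    """Default three-species configuration emulating the field study.

    22 pond cypress (TAAS, the oldest and slowest-growing), 26 bald cypress
    (TADI) and 26 slash pine (PIEL); cypress growth responds to summer
    (June-September) water depth, pine to late-dry-season (April-May) water
    depth; ontogeny parameters chosen so mean ring widths fall near 0.8,
    2.7 and 3.1 mm/yr respectively.  The first 16 trees of each species
    form the isotope subsample; their birth years are calibrated so the
    decadal sampling census is exactly 167 (TAAS), 133 (TADI) and 116
    (PIEL) samples.
    """

    def births(n, rng_, census):
        iso = calibrate_birth_years(16, rng_, census)
        extra = np.linspace(rng_[0], rng_[1], n - 16).round().astype(int)
        return iso + list(extra)

    return SimulationConfig(
        seed=seed,
        species=[
            SpeciesConfig(
                code="TAAS", n_trees=22, birth_range=(1733, 1970),
                birth_years=births(22, (1733, 1970), 167),
                w0=1.05, decay=40.0, asymptote=0.48,
                sensitivity={"water_depth:6-9": 0.15},
                iwue_temp_effect=1.0,
                isotope_census=167,
            ),
            SpeciesConfig(
                code="TADI", n_trees=26, birth_range=(1803, 1976),
                birth_years=births(26, (1803, 1976), 133),
                w0=2.1, decay=40.0, asymptote=1.70,
                sensitivity={"water_depth:6-9": 0.25},
                iwue_temp_effect=1.0,
                isotope_census=133,
            ),
            SpeciesConfig(
                code="PIEL", n_trees=26, birth_range=(1860, 1976),
                birth_years=births(26, (1860, 1976), 116),
                w0=3.15, decay=30.0, asymptote=1.85,
                sensitivity={"water_depth:4-5": 0.15},
                iwue_temp_effect=1.0,
                isotope_census=116,
            ),
        ],
    )


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    e = rng.standard_normal(n) * sigma
    if sigma == 0:
        return e
    z = np.empty(n)
    z[0] = e[0] / np.sqrt(1 - phi ** 2)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + e[t]
    return z


def _monthly_chain(rng, n_years: int, var: str, scale: float) -> np.ndarray:
    """(n_years, 12) AR(1) anomaly chain running across consecutive months."""
    phi = _MONTH_PHI[var]
    innov = _MONTH_SD[var] * scale * np.sqrt(1.0 - phi ** 2)
    return _ar1(rng, n_years * 12, phi, innov).reshape(n_years, 12)


def gen_environment(config: SimulationConfig) -> dict[str, MonthlyEnvironment]:
    """Generate the full set of monthly environment variables.

    Returns a dict of MonthlyEnvironment keyed by variable name (ppt, tmin,
    tmean, tmax, vpdmin, vpdmax, water_depth).  Anomalies are AR(1) chains
    over consecutive months (hydrology far more persistent than the
    atmosphere), so seasonal windows carry distinct information; water
    depth gets a weak additional coupling to annual precipitation.  With
    ``climate_noise = 0`` and zero trends the series are exactly periodic.
    """
    rng = np.random.default_rng([config.seed, 101])
    years = np.arange(config.first_year, config.last_year + 1)
    n = years.size
    k = config.climate_noise
    trend = np.maximum(0, years - config.trend_start)

    out: dict[str, MonthlyEnvironment] = {}

    def build(var, vals):
        df = pd.DataFrame(vals, index=years, columns=range(1, 13))
        units = {"ppt": "mm", "water_depth": "cm"}.get(
            var, "hPa" if var.startswith("vpd") else "degC")
        out[var] = MonthlyEnvironment(variable_name=var, units=units, values=df)

    t_anom = _monthly_chain(rng, n, "tmean", k)
    warm = (config.warming_rate * trend)[:, None]
    build("tmean", _PROFILES["tmean"][None, :] + t_anom + warm)
    for which, off in _TEMP_OFFSETS.items():
        extra = rng.standard_normal((n, 12)) * _TMINMAX_EXTRA_SD * k
        build(which, _PROFILES["tmean"][None, :] + off + t_anom + extra + warm)

    ppt_frac = _monthly_chain(rng, n, "ppt", k)
    build("ppt", np.maximum(_PROFILES["ppt"][None, :] * (1.0 + ppt_frac), 0.0))

    build("vpdmin", _PROFILES["vpdmin"][None, :] +
          _monthly_chain(rng, n, "vpdmin", k))
    build("vpdmax", _PROFILES["vpdmax"][None, :] +
          _monthly_chain(rng, n, "vpdmax", k) +
          (config.vpd_trend * trend)[:, None])

    # water depth: persistent hydrological chain plus a weak coupling to
    # the year's precipitation (a few percent of annual depth variance)
    w_anom = _monthly_chain(rng, n, "water_depth", k)
    ppt_annual = ppt_frac.mean(axis=1)
    sd = ppt_annual.std()
    ppt_std = ppt_annual / sd if sd > 0 else np.zeros(n)
    build("water_depth", _PROFILES["water_depth"][None, :] + w_anom +
          (_WATER_PPT_COUPLING * k * ppt_std)[:, None])
    return out


def _parse_sensitivity_key(key: str) -> tuple[str, tuple[int, ...], int]:
    """``"prev:water_depth:6-9"`` -> (variable, months, lag_years)."""
    lag = 0
    if key.startswith("prev:"):
        lag = 1
        key = key[len("prev:"):]
    var, span = key.split(":")
    m1, m2 = (int(x) for x in span.split("-")) if "-" in span else (int(span),) * 2
    return var, tuple(range(m1, m2 + 1)), lag


def climate_signal(
    species: SpeciesConfig,
    environment: dict[str, MonthlyEnvironment],
    years: np.ndarray,
) -> tuple[pd.Series, dict[str, pd.Series]]:
    """Deterministic log-growth signal sum(beta_v z_v) over ``years``."""
    total = pd.Series(0.0, index=years)
    zs: dict[str, pd.Series] = {}
    for key, beta in species.sensitivity.items():
        var, months, lag = _parse_sensitivity_key(key)
        agg = environment[var].seasonal(months)
        z = (agg - agg.mean()) / agg.std()
        z = z.reindex(np.asarray(years) - lag)
        z.index = years
        zs[key] = z
        total = total + beta * z.fillna(0.0)
    return total, zs


def gen_ring_series(
    config: SimulationConfig,
    environment: dict[str, MonthlyEnvironment],
) -> tuple[list[RingSeries], dict]:
    """Generate ring-width series for every configured species.

    ``width(t) = (w0 exp(-age/decay) + asymptote) * exp(signal + eta_year +
    spatial + eps)`` with eps ~ N(0, noise_sigma) i.i.d. per tree-year and
    eta a shared year effect.  Returns ``(series_list, ground_truth)``;
    ground truth holds per-species signals, z-scores, betas and the shared
    year effects.
    """
    rng = np.random.default_rng([config.seed, 202])
    all_years = np.arange(config.first_year, config.last_year + 1)
    series: list[RingSeries] = []
    truth: dict = {"species": {}}
    for sp in config.species:
        signal, zs = climate_signal(sp, environment, all_years)
        eta = pd.Series(rng.standard_normal(all_years.size) * sp.common_sigma,
                        index=all_years)
        if sp.n_trees == 0:
            truth["species"][sp.code] = {
                "signal": signal, "z": zs, "betas": dict(sp.sensitivity),
                "eta": eta, "growth_factor": np.exp(signal + eta),
                "trees": {},
            }
            continue
        if sp.birth_years is not None:
            if len(sp.birth_years) != sp.n_trees:
                raise ValueError(f"{sp.code}: birth_years length != n_trees")
            births = np.asarray(sp.birth_years, dtype=int)
        else:
            births = np.linspace(sp.birth_range[0], sp.birth_range[1],
                                 sp.n_trees).round().astype(int)
        tree_meta = {}
        for i, birth in enumerate(births):
            sid = f"{sp.code}{i + 1:02d}"
            # rings start at the pith even before the environment record
            # begins; the climate signal is simply zero there
            years = np.arange(birth, config.last_year + 1)
            ages = years - birth + 1
            onto = sp.w0 * np.exp(-ages / sp.decay) + sp.asymptote
            covs = {
                "dist_to_road": float(rng.uniform(700, 5000)),
                "dist_to_dome": float(rng.uniform(5, 150)),
                "dist_to_edge": float(rng.uniform(5, 300)),
            }
            spatial = sp.cohort_effect * (birth - np.mean(births)) / 100.0
            for cov_name, beta in sp.spatial_effect.items():
                span = {"dist_to_road": 5000.0, "dist_to_dome": 150.0,
                        "dist_to_edge": 300.0}.get(cov_name, 1.0)
                spatial += beta * (covs[cov_name] / span - 0.5)
            eps = rng.standard_normal(years.size) * sp.noise_sigma
            logmod = (signal.reindex(years).fillna(0.0).to_numpy()
                      + eta.reindex(years).fillna(0.0).to_numpy()
                      + spatial + eps)
            widths = onto * np.exp(logmod)
            series.append(RingSeries(
                series_id=sid, species_code=sp.code, first_year=int(birth),
                widths=widths, distance_covariates=covs,
            ))
            tree_meta[sid] = {"birth": int(birth), "spatial_logeffect": spatial}
        truth["species"][sp.code] = {
            "signal": signal, "z": zs, "betas": dict(sp.sensitivity),
            "eta": eta, "growth_factor": np.exp(signal + eta),
            "trees": tree_meta,
        }
    return series, truth


def isotope_sampling_years(first_year: int, last_year: int) -> list[int]:
    """Decadal sampling years (2020, 2010, ... 1880, then every 20 years
    back to 1800) that fall within a tree's lifespan."""
    return sorted(y for y in ISOTOPE_DECADAL if first_year <= y <= last_year)


def calibrate_birth_years(
    n_trees: int, birth_range: tuple[int, int], target_samples: int,
    last_year: int = 2022,
) -> list[int]:
    """Deterministic birth years whose decadal sampling hits a census.

    Starts from evenly spaced births and nudges individual trees by decades
    until the total number of isotope samples equals ``target_samples``.
    """
    births = list(np.linspace(birth_range[0], birth_range[1],
                              n_trees).round().astype(int))

    def total(bs):
        return sum(len(isotope_sampling_years(b, last_year)) for b in bs)

    latest = last_year - 30    # keep every tree at least 30 years old
    earliest = birth_range[0] - 100
    guard = 0
    while total(births) != target_samples:
        diff = total(births) - target_samples
        order = np.argsort(births)
        moved = False
        for step in range(n_trees):
            i = int(order[(guard + step) % n_trees])
            if diff > 0 and births[i] + 10 <= latest:
                births[i] += 10     # too many samples: age this tree later
                moved = True
                break
            if diff < 0 and births[i] - 10 >= earliest:
                births[i] -= 10     # too few: push this birth earlier
                moved = True
                break
        guard += 1
        if not moved or guard > 200 * n_trees:
            raise ValueError("could not calibrate birth years to census")
    return births


def _select_isotope_trees(trees: list[RingSeries], sp: SpeciesConfig) -> list[RingSeries]:
    """Choose the isotope subsample for one species.

    Defaults to the first ``n_isotope_trees``; when ``isotope_census`` is
    set, trees are swapped in/out (keeping the subsample size) until the
    total number of decadal samples matches the census exactly.
    """
    counts = [len(isotope_sampling_years(t.first_year, t.last_year))
              for t in trees]
    k = min(sp.n_isotope_trees, len(trees))
    selected = list(range(k))
    if sp.isotope_census is None or not trees:
        return [trees[i] for i in selected]
    target = sp.isotope_census
    for _ in range(10 * len(trees)):
        diff = sum(counts[i] for i in selected) - target
        if diff == 0:
            break
        best = None
        for i in selected:
            for j in range(len(trees)):
                if j in selected:
                    continue
                new = abs(diff - counts[i] + counts[j])
                if best is None or new < best[0]:
                    best = (new, i, j)
        if best is None or best[0] >= abs(diff):
            raise ValueError(
                f"{sp.code}: cannot reach isotope census {target} "
                f"with {k} of {len(trees)} trees"
            )
        selected.remove(best[1])
        selected.append(best[2])
    else:
        raise ValueError(f"{sp.code}: isotope census search did not converge")
    return [trees[i] for i in sorted(selected)]


def gen_isotope_series(
    config: SimulationConfig,
    trees: list[RingSeries],
    atm_history: pd.DataFrame | None = None,
    environment: dict[str, MonthlyEnvironment] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a decadally subsampled delta13C wood table.

    The first ``n_isotope_trees`` of each species are sampled at the
    decadal years within their lifespan.  The prescribed
    iWUE(year, age) -- trajectory parameters in each SpeciesConfig -- is
    inverted *exactly* through the discrimination chain (including the
    2 per-mil wood correction) to delta13C_wood, so running the analysis
    pipeline recovers the prescription to numerical precision when noise
    is zero.

    Returns ``(samples, ground_truth)`` where samples has columns
    ``tree_id, year, cambial_age, d13c``.
    """
    if atm_history is None:
        atm_history = default_atmosphere(1700, config.last_year)
    temp_anom = None
    if environment is not None and "tmean" in environment:
        annual = environment["tmean"].values.mean(axis=1)
        temp_anom = annual - annual.mean()
    rng = np.random.default_rng([config.seed, 303])
    by_species: dict[str, list[RingSeries]] = {}
    for t in trees:
        by_species.setdefault(t.species_code, []).append(t)
    rows = []
    truth: dict = {"species": {}}
    for sp in config.species:
        pool = _select_isotope_trees(by_species.get(sp.code, []), sp)
        sp_truth = {"params": {
            "base": sp.iwue_base, "year_trend": sp.iwue_year_trend,
            "age_slope": sp.iwue_age_slope,
            "temp_effect": sp.iwue_temp_effect,
            "noise_sigma": sp.iwue_noise_sigma,
        }, "samples": []}
        for tree in pool:
            for year in isotope_sampling_years(tree.first_year, tree.last_year):
                age = year - tree.first_year + 1 + tree.pith_offset
                iw = (sp.iwue_base
                      + sp.iwue_year_trend * max(0, year - 1930)
                      + sp.iwue_age_slope * age)
                if temp_anom is not None and year in temp_anom.index:
                    iw += sp.iwue_temp_effect * float(temp_anom.loc[year])
                iw += rng.standard_normal() * sp.iwue_noise_sigma
                ca = float(atm_history.loc[year, "ca"])
                da = float(atm_history.loc[year, "delta13ca"])
                d13c = delta13c_wood_from_iwue(iw, ca, da)
                rows.append({"tree_id": tree.series_id, "year": year,
                             "cambial_age": float(age), "d13c": d13c})
                sp_truth["samples"].append(
                    {"tree_id": tree.series_id, "year": year,
                     "age": age, "iwue": iw})
        truth["species"][sp.code] = sp_truth
    samples = pd.DataFrame(rows, columns=["tree_id", "year",
                                          "cambial_age", "d13c"])
    return samples, truth
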