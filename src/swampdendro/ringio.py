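"""Readers and writers for ring-width and monthly-environment tables.

Ring widths travel in the Tucson decadal (``.rwl``) format used by the ITRDB.
Two end-marker dialects circulate in public archives and both are supported:
a ``999`` terminator means values are hundredths of a millimetre, a ``-9999``
terminator means thousandths.  Monthly climate/water tables and per-ring
isotope samples are plain long-form CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RingSeries",
    "MonthlyEnvironment",
    "RwlParseError",
    "read_rwl",
    "write_rwl",
    "read_monthly_table",
    "read_isotope_table",
]

#: divisor converting stored integers to millimetres, keyed by terminator
_DIALECTS = {999: 100.0, -9999: 1000.0}


class RwlParseError(ValueError):
    """Raised when a Tucson-format file cannot be decoded."""


@dataclass
class RingSeries:
    """One tree's dated annual ring widths.

    Parameters
    ----------
    series_id:
        Core/tree identifier (at most 8 characters in Tucson files).
    species_code:
        Species tag such as ``TAAS``, ``TADI`` or ``PIEL``; free text.
    first_year:
        Calendar year CE of the innermost measured ring.
    widths:
        Ring widths in mm/year, one per calendar year.  A width of 0.0
        encodes a locally absent ring; widths are never negative.
    pith_offset:
        Estimated number of rings missed between the innermost measured
        ring and the pith (>= 0).
    distance_covariates:
        Optional named distances in metres (e.g. ``dist_to_road``).
    """

    series_id: str
    species_code: str
    first_year: int
    widths: np.ndarray
    pith_offset: int = 0
    distance_covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size == 0:
            raise ValueError("widths must be a nonempty 1-D array")
        if not np.all(np.isfinite(self.widths)):
            raise ValueError(f"series {self.series_id}: non-finite width")
        if np.any(self.widths < 0):
            raise ValueError(f"series {self.series_id}: negative ring width")
        if self.pith_offset < 0:
            raise ValueError("pith_offset must be >= 0")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def cambial_ages(self) -> np.ndarray:
        """Cambial age of each ring: y - first_year + 1 + pith_offset."""
        return np.arange(1, len(self.widths) + 1) + self.pith_offset

    @property
    def absent_rings(self) -> np.ndarray:
        """Calendar years whose ring is locally absent (width 0)."""
        return self.years[self.widths == 0.0]


@dataclass
class MonthlyEnvironment:
    """A year x 12 matrix of one monthly climate or hydrology variable.

    ``values`` is a DataFrame indexed by calendar year with integer columns
    1..12; missing months are NaN.  A year is present iff at least one of
    its months is non-missing.
    """

    variable_name: str
    units: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values.copy()
        df.columns = [int(c) for c in df.columns]
        if list(df.columns) != list(range(1, 13)):
            df = df.reindex(columns=range(1, 13))
        df = df.astype(float).sort_index()
        df = df.loc[df.notna().any(axis=1)]
        self.values = df

    @property
    def years(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def monthly(self, month: int) -> pd.Series:
        """One month's values across years."""
        if not 1 <= month <= 12:
            raise ValueError("month must be in 1..12")
        return self.values[month]

    def seasonal(self, months: tuple[int, ...], how: str | None = None) -> pd.Series:
        """Aggregate a window of months per year.

        Precipitation windows are summed, everything else is averaged,
        following standard climate-growth practice; pass ``how`` to
        override.  Years with any missing month in the window are NaN.
        """
        if how is None:
            how = "sum" if self.variable_name == "ppt" else "mean"
        block = self.values[list(months)]
        out = block.sum(axis=1) if how == "sum" else block.mean(axis=1)
        out[block.isna().any(axis=1)] = np.nan
        return out


# ---------------------------------------------------------------------------
# Tucson .rwl
# ---------------------------------------------------------------------------

def read_rwl(path, species_code: str = "") -> list[RingSeries]:
    """Read a decadal Tucson ``.rwl`` file.

    The precision dialect is auto-detected per series from its terminator:
    ``999`` means hundredths of a millimetre and ``-9999`` thousandths.
    Lines starting with ``#`` and the optional three-line ITRDB header are
    skipped.  Years must be contiguous within a series.
    """
    raw: dict[str, list[tuple[int, list[int], int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or not rest:
                raise RwlParseError(f"{path}: line {lineno}: malformed decade line")
            try:
                year = int(rest[0])
                vals = [int(v) for v in rest[1:]]
            except ValueError as exc:
                raise RwlParseError(
                    f"{path}: line {lineno}: malformed decade line ({exc})"
                ) from None
            # at most 10 measurements per decade line, plus an optional
            # trailing terminator
            if len(vals) > 11 or (len(vals) == 11 and vals[-1] not in _DIALECTS):
                raise RwlParseError(
                    f"{path}: line {lineno}: more than 10 values on a decade line"
                )
            raw.setdefault(sid, []).append((year, vals, lineno))
            if sid not in order:
                order.append(sid)

    out: list[RingSeries] = []
    seen: set[str] = set()
    for sid in order:
        if sid in seen:
            raise RwlParseError(f"{path}: duplicate series id {sid!r}")
        seen.add(sid)
        chunks = raw[sid]
        values: list[int] = []
        first_year = chunks[0][0]
        expect = first_year
        for year, vals, lineno in chunks:
            if year != expect:
                raise RwlParseError(
                    f"{path}: line {lineno}: series {sid!r} year {year} "
                    f"not contiguous (expected {expect})"
                )
            values.extend(vals)
            expect = (year // 10) * 10 + 10
        term = values[-1]
        if term not in _DIALECTS:
            raise RwlParseError(
                f"{path}: series {sid!r} missing 999/-9999 terminator"
            )
        divisor = _DIALECTS[term]
        widths = np.asarray(values[:-1], dtype=float) / divisor
        if widths.size == 0:
            raise RwlParseError(f"{path}: series {sid!r} has no measurements")
        if np.any(widths < 0):
            raise RwlParseError(f"{path}: series {sid!r} has negative widths")
        out.append(
            RingSeries(series_id=sid, species_code=species_code,
                       first_year=first_year, widths=widths)
        )
    return out


def write_rwl(series_list: list[RingSeries], path, dialect: int = -9999) -> None:
    """Write series to a decadal Tucson file.

    ``dialect`` is the terminator (999 for 0.01 mm precision, -9999 for
    0.001 mm).  Widths that cannot be represented in the 6-character field
    or that collide with the terminator raise ``ValueError``; the
    read/write round trip is the identity at dialect precision.
    """
    if dialect not in _DIALECTS:
        raise ValueError("dialect must be 999 or -9999")
    mult = _DIALECTS[dialect]
    with open(path, "w") as fh:
        for s in series_list:
            ints = np.rint(s.widths * mult).astype(int)
            if np.any(ints >= 100000) or (dialect == 999 and np.any(ints >= 999)):
                raise ValueError(
                    f"series {s.series_id}: width overflows dialect {dialect}"
                )
            year = s.first_year
            vals = list(ints)
            pos = 0
            while pos < len(vals):
                decade_end = (year // 10) * 10 + 10
                take = min(decade_end - year, len(vals) - pos)
                row = vals[pos:pos + take]
                pos += take
                if pos == len(vals):
                    row = row + [dialect]
                fh.write(f"{s.series_id:<8s}{year:4d}" +
                         "".join(f"{v:6d}" for v in row) + "\n")
                year += take


# ---------------------------------------------------------------------------
# long-form CSV tables
# ---------------------------------------------------------------------------

_UNIT_GUESS = {
    "ppt": "mm", "tmin": "degC", "tmean": "degC", "tmax": "degC",
    "vpdmin": "hPa", "vpdmax": "hPa", "water_depth": "cm",
}


def read_monthly_table(path, variable_name: str, units: str | None = None) -> MonthlyEnvironment:
    """Read a long-form ``year,month,value`` CSV into a MonthlyEnvironment.

    Duplicate (year, month) rows and months outside 1..12 are rejected;
    missing months are simply absent rows and become NaN cells.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    for need in ("year", "month"):
        if need not in cols:
            raise ValueError(f"{path}: missing column {need!r}")
    value_col = cols.get("value") or cols.get(variable_name.lower())
    if value_col is None:
        raise ValueError(f"{path}: missing value column")
    year = df[cols["year"]].astype(int)
    month = df[cols["month"]].astype(int)
    if ((month < 1) | (month > 12)).any():
        bad = month[(month < 1) | (month > 12)].iloc[0]
        raise ValueError(f"{path}: month {bad} outside 1..12")
    if df.duplicated(subset=[cols["year"], cols["month"]]).any():
        dup = df[df.duplicated(subset=[cols["year"], cols["month"]])].iloc[0]
        raise ValueError(
            f"{path}: duplicate entry for ({int(dup[cols['year']])}, "
            f"{int(dup[cols['month']])})"
        )
    values = pd.to_numeric(df[value_col], errors="raise").astype(float)
    wide = pd.DataFrame({"year": year, "month": month, "value": values}).pivot(
        index="year", columns="month", values="value"
    )
    units = units or _UNIT_GUESS.get(variable_name, "")
    return MonthlyEnvironment(variable_name=variable_name, units=units, values=wide)


def write_monthly_table(env: MonthlyEnvironment, path) -> None:
    """Write a MonthlyEnvironment back to long-form CSV (NaN rows dropped)."""
    long = env.values.stack().rename("value").reset_index()
    long.columns = ["year", "month", "value"]
    long.to_csv(path, index=False)


def read_isotope_table(path) -> pd.DataFrame:
    """Read a per-ring delta13C sample table.

    Expected columns: ``tree_id, year, cambial_age, d13c`` (wood delta13C in
    per-mil VPDB).  One row per tree x year; values far outside the plausible
    wood range [-35, -15] raise a warning but are kept.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    rename = {}
    for want, aliases in {
        "tree_id": ("tree_id", "tree"),
        "year": ("year", "calendar_year"),
        "cambial_age": ("cambial_age", "age"),
        "d13c": ("d13c", "delta13c", "delta13c_wood", "d13c_wood"),
    }.items():
        for a in aliases:
            if a in cols:
                rename[cols[a]] = want
                break
        else:
            raise ValueError(f"{path}: missing column {want!r}")
    df = df.rename(columns=rename)[["tree_id", "year", "cambial_age", "d13c"]]
    df["year"] = df["year"].astype(int)
    df["cambial_age"] = df["cambial_age"].astype(float)
    df["d13c"] = df["d13c"].astype(float)
    if df.duplicated(subset=["tree_id", "year"]).any():
        raise ValueError(f"{path}: duplicate (tree_id, year) rows")
    outside = (df["d13c"] < -35) | (df["d13c"] > -15)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} delta13C values outside the plausible "
            "wood range [-35, -15] per-mil",
            stacklevel=2,
        )
    return df


def read_covariate_table(path) -> pd.DataFrame:
    """Read per-tree spatial covariates (``tree_id`` plus distance columns, m)."""
    df = pd.read_csv(path)
    if "tree_id" not in {c.lower() for c in df.columns}:
        raise ValueError(f"{path}: missing column 'tree_id'")
    df.columns = [c.lower() for c in df.columns]
    return df.set_index("tree_id")
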