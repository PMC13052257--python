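import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swampdendro.ringio import (
    RingSeries,
    RwlParseError,
    read_rwl,
    write_rwl,
    read_monthly_table,
    read_isotope_table,
    write_monthly_table,
)


def _write(tmp_path, text, name="test.rwl"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadRwl:
    def test_999_dialect_decodes_to_hundredths_mm(self, tmp_path):
        p = _write(tmp_path, "TST01   1990   100   200   999\n")
        (s,) = read_rwl(p)
        assert s.first_year == 1990
        np.testing.assert_allclose(s.widths, [1.00, 2.00])

    def test_minus9999_dialect_decodes_to_thousandths_mm(self, tmp_path):
        p = _write(tmp_path, "TST01   1990   100   200 -9999\n")
        (s,) = read_rwl(p)
        np.testing.assert_allclose(s.widths, [0.100, 0.200])

    def test_multiline_series_contiguous_years(self, tmp_path):
        # decade lines: 1988-1989, then 1990-1992 with terminator
        p = _write(tmp_path,
                   "TST01   1988    50    60\n"
                   "TST01   1990    70    80    90   999\n")
        (s,) = read_rwl(p)
        assert s.first_year == 1988
        assert s.last_year == 1992
        np.testing.assert_allclose(s.widths, [0.5, 0.6, 0.7, 0.8, 0.9])

    def test_zero_value_kept_as_absent_ring(self, tmp_path):
        # hand-decoded fixture: 0 encodes a locally absent ring in 1991
        p = _write(tmp_path, "TST01   1990   100     0   150   999\n")
        (s,) = read_rwl(p)
        np.testing.assert_allclose(s.widths, [1.0, 0.0, 1.5])
        assert list(s.absent_rings) == [1991]

    def test_malformed_line_error_names_line_number(self, tmp_path):
        p = _write(tmp_path, "TST01   1990   100   abc   999\n")
        with pytest.raises(RwlParseError, match="line 1"):
            read_rwl(p)

    def test_noncontiguous_years_rejected(self, tmp_path):
        p = _write(tmp_path,
                   "TST01   1980    50\n"
                   "TST01   2000    70   999\n")
        with pytest.raises(RwlParseError, match="not contiguous"):
            read_rwl(p)

    def test_missing_terminator_rejected(self, tmp_path):
        p = _write(tmp_path, "TST01   1990   100   200\n")
        with pytest.raises(RwlParseError, match="terminator"):
            read_rwl(p)


class TestWriteRwl:
    def test_empty_list_gives_empty_file(self, tmp_path):
        p = tmp_path / "empty.rwl"
        write_rwl([], p)
        assert p.read_text() == ""

    def test_negative_width_rejected_at_construction(self):
        with pytest.raises(ValueError, match="negative"):
            RingSeries("BAD01", "TST", 1990, np.array([1.0, -0.5]))

    def test_overflow_for_999_dialect(self, tmp_path):
        s = RingSeries("BIG01", "TST", 1990, np.full(12, 12.0))
        with pytest.raises(ValueError, match="overflow"):
            write_rwl([s], tmp_path / "big.rwl", dialect=999)

    @pytest.mark.parametrize("dialect,decimals", [(999, 2), (-9999, 3)])
    def test_round_trip_identity(self, tmp_path, rng, dialect, decimals):
        series = [
            RingSeries(f"RT{i:02d}", "TST", 1900 + 7 * i,
                       np.round(rng.uniform(0.0, 9.0, size=25 + i), decimals))
            for i in range(4)
        ]
        p = tmp_path / "rt.rwl"
        write_rwl(series, p, dialect=dialect)
        back = read_rwl(p)
        assert [b.series_id for b in back] == [s.series_id for s in series]
        for s, b in zip(series, back):
            assert b.first_year == s.first_year
            np.testing.assert_allclose(b.widths, s.widths, atol=10 ** -decimals / 2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        first_year=st.integers(1700, 2000),
        widths=st.lists(
            st.integers(0, 9000).map(lambda v: v / 1000.0),
            min_size=1, max_size=60,
        ),
    )
    def test_round_trip_property(self, tmp_path_factory, first_year, widths):
        s = RingSeries("PROP01", "TST", first_year, np.array(widths))
        p = tmp_path_factory.mktemp("rwl") / "prop.rwl"
        write_rwl([s], p, dialect=-9999)
        (b,) = read_rwl(p)
        assert b.first_year == first_year
        np.testing.assert_allclose(b.widths, s.widths, atol=5e-4)


class TestRingSeriesInvariants:
    def test_last_year_and_cambial_age(self):
        s = RingSeries("A", "TST", 1990, np.ones(5), pith_offset=3)
        assert s.last_year == 1994
        assert list(s.cambial_ages) == [4, 5, 6, 7, 8]


class TestMonthlyTable:
    def _csv(self, tmp_path, rows, name="env.csv"):
        p = tmp_path / name
        pd.DataFrame(rows, columns=["year", "month", "value"]).to_csv(
            p, index=False)
        return p

    def test_complete_year(self, tmp_path):
        p = self._csv(tmp_path, [(1990, m, float(m)) for m in range(1, 13)])
        env = read_monthly_table(p, "tmean")
        assert list(env.years) == [1990]
        np.testing.assert_allclose(env.values.loc[1990], np.arange(1, 13))

    def test_duplicate_rejected(self, tmp_path):
        rows = [(1990, m, 1.0) for m in range(1, 13)] + [(1990, 5, 2.0)]
        with pytest.raises(ValueError, match=r"\(1990, 5\)"):
            read_monthly_table(self._csv(tmp_path, rows), "tmean")

    def test_missing_month_is_nan_not_error(self, tmp_path):
        rows = [(1990, m, 1.0) for m in range(1, 13) if m != 6]
        env = read_monthly_table(self._csv(tmp_path, rows), "tmean")
        assert np.isnan(env.values.loc[1990, 6])
        assert env.values.loc[1990].notna().sum() == 11

    def test_month_out_of_range_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="13"):
            read_monthly_table(self._csv(tmp_path, [(1990, 13, 1.0)]), "tmean")

    def test_non_numeric_value_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("year,month,value\n1990,1,oops\n")
        with pytest.raises(ValueError):
            read_monthly_table(p, "tmean")

    def test_seasonal_aggregation_rule(self, tmp_path):
        rows = [(1990, m, {1: 10.0, 2: 20.0, 3: 30.0}.get(m, 5.0))
                for m in range(1, 13)]
        ppt = read_monthly_table(self._csv(tmp_path, rows), "ppt")
        tme = read_monthly_table(self._csv(tmp_path, rows, "t.csv"), "tmean")
        assert ppt.seasonal((1, 2, 3)).loc[1990] == 60.0   # sums
        assert tme.seasonal((1, 2, 3)).loc[1990] == 20.0   # means

    def test_write_read_round_trip(self, tmp_path):
        rows = [(y, m, y + m / 100) for y in (1990, 1991) for m in range(1, 13)]
        env = read_monthly_table(self._csv(tmp_path, rows), "water_depth")
        out = tmp_path / "back.csv"
        write_monthly_table(env, out)
        back = read_monthly_table(out, "water_depth")
        pd.testing.assert_frame_equal(env.values, back.values)


class TestIsotopeTable:
    def test_read_and_warn_outside_plausible_range(self, tmp_path):
        p = tmp_path / "d13c.csv"
        pd.DataFrame({
            "tree_id": ["T1", "T1", "T2"],
            "year": [2000, 2010, 2000],
            "cambial_age": [50, 60, 30],
            "d13c": [-26.0, -27.5, -10.0],  # -10 is implausible for wood
        }).to_csv(p, index=False)
        with pytest.warns(UserWarning, match="plausible"):
            df = read_isotope_table(p)
        assert len(df) == 3

    def test_duplicate_tree_year_rejected(self, tmp_path):
        p = tmp_path / "d13c.csv"
        pd.DataFrame({
            "tree_id": ["T1", "T1"], "year": [2000, 2000],
            "cambial_age": [50, 50], "d13c": [-26.0, -26.5],
        }).to_csv(p, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_isotope_table(p)
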