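import numpy as np
import pandas as pd
import pytest

from swampdendro.isotopes import (
    age_detrend_iwue,
    ci_from_discrimination,
    default_atmosphere,
    delta13c_from_ratios,
    delta13c_wood_from_iwue,
    discrimination,
    iwue,
    iwue_covariate_regressions,
    iwue_pipeline,
    records_to_frame,
)


class TestDelta13c:
    @pytest.mark.parametrize("factor,expected", [
        (1.0, 0.0), (0.99, -10.0), (1.01, 10.0),
    ])
    def test_linear_definition(self, factor, expected):
        assert delta13c_from_ratios(0.0112 * factor, 0.0112) == pytest.approx(
            expected)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            delta13c_from_ratios(-1.0, 0.0112)


class TestDiscrimination:
    def test_equal_compositions_give_zero(self):
        assert discrimination(-8.0, -8.0) == 0.0

    def test_hand_arithmetic_oracle(self):
        # (-8 - (-27)) / (1 - 27/1000) = 19 / 0.973
        assert discrimination(-8.0, -27.0) == pytest.approx(19.0 / 0.973)

    def test_strictly_decreasing_in_sample_delta(self):
        ds = np.linspace(-35.0, -15.0, 50)
        vals = discrimination(-8.0, ds)
        assert np.all(np.diff(vals) < 0)


class TestCiFromDiscrimination:
    def test_boundary_delta_equals_a(self):
        assert ci_from_discrimination(4.4, 400.0) == pytest.approx(0.0)

    def test_boundary_delta_equals_b(self):
        assert ci_from_discrimination(27.0, 400.0) == pytest.approx(400.0)

    def test_oracle_chain_value(self):
        bd = discrimination(-8.0, -27.0)
        ci = ci_from_discrimination(bd, 370.0)
        assert ci == pytest.approx(370.0 * (19.0 / 0.973 - 4.4) / 22.6)
        assert iwue(370.0, ci) == pytest.approx((370.0 - ci) / 1.6)

    def test_degenerate_fractionations_rejected(self):
        with pytest.raises(ValueError):
            ci_from_discrimination(10.0, 400.0, a=5.0, b=5.0)


class TestIwue:
    def test_closed_stomata_limit(self):
        assert iwue(370.0, 0.0) == pytest.approx(370.0 / 1.6)

    def test_ci_equal_ca_gives_zero(self):
        assert iwue(370.0, 370.0) == 0.0


class TestPipeline:
    def _samples(self, years, d13c, tree="T1"):
        return pd.DataFrame({
            "tree_id": tree, "year": years,
            "cambial_age": np.arange(len(years), dtype=float) + 30,
            "d13c": d13c,
        })

    def test_round_trip_recovers_prescribed_iwue(self):
        atm = default_atmosphere()
        years = [1950, 1980, 2010]
        prescribed = [60.0, 75.0, 95.0]
        d13c = [delta13c_wood_from_iwue(w, atm.loc[y, "ca"],
                                        atm.loc[y, "delta13ca"])
                for w, y in zip(prescribed, years)]
        recs = iwue_pipeline(self._samples(years, d13c), atm)
        np.testing.assert_allclose([r.iwue for r in recs], prescribed,
                                   atol=1e-9)

    def test_zero_wood_correction_reduces_to_leaf_computation(self):
        atm = default_atmosphere()
        samples = self._samples([2000], [-27.0])
        (leaf,) = iwue_pipeline(samples, atm, wood_correction_d=0.0)
        bd = discrimination(atm.loc[2000, "delta13ca"], -27.0)
        ci = ci_from_discrimination(bd, atm.loc[2000, "ca"])
        assert leaf.iwue == pytest.approx(iwue(atm.loc[2000, "ca"], ci))

    def test_missing_year_error_names_year(self):
        atm = default_atmosphere(1900, 2000)
        with pytest.raises(ValueError, match="2010"):
            iwue_pipeline(self._samples([2010], [-26.0]), atm)

    def test_nonphysical_ci_flagged_not_dropped(self):
        atm = default_atmosphere()
        # extremely enriched wood pushes Ci below zero
        samples = self._samples([2000], [-5.0])
        with pytest.warns(UserWarning, match="nonphysical"):
            recs = iwue_pipeline(samples, atm)
        assert len(recs) == 1
        assert recs[0].nonphysical

    def test_round_trip_grid_exact(self):
        atm = default_atmosphere()
        deltas = np.linspace(-32.0, -20.0, 7)
        years = [1930, 1970, 2000, 2020]
        for y in years:
            ca = atm.loc[y, "ca"]
            da = atm.loc[y, "delta13ca"]
            for d in deltas:
                one = self._samples([y], [d])
                (rec,) = iwue_pipeline(one, atm)
                if rec.nonphysical:
                    continue
                back = delta13c_wood_from_iwue(rec.iwue, ca, da)
                assert back == pytest.approx(d, abs=1e-9)


class TestAgeDetrend:
    def _records(self, ages, values, years=None, tree="T1"):
        atm = default_atmosphere()
        years = years or [2000] * len(ages)
        recs = []
        samples = pd.DataFrame({
            "tree_id": [f"{tree}{i}" for i in range(len(ages))],
            "year": years, "cambial_age": ages,
            "d13c": [delta13c_wood_from_iwue(v, atm.loc[y, "ca"],
                                             atm.loc[y, "delta13ca"])
                     for v, y in zip(values, years)],
        })
        return iwue_pipeline(samples, atm)

    def test_exactly_linear_iwue_leaves_zero_residuals(self):
        ages = np.linspace(10, 120, 15)
        values = 90.0 - 0.2 * ages
        recs = self._records(ages, values)
        fits = age_detrend_iwue(recs)
        assert fits["all"].slope == pytest.approx(-0.2, abs=1e-9)
        assert np.allclose([r.iwue_age_residual for r in recs], 0.0,
                           atol=1e-9)

    def test_residuals_sum_to_zero(self, rng):
        ages = np.linspace(5, 150, 40)
        values = 80 - 0.1 * ages + rng.standard_normal(40)
        recs = self._records(ages, values)
        age_detrend_iwue(recs)
        assert np.sum([r.iwue_age_residual for r in recs]) == pytest.approx(
            0.0, abs=1e-8)

    def test_degenerate_age_range_rejected(self):
        recs = self._records(np.full(12, 50.0), np.linspace(60, 80, 12))
        with pytest.raises(ValueError, match="cambial age"):
            age_detrend_iwue(recs)


class TestCovariateRegressions:
    def test_self_covariate_gives_r2_one(self, rng):
        ages = np.linspace(5, 150, 30)
        years = list(np.linspace(1900, 2020, 30).round().astype(int))
        atm = default_atmosphere()
        values = 75 + rng.standard_normal(30) * 3
        samples = pd.DataFrame({
            "tree_id": [f"T{i}" for i in range(30)], "year": years,
            "cambial_age": ages,
            "d13c": [delta13c_wood_from_iwue(v, atm.loc[y, "ca"],
                                             atm.loc[y, "delta13ca"])
                     for v, y in zip(values, years)],
        })
        recs = iwue_pipeline(samples, atm)
        age_detrend_iwue(recs)
        df = records_to_frame(recs)
        cov = (df.groupby("calendar_year")["iwue_age_residual"].mean()
               .rename("self").to_frame())
        cov.index.name = None
        table = iwue_covariate_regressions(recs, cov)
        assert table.loc[0, "r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_requires_age_detrend_first(self):
        atm = default_atmosphere()
        samples = pd.DataFrame({
            "tree_id": ["T1"], "year": [2000], "cambial_age": [40.0],
            "d13c": [-26.0]})
        recs = iwue_pipeline(samples, atm)
        with pytest.raises(ValueError, match="age_detrend"):
            iwue_covariate_regressions(recs, pd.DataFrame({"x": [1.0]}))


class TestAtmosphere:
    def test_industrial_era_monotonicity(self):
        atm = default_atmosphere()
        modern = atm.loc[1850:2022]
        assert (np.diff(modern["ca"]) > 0).all()
        assert (np.diff(modern["delta13ca"]) < 0).all()
        assert (atm["ca"] > 250).all()

    def test_iwue_rises_through_20th_century_at_constant_leaf_delta(self):
        # constant delta13C_leaf plus rising Ca implies rising iWUE
        atm = default_atmosphere()
        vals = []
        for y in range(1930, 2021, 10):
            bd = discrimination(atm.loc[y, "delta13ca"], -27.0)
            ci = ci_from_discrimination(bd, atm.loc[y, "ca"])
            vals.append(iwue(atm.loc[y, "ca"], ci))
        assert np.all(np.diff(vals) > 0)
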