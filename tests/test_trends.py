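import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from weedclim.coupling import CouplingConfig
from weedclim.errors import DataError
from weedclim.trends import (LocationSeries, build_location_series,
                             classify_all_locations, coupling_frequency_trend,
                             elevation_trend, high_elevation_flag,
                             location_env_trends, windowed_pca)


class TestHighElevationFlag:
    @pytest.mark.parametrize("elev, expected", [
        (1000.0, False),    # strict reading: must exceed the benchmark
        (1000.1, True),
        (-223.0, False),    # below-sea-level records are valid values
    ])
    def test_strict_default(self, elev, expected):
        assert high_elevation_flag(elev) is expected

    def test_inclusive_variant(self):
        assert high_elevation_flag(1000.0, inclusive=True) is True

    def test_missing_elevation_raises(self):
        with pytest.raises(DataError):
            high_elevation_flag(float("nan"))


def _species_frame(rng, n_per_year=40, years=range(2006, 2023), drift=0.0,
                   base_elev=900.0, sd=200.0):
    rows = []
    for yi, year in enumerate(years):
        elev = rng.normal(base_elev + drift * yi, sd, size=n_per_year)
        rows.append(pd.DataFrame({"year": year, "elevation_m": elev}))
    return pd.concat(rows, ignore_index=True)


class TestElevationTrend:
    def test_constant_zero_indicator_flagged_not_fatal(self, rng):
        df = _species_frame(rng, base_elev=200.0, sd=10.0)
        fit, odds = elevation_trend(df)
        assert fit.separation
        assert odds["separation"]

    def test_planted_drift_detected(self, rng):
        df = _species_frame(rng, drift=25.0)
        fit, odds = elevation_trend(df)
        assert fit.slope > 0
        assert fit.p_wald < 0.05
        assert odds["odds_ratio_total"] > 1.0

    def test_permutation_null_rate(self, rng):
        """Shuffling years against the indicator keeps the Wald test at
        its nominal level."""
        df = _species_frame(rng, drift=0.0)
        y = (df["elevation_m"] > 1000.0).to_numpy(dtype=float)
        t = df["year"].to_numpy(dtype=float)
        from weedclim.stats import fit_logit_trend
        hits = 0
        n_perm = 200
        for _ in range(n_perm):
            fit = fit_logit_trend(t, rng.permutation(y))
            hits += (not fit.separation) and fit.p_wald < 0.05
        assert 0.01 <= hits / n_perm <= 0.11

    def test_single_year_rejected(self, rng):
        df = _species_frame(rng, years=[2010])
        with pytest.raises(DataError):
            elevation_trend(df)


def _loc(lst, rzsm, elev=1200.0):
    lst = np.asarray(lst, dtype=float)
    return LocationSeries(lon=35.0, lat=-5.0, elevation_m=elev,
                          start=(2006, 1), lst_c=lst,
                          rzsm_pct=np.asarray(rzsm, dtype=float))


class TestLocationEnvTrends:
    def test_pure_ramp_has_tau_one(self):
        n = 48
        out = location_env_trends(_loc(np.arange(n), np.linspace(0, 99, n)))
        assert out["lst"].tau == 1.0
        assert out["lst"].p < 1e-6

    def test_short_series_reports_reason(self):
        out = location_env_trends(_loc(np.arange(10), np.arange(10.0)))
        assert not out["lst"].valid
        assert "24" in out["lst"].reason

    def test_planted_cell_trend_recovered(self, world):
        """The generator's designated montane cells carry a wetting trend;
        a stationary lowland cell does not."""
        g = world["grids"]
        elev = g["elev"].values
        des = np.argwhere(elev > 1000.0)
        low = np.argwhere(elev < 600.0)
        iy, ix = des[0]
        ly, lx = low[0]
        mk_wet = location_env_trends(_loc(g["lst"].values[:, iy, ix],
                                          g["rzsm"].values[:, iy, ix]))
        mk_dry = location_env_trends(_loc(g["lst"].values[:, ly, lx],
                                          g["rzsm"].values[:, ly, lx]))
        assert mk_wet["rzsm"].tau > 0 and mk_wet["rzsm"].p < 0.05
        assert abs(mk_dry["rzsm"].tau) < 0.15


class TestCouplingFrequencyTrend:
    def test_rising_coupling_classified_increase(self, rng):
        n = 204
        p = np.linspace(0.05, 0.5, n)
        lst = np.where(rng.random(n) < p, 30.0, 10.0)
        fit, odds, cls = coupling_frequency_trend(_loc(lst, np.full(n, 90.0)))
        assert cls.label == "increase"
        assert odds["odds_ratio_total"] > 1.0

    def test_never_coupling_separation_class_none(self):
        n = 48
        fit, odds, cls = coupling_frequency_trend(
            _loc(np.full(n, 10.0), np.full(n, 90.0)))
        assert fit.separation
        assert cls.label == "none"

    def test_too_few_decidable_months(self):
        n = 30
        lst = np.full(n, 30.0)
        lst[5:] = np.nan
        with pytest.raises(DataError, match="decidable"):
            coupling_frequency_trend(_loc(lst, np.full(n, 90.0)))


class TestClassifyAllLocations:
    def _locs(self, rng, n, p0, p1, elev):
        out = []
        for _ in range(n):
            p = np.linspace(p0, p1, 120)
            lst = np.where(rng.random(120) < p, 30.0, 10.0)
            out.append(_loc(lst, np.full(120, 90.0), elev=elev))
        return out

    def test_all_increasing_is_100pct(self, rng):
        summary, table = classify_all_locations(self._locs(rng, 8, 0.05, 0.7, 1500.0))
        assert summary["above"]["pct_increase"] == 100.0
        assert summary["below"]["n"] == 0
        assert summary["below"]["pct_increase"] is None

    def test_alpha_zero_gates_everything_off(self, rng):
        summary, table = classify_all_locations(
            self._locs(rng, 5, 0.05, 0.7, 1500.0), alpha=0.0)
        assert summary["above"]["pct_increase"] == 0.0
        assert summary["above"]["pct_decrease"] == 0.0
        assert (table["class"] == "none").all()

    def test_percentages_complete_per_stratum(self, rng):
        locs = (self._locs(rng, 4, 0.05, 0.6, 1500.0)
                + self._locs(rng, 6, 0.3, 0.3, 500.0))
        summary, table = classify_all_locations(locs)
        for stratum in ("above", "below"):
            s = summary[stratum]
            assert 0 <= s["pct_increase"] + s["pct_decrease"] <= 100.0


class TestBuildLocationSeries:
    def test_cells_deduplicated_and_aligned(self, world, enriched):
        g = world["grids"]
        focal = enriched[enriched["species"] == "Striga asiatica"]
        locs = build_location_series(focal, g["lst"], g["rzsm"], g["elev"])
        assert 0 < len(locs) <= focal[["lon", "lat"]].drop_duplicates().shape[0]
        coords = {(l.lon, l.lat) for l in locs}
        assert len(coords) == len(locs)
        assert all(l.n_months == g["lst"].n_times for l in locs)


class TestWindowedPCA:
    def test_full_window_equals_unwindowed(self, enriched):
        from weedclim.stats import pca_3var
        focal = enriched[enriched["species"] == "Striga asiatica"]
        res_w = windowed_pca(focal, (2006, 2022))
        cols = focal[["elevation_m", "lst_c_lag1", "rzsm_pct_lag1"]].dropna()
        res_u = pca_3var(cols, variables=list(cols.columns))
        np.testing.assert_allclose(res_w.loadings, res_u.loadings, atol=1e-12)
        np.testing.assert_allclose(res_w.explained, res_u.explained, atol=1e-12)

    def test_late_window_builds_elevation_moisture_alignment(self, enriched):
        """The wetting trend at montane cells is planted from the start but
        accumulates: the late-window elevation/moisture alignment on the
        leading components clearly exceeds the early-window one."""
        focal = enriched[enriched["species"] == "Striga asiatica"]
        def alignment(res):
            # signed elevation-rzsm agreement weighted by explained variance
            l = res.loadings
            return sum(res.explained[j] * l[0, j] * l[2, j] for j in range(3))
        early = windowed_pca(focal, (2006, 2017))
        late = windowed_pca(focal, (2018, 2022))
        assert alignment(late) > alignment(early)
        l1 = late.loadings[:, 0]
        assert np.sign(l1[0]) == np.sign(l1[2])

    def test_empty_window_fails_with_count(self, enriched):
        focal = enriched[enriched["species"] == "Striga asiatica"]
        with pytest.raises(DataError, match="0 complete"):
            windowed_pca(focal, (1990, 1991))
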