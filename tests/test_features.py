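"""Grid operations and predictor-vector assembly."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from xishumid import features as F
from xishumid.features import GridField
from xishumid.observations import STUDY_UTC_OFFSET

DAY = dt.date(2010, 7, 1)


def hourly_field(values, lon=None, lat=None):
    """(24, nlat, nlon) hourly field for one study day."""
    values = np.asarray(values, dtype=float)
    nlat, nlon = values.shape[1:]
    times = [pd.Timestamp(DAY, tz=STUDY_UTC_OFFSET) + pd.Timedelta(hours=h)
             for h in range(values.shape[0])]
    return GridField(
        lon=np.arange(nlon, dtype=float) if lon is None else lon,
        lat=np.arange(nlat, dtype=float) if lat is None else lat,
        time=times, values=values)


class TestAggregate:
    def test_constant_field_every_dv(self):
        h = hourly_field(np.full((24, 2, 3), 287.0))
        t = hourly_field(np.random.default_rng(0).uniform(280, 310, (24, 2, 3)))
        for dv in ("min", "mean", "max"):
            out = F.aggregate_hourly_to_dv(h, t, dv)
            assert out.values == pytest.approx(np.full((1, 2, 3), 287.0))
            assert out.time == [DAY]

    def test_max_analog_takes_humidity_at_temperature_peak(self):
        rng = np.random.default_rng(1)
        h = hourly_field(rng.uniform(280, 300, (24, 1, 1)))
        tvals = np.zeros((24, 1, 1)) + 290.0
        tvals[14] = 305.0  # temperature peaks at hour 14
        t = hourly_field(tvals)
        out = F.aggregate_hourly_to_dv(h, t, "max")
        assert out.values[0, 0, 0] == h.values[14, 0, 0]

    def test_extremum_tie_takes_earliest_hour(self):
        h = hourly_field(np.arange(24, dtype=float).reshape(24, 1, 1))
        tvals = np.full((24, 1, 1), 290.0)
        tvals[[5, 17]] = 280.0  # tied minima
        out = F.aggregate_hourly_to_dv(h, hourly_field(tvals), "min")
        assert out.values[0, 0, 0] == 5.0

    def test_mean_matches_brute_force_average(self):
        rng = np.random.default_rng(2)
        vals = 285.0 + 5 * np.sin(np.arange(24) / 24 * 2 * np.pi)[:, None, None] \
            + rng.normal(0, 1, (24, 3, 4))
        h = hourly_field(vals)
        t = hourly_field(rng.uniform(280, 310, (24, 3, 4)))
        out = F.aggregate_hourly_to_dv(h, t, "mean")
        assert out.values[0] == pytest.approx(vals.mean(axis=0), abs=1e-9)

    def test_commutes_with_constant_shift(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(280, 300, (24, 2, 2))
        t = hourly_field(rng.uniform(280, 310, (24, 2, 2)))
        for dv in ("min", "mean", "max"):
            a = F.aggregate_hourly_to_dv(hourly_field(vals + 2.5), t, dv)
            b = F.aggregate_hourly_to_dv(hourly_field(vals), t, dv)
            assert a.values == pytest.approx(b.values + 2.5, abs=1e-9)

    def test_mismatched_axes_rejected(self):
        h = hourly_field(np.zeros((24, 2, 2)))
        t = hourly_field(np.zeros((24, 2, 3)))
        with pytest.raises(ValueError):
            F.aggregate_hourly_to_dv(h, t, "mean")


def daily_grid(values, lon, lat, qa=None):
    return GridField(lon=np.asarray(lon, float), lat=np.asarray(lat, float),
                     time=[DAY], values=np.asarray(values, float)[None],
                     qa=None if qa is None else np.asarray(qa)[None])


class TestFillFromCoarse:
    def setup_method(self):
        rng = np.random.default_rng(4)
        self.flon = np.arange(0.05, 0.85, 0.1)
        self.flat = np.arange(0.05, 0.65, 0.1)
        self.clon = np.arange(0.1, 0.9, 0.2)
        self.clat = np.arange(0.1, 0.7, 0.2)
        self.fine_vals = rng.uniform(280, 300, (len(self.flat), len(self.flon)))
        self.coarse_vals = rng.uniform(280, 300, (len(self.clat), len(self.clon)))

    def test_fully_present_fine_is_untouched(self):
        fine = daily_grid(self.fine_vals, self.flon, self.flat)
        coarse = daily_grid(self.coarse_vals, self.clon, self.clat)
        out, prov = F.fill_from_coarse(fine, coarse)
        np.testing.assert_array_equal(out.values, fine.values)
        assert (prov == 0).all()

    def test_fully_missing_fine_resampled_from_coarse(self):
        fine = daily_grid(np.full_like(self.fine_vals, np.nan), self.flon, self.flat)
        coarse = daily_grid(self.coarse_vals, self.clon, self.clat)
        out, prov = F.fill_from_coarse(fine, coarse)
        assert (prov == 1).all()
        for i, y in enumerate(self.flat):
            for j, x in enumerate(self.flon):
                ci = np.argmin(np.abs(self.clat - y))
                cj = np.argmin(np.abs(self.clon - x))
                assert out.values[0, i, j] == self.coarse_vals[ci, cj]

    def test_checkerboard_fill_matches_exhaustive_nearest(self):
        vals = self.fine_vals.copy()
        mask = (np.add.outer(np.arange(len(self.flat)),
                             np.arange(len(self.flon))) % 2).astype(bool)
        vals[mask] = np.nan
        fine = daily_grid(vals, self.flon, self.flat)
        coarse = daily_grid(self.coarse_vals, self.clon, self.clat)
        out, prov = F.fill_from_coarse(fine, coarse)
        for i, y in enumerate(self.flat):
            for j, x in enumerate(self.flon):
                if mask[i, j]:
                    ci = np.argmin(np.abs(self.clat - y))
                    cj = np.argmin(np.abs(self.clon - x))
                    assert out.values[0, i, j] == self.coarse_vals[ci, cj]
                    assert prov[0, i, j] == 1
                else:
                    assert out.values[0, i, j] == self.fine_vals[i, j]
                    assert prov[0, i, j] == 0


class TestFilterCwv:
    def test_exhaustive_bitmask_sweep(self):
        qa = np.arange(256).reshape(16, 16)
        field = daily_grid(np.full((16, 16), 1.5), np.arange(16.0),
                           np.arange(16.0), qa=qa)
        out = F.filter_cwv(field)
        kept = np.isfinite(out.values[0])
        np.testing.assert_array_equal(kept, (qa & 0b111) != 3)

    @pytest.mark.parametrize("qa,expect_kept", [
        (0b011, False), (0b010, True), (0b1011, False), (0b100, True),
    ])
    def test_cloud_rule_examples(self, qa, expect_kept):
        field = daily_grid([[2.0]], [0.0], [0.0], qa=[[qa]])
        out = F.filter_cwv(field)
        assert np.isfinite(out.values[0, 0, 0]) == expect_kept

    def test_idempotent_and_never_restores(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 5, (8, 8))
        vals[0, :] = np.nan
        qa = rng.integers(0, 256, (8, 8))
        field = daily_grid(vals, np.arange(8.0), np.arange(8.0), qa=qa)
        once = F.filter_cwv(field)
        twice = F.filter_cwv(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert np.isfinite(once.values).sum() <= np.isfinite(vals).sum()


class TestSampleGrid:
    def test_cell_center_and_outside(self):
        g = daily_grid([[1.0, 2.0], [3.0, 4.0]], [0.0, 1.0], [10.0, 11.0])
        assert F.sample_grid(g, 1.0, 11.0, DAY) == 4.0
        assert np.isnan(F.sample_grid(g, 5.0, 10.0, DAY))  # outside bbox
        assert np.isnan(F.sample_grid(g, 1.0, 11.0, dt.date(2011, 1, 1)))

    def test_matches_exhaustive_nearest_search(self):
        rng = np.random.default_rng(6)
        lon = np.arange(-102.0, -94.0, 0.25)
        lat = np.arange(32.0, 38.0, 0.25)
        vals = rng.uniform(0, 1, (len(lat), len(lon)))
        g = daily_grid(vals, lon, lat)
        for _ in range(50):
            x = rng.uniform(-102.0, -94.2)
            y = rng.uniform(32.0, 37.8)
            i = np.argmin(np.abs(lat - y))
            j = np.argmin(np.abs(lon - x))
            assert F.sample_grid(g, x, y, DAY) == vals[i, j]


class TestAssembly:
    def test_eighteen_feature_slots(self):
        assert len(F.FEATURE_COLUMNS) == 18
        assert F.FEATURE_COLUMNS[0] == "idw"

    def test_constant_grids_give_constant_features(self, small_bundle):
        from xishumid import observations as obsmod
        b = small_bundle
        days = obsmod.derive_station_days(b.observations, obsmod.CleaningConfig())
        grids = b.grids
        const = lambda f, c: GridField(lon=f.lon, lat=f.lat, time=list(f.time),
                                       values=np.full_like(f.values, c))
        bundle_const = F.GridBundle(
            humidity_fine=const(grids.humidity_fine, 288.0),
            temperature_fine=const(grids.temperature_fine, 298.0),
            humidity_coarse=const(grids.humidity_coarse, 288.0),
            temperature_coarse=const(grids.temperature_coarse, 298.0))
        tab = F.assemble_features(days, bundle_const, b.statics, "mean")
        assert tab["era5_humidity_dv"].to_numpy() == pytest.approx(288.0)
        assert tab["era5_temperature_dv"].to_numpy() == pytest.approx(298.0)
        assert tab["cwv_terra"].isna().all()  # no CWV fields supplied

    def test_spot_check_rows_against_recomputation(self, small_bundle, small_table):
        b, tab = small_bundle, small_table
        rng = np.random.default_rng(7)
        statics = b.statics.set_index("station_id")
        for i in rng.choice(len(tab), 10, replace=False):
            row = tab.iloc[i]
            day = row["day"]
            daily = b.grids.daily_dv_grids(day, "mean")
            assert row["era5_humidity_dv"] == pytest.approx(
                daily["era5_humidity_dv"].sample(row.lon, row.lat, day), nan_ok=True)
            cw = F.filter_cwv(b.grids.cwv_terra)
            got = cw.sample(row.lon, row.lat, day)
            assert row["cwv_terra"] == pytest.approx(got, nan_ok=True)
            assert row["elevation_m"] == pytest.approx(
                statics.loc[row.station_id, "elevation_m"])

    def test_deterministic_under_row_shuffle(self, small_bundle):
        from xishumid import observations as obsmod
        b = small_bundle
        days = obsmod.derive_station_days(b.observations, obsmod.CleaningConfig())
        shuffled = days.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = F.assemble_features(days, b.grids, b.statics, "mean")
        c = F.assemble_features(shuffled, b.grids, b.statics, "mean")
        key = ["station_id", "day"]
        a = a.sort_values(key).reset_index(drop=True)
        c = c.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, c)

    def test_missing_static_station_rejected(self, small_bundle):
        from xishumid import observations as obsmod
        b = small_bundle
        days = obsmod.derive_station_days(b.observations, obsmod.CleaningConfig())
        statics = b.statics[b.statics.station_id != days.station_id.iloc[0]]
        with pytest.raises(ValueError, match="lacks stations"):
            F.assemble_features(days, b.grids, statics, "mean")


class TestNetcdfRoundTrip:
    def test_hourly_field(self, tmp_path):
        rng = np.random.default_rng(8)
        field = hourly_field(rng.uniform(280, 300, (24, 3, 4)))
        field.to_netcdf(tmp_path / "f.nc")
        back = GridField.from_netcdf(tmp_path / "f.nc")
        np.testing.assert_allclose(back.values, field.values)
        assert [t.tz_convert("UTC") for t in back.time] == \
            [t.tz_convert("UTC") for t in field.time]

    def test_daily_field_with_qa(self, tmp_path):
        rng = np.random.default_rng(9)
        field = daily_grid(rng.uniform(0, 5, (4, 4)), np.arange(4.0),
                           np.arange(4.0), qa=rng.integers(0, 256, (4, 4)))
        field.to_netcdf(tmp_path / "c.nc")
        back = GridField.from_netcdf(tmp_path / "c.nc", daily=True)
        np.testing.assert_allclose(back.values, field.values)
        np.testing.assert_array_equal(back.qa, field.qa)
        assert back.time == [DAY]
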