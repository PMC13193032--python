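"""Predictor processing: gridded fields and per-station-day feature vectors.

Hourly reanalysis-style grids (a fine field with gaps, backed by a coarser
complete field) are aggregated to daily grids *analogous to the dependent
variable* — the daily mean-humidity model sees the grid's daily mean
humidity, the T-max model sees the grid humidity at each cell's hour of
maximum temperature, and so on. Daily column-water-vapor (CWV) grids carry a
per-cell quality bitmask whose low three bits equal to 3 mark a cloudy pixel
to be discarded. Static covariates (elevation, distance from water,
population density, ...) are joined from a per-station table according to a
named feature registry.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .idw import IdwConfig, idw_training_features

DV_KINDS = ("min", "mean", "max")

#: Cloudy-pixel test: value dropped iff (qa AND 0b111) == 3.
QA_CLOUD_MASK = 0b111
QA_CLOUD_VALUE = 0b011

#: The named static/calendar feature block. ``static`` features come from the
#: per-station statics table; ``coordinate`` from the station-day row itself;
#: ``calendar`` are computed from the day-of-year.
STATIC_FEATURE_REGISTRY: dict[str, str] = {
    "lon": "coordinate",
    "lat": "coordinate",
    "elevation_m": "static",
    "distance_water_km": "static",
    "population_density": "static",
    "isolation_km": "static",
    "slope_m_per_km": "static",
    "vegetation_index": "static",
    "imperviousness": "static",
    "distance_urban_km": "static",
    "water_frac_10km": "static",
    "doy_sin": "calendar",
    "doy_cos": "calendar",
}

GRID_FEATURES = ["era5_humidity_dv", "era5_temperature_dv", "cwv_terra", "cwv_aqua"]

#: Full predictor-vector column order: the IDW feature plus 17 predictors.
FEATURE_COLUMNS = ["idw"] + GRID_FEATURES + list(STATIC_FEATURE_REGISTRY)


@dataclasses.dataclass
class GridField:
    """A regular lon-lat raster time series with nearest-cell lookup.

    ``values`` has shape ``(time, lat, lon)`` with NaN as the missing
    marker; ``time`` is either hourly instants (tz-aware) or daily dates.
    ``qa`` is an optional integer bitmask of the same shape (daily CWV
    fields only).
    """

    lon: np.ndarray  # cell-center axis, strictly increasing, degrees east
    lat: np.ndarray  # cell-center axis, strictly increasing, degrees north
    time: list  # hourly pd.Timestamp or daily datetime.date entries
    values: np.ndarray  # (time, lat, lon), NaN = missing
    qa: np.ndarray | None = None

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        for ax in (self.lon, self.lat):
            if ax.ndim != 1 or len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError("grid axes must be 1-D and strictly increasing")
        if self.values.shape != (len(self.time), len(self.lat), len(self.lon)):
            raise ValueError("values shape does not match (time, lat, lon) axes")
        if self.qa is not None and self.qa.shape != self.values.shape:
            raise ValueError("qa shape must match values")

    # -- lookup -----------------------------------------------------------
    def _nearest_index(self, axis: np.ndarray, x: float) -> int | None:
        half = np.diff(axis).min() / 2.0 if len(axis) > 1 else np.inf
        if x < axis[0] - half or x > axis[-1] + half:
            return None
        # ties between two equidistant centers resolve toward the lower index
        d = np.abs(axis - x)
        return int(np.argmin(d))

    def time_index(self, when) -> int | None:
        try:
            return self.time.index(when)
        except ValueError:
            return None

    def sample(self, lon: float, lat: float, when) -> float:
        """Nearest-cell-center value at a point and time; NaN when outside
        the grid's bounding box, at an unknown time, or masked."""
        ti = self.time_index(when)
        i = self._nearest_index(self.lat, lat)
        j = self._nearest_index(self.lon, lon)
        if ti is None or i is None or j is None:
            return float("nan")
        return float(self.values[ti, i, j])

    # -- xarray / NetCDF bridge ------------------------------------------
    def to_dataset(self, name: str = "value") -> xr.Dataset:
        # NetCDF has no timezone notion: serialize instants as naive UTC
        time = [pd.Timestamp(t).tz_convert("UTC").tz_localize(None)
                if getattr(pd.Timestamp(t), "tzinfo", None) is not None
                else pd.Timestamp(t) for t in self.time]
        ds = xr.Dataset(
            {name: (("time", "lat", "lon"), self.values)},
            coords={"time": time, "lat": self.lat, "lon": self.lon},
        )
        if self.qa is not None:
            ds["qa"] = (("time", "lat", "lon"), self.qa.astype(np.int32))
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset, name: str = "value",
                     daily: bool = False) -> "GridField":
        times = [pd.Timestamp(t) for t in pd.to_datetime(ds["time"].values)]
        if daily:
            time = [t.date() for t in times]
        else:
            from .observations import STUDY_UTC_OFFSET
            time = [t.tz_localize("UTC").tz_convert(STUDY_UTC_OFFSET)
                    for t in times]
        qa = ds["qa"].values.astype(np.int64) if "qa" in ds else None
        return cls(lon=ds["lon"].values, lat=ds["lat"].values, time=time,
                   values=ds[name].values, qa=qa)

    def to_netcdf(self, path, name: str = "value") -> None:
        self.to_dataset(name).to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path, name: str = "value", daily: bool = False) -> "GridField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load(), name=name, daily=daily)


# ---------------------------------------------------------------------------
# grid operations

def aggregate_hourly_to_dv(
    hourly: GridField, temperature_hourly: GridField, dv_kind: str
) -> GridField:
    """Collapse one day of hourly grids to a daily DV-analogous grid.

    ``mean``: plain average over the day's hours per cell. ``min``/``max``:
    the ``hourly`` value at the hour of the cell's *temperature*
    minimum/maximum (earliest hour on ties) — the grid analog of T-min /
    T-max humidity. Pass the temperature field as ``hourly`` itself to
    aggregate temperature.
    """
    if dv_kind not in DV_KINDS:
        raise ValueError(f"dv_kind must be one of {DV_KINDS}")
    if (not np.array_equal(hourly.lon, temperature_hourly.lon)
            or not np.array_equal(hourly.lat, temperature_hourly.lat)
            or hourly.time != temperature_hourly.time):
        raise ValueError("humidity and temperature grids must share axes")
    days = sorted({t.date() for t in hourly.time})
    if len(days) != 1:
        raise ValueError("aggregate one study day at a time")
    if dv_kind == "mean":
        ok = np.isfinite(hourly.values)
        cnt = ok.sum(axis=0)
        total = np.where(ok, hourly.values, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            out = np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)[None]
    else:
        tv = temperature_hourly.values
        # NaN temperatures never win the extremum; all-NaN columns stay missing
        filled = np.where(np.isfinite(tv), tv, np.inf if dv_kind == "min" else -np.inf)
        idx = (np.argmin if dv_kind == "min" else np.argmax)(filled, axis=0)
        out = np.take_along_axis(hourly.values, idx[None], axis=0)
        allnan = ~np.isfinite(tv).any(axis=0)
        out[0][allnan] = np.nan
    return GridField(lon=hourly.lon, lat=hourly.lat, time=[days[0]], values=out)


def fill_from_coarse(fine: GridField, coarse: GridField) -> tuple[GridField, np.ndarray]:
    """Backfill missing fine cells with the nearest coarse cell's value.

    Present fine values are never altered. Returns the filled field and a
    provenance mask (0 = fine, 1 = coarse, 2 = still missing) per cell.
    """
    if fine.time != coarse.time:
        raise ValueError("fine and coarse fields must share the time axis")
    ii = np.array([np.argmin(np.abs(coarse.lat - y)) for y in fine.lat])
    jj = np.array([np.argmin(np.abs(coarse.lon - x)) for x in fine.lon])
    resampled = coarse.values[:, ii[:, None], jj[None, :]]
    out = np.where(np.isfinite(fine.values), fine.values, resampled)
    provenance = np.full(out.shape, 2, dtype=np.int8)
    provenance[np.isfinite(resampled)] = 1
    provenance[np.isfinite(fine.values)] = 0
    return GridField(lon=fine.lon, lat=fine.lat, time=list(fine.time),
                     values=out), provenance


def filter_cwv(field: GridField) -> GridField:
    """Drop cloudy CWV cells: keep a value iff (qa AND 0b111) != 3.

    Idempotent; never turns a missing cell into a present one.
    """
    if field.qa is None:
        raise ValueError("filter_cwv requires a qa bitmask")
    cloudy = (field.qa & QA_CLOUD_MASK) == QA_CLOUD_VALUE
    values = np.where(cloudy, np.nan, field.values)
    return GridField(lon=field.lon, lat=field.lat, time=list(field.time),
                     values=values, qa=field.qa.copy())


def sample_grid(field: GridField, lon: float, lat: float, when) -> float:
    """Nearest-cell-center lookup (NaN outside the bounding box)."""
    return field.sample(lon, lat, when)


# ---------------------------------------------------------------------------
# feature assembly

def day_of_year_harmonics(day: dt.date) -> tuple[float, float]:
    doy = day.timetuple().tm_yday
    ang = 2.0 * np.pi * (doy - 1) / 365.25
    return float(np.sin(ang)), float(np.cos(ang))


def hours_of_day(day: dt.date, tz) -> list[pd.Timestamp]:
    start = pd.Timestamp(day, tz=tz)
    return [start + pd.Timedelta(hours=h) for h in range(24)]


@dataclasses.dataclass
class GridBundle:
    """The gridded predictor inputs for feature assembly.

    ``humidity_fine``/``temperature_fine`` are hourly fields possibly with
    gaps; the ``*_coarse`` pair backfills them. ``cwv_terra``/``cwv_aqua``
    are daily fields with QA bitmasks.
    """

    humidity_fine: GridField
    temperature_fine: GridField
    humidity_coarse: GridField
    temperature_coarse: GridField
    cwv_terra: GridField | None = None
    cwv_aqua: GridField | None = None

    def _one_day(self, field: GridField, day: dt.date) -> GridField:
        keep = [k for k, t in enumerate(field.time) if t.date() == day]
        if not keep:
            raise ValueError(f"grid has no hours for day {day}")
        return GridField(lon=field.lon, lat=field.lat,
                         time=[field.time[k] for k in keep],
                         values=field.values[keep])

    def daily_dv_grids(self, day: dt.date, dv_kind: str) -> dict[str, GridField]:
        """Daily DV-analogous humidity and temperature grids, coarse-backfilled."""
        out = {}
        for key, fine_f, coarse_f in (
            ("era5_humidity_dv", self.humidity_fine, self.humidity_coarse),
            ("era5_temperature_dv", self.temperature_fine, self.temperature_coarse),
        ):
            fine = aggregate_hourly_to_dv(
                self._one_day(fine_f, day), self._one_day(self.temperature_fine, day),
                dv_kind)
            coarse = aggregate_hourly_to_dv(
                self._one_day(coarse_f, day), self._one_day(self.temperature_coarse, day),
                dv_kind)
            out[key], _ = fill_from_coarse(fine, coarse)
        return out


def read_statics(path) -> pd.DataFrame:
    """Read the statics table (wide, registry-named columns, or long form)."""
    df = pd.read_csv(path, dtype={"station_id": str})
    if set(df.columns) == {"station_id", "feature", "value"}:
        df = df.pivot(index="station_id", columns="feature", values="value").reset_index()
    return df


def assemble_features(
    days: pd.DataFrame,
    grids: GridBundle,
    statics: pd.DataFrame,
    dv_kind: str,
    idw_cfg: IdwConfig = IdwConfig(),
    registry: Mapping[str, str] = STATIC_FEATURE_REGISTRY,
) -> pd.DataFrame:
    """Build one predictor vector per station-day.

    Returns the station-day table extended with the observed DV column
    ``y``, the leave-self-out ``idw`` feature, the dv-matched grid features
    and the registry block — 18 feature slots in all with the default
    registry. Missing IDW (single-station days) and missing CWV pass through
    as NaN.
    """
    if dv_kind not in DV_KINDS:
        raise ValueError(f"dv_kind must be one of {DV_KINDS}")
    dv_col = f"humid_{dv_kind}"
    static_names = [k for k, src in registry.items() if src == "static"]
    missing_stations = set(days["station_id"]) - set(statics["station_id"])
    if missing_stations:
        raise ValueError(
            f"statics table lacks stations: {sorted(missing_stations)[:10]}")
    absent = [c for c in static_names if c not in statics.columns]
    if absent:
        raise ValueError(f"statics table lacks registry features: {absent}")

    out = days.reset_index(drop=True).copy()
    out["y"] = out[dv_col].astype(float)
    out["idw"] = idw_training_features(out, dv_col, idw_cfg).to_numpy()

    # grid features, one pass per day
    for col in GRID_FEATURES:
        out[col] = np.nan
    cwv = {}
    for sat, field in (("cwv_terra", grids.cwv_terra), ("cwv_aqua", grids.cwv_aqua)):
        cwv[sat] = filter_cwv(field) if field is not None else None
    for day, grp in out.groupby("day", sort=False):
        daily = grids.daily_dv_grids(day, dv_kind)
        for col, field in daily.items():
            out.loc[grp.index, col] = [
                field.sample(r.lon, r.lat, day) for r in grp.itertuples()]
        for sat, field in cwv.items():
            if field is not None:
                out.loc[grp.index, sat] = [
                    field.sample(r.lon, r.lat, day) for r in grp.itertuples()]

    # registry block
    st = statics.set_index("station_id")
    for name, src in registry.items():
        if src == "static":
            out[name] = st.loc[out["station_id"], name].to_numpy(dtype=float)
        elif src == "calendar":
            harm = [day_of_year_harmonics(d) for d in out["day"]]
            out["doy_sin"] = [h[0] for h in harm]
            out["doy_cos"] = [h[1] for h in harm]
        # "coordinate" features (lon, lat) are already columns of the table

    if registry is STATIC_FEATURE_REGISTRY:
        # IDW + 4 grid features + 13-name registry block = 18 slots
        assert len(["idw"] + GRID_FEATURES + list(registry)) == 18
    return out
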