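"""Synthetic station networks, observations, grids and statics with known truth.

The generator emulates the statistical structure the estimator assumes:
a smooth spatiotemporal dew-point field observed with noise at stations on a
sub-daily schedule; hourly gridded versions of the field at a fine
resolution (with coastal gaps) and a coarse resolution (complete); a daily
cloud-masked column-water-vapor proxy; and static covariates that really do
shape the field (elevation lapse, drying with distance from water), plus
inert ones. Everything is a deterministic function of the configuration and
its seed, so tests can compare any pipeline output against the ground
truth.

The truth field is built from a low-frequency sinusoidal basis rather than a
Gaussian-process draw: it can be evaluated at arbitrary points and hours in
O(1), which the interpolation and grid tests need, while the basis
frequencies set a controllable spatial correlation length.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

from .features import GridBundle, GridField
from .idw import haversine_km
from .observations import STUDY_UTC_OFFSET, Observation

KM_PER_DEG = 111.195  # one degree of arc on the 6371-km sphere


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for the synthetic domain.

    The defaults describe a desk-scale regional network: 150 stations in an
    8 x 6 degree box observed every 3 hours for 30 summer days with 1 K
    observation noise, a dew-point field with ~250 km spatial correlation,
    a mild diurnal cycle and physically signed covariate effects
    (about -2 K per km of elevation, ~2 K of drying moving inland).
    ``nonlinear_amp`` adds a step effect of elevation that a linear model
    cannot represent; it is 0 in the default scenario.
    """

    n_stations: int = 150
    lon_min: float = -102.0
    lon_max: float = -94.0
    lat_min: float = 32.0
    lat_max: float = 38.0
    n_days: int = 30
    start_day: dt.date = dt.date(2010, 7, 1)
    obs_per_day: int = 8
    noise_sd: float = 1.0  # K, station observation noise
    missing_dewpoint_frac: float = 0.05

    # truth-field shape
    length_scale_km: float = 160.0  # variogram range of the spatial component
    temporal_scale_days: float = 10.0
    spatial_amp: float = 5.0  # K
    temporal_amp: float = 3.0  # K
    diurnal_amp: float = 1.5  # K, dew point; temperature uses 6 K
    elev_lapse_k_per_km: float = -2.0
    water_effect_k: float = -2.0  # asymptotic inland drying
    water_scale_km: float = 75.0
    pop_effect_k: float = 0.3  # per unit of log-density
    elev_scale_km: float = 150.0  # terrain correlation length
    nonlinear_amp: float = 0.0  # K, step effect of elevation
    nonlinear_elev_km: float = 0.45  # step threshold

    # gridded predictors
    fine_res_deg: float = 0.1
    coarse_factor: int = 2  # coarse cell = coarse_factor^2 fine cells
    era5_bias_amp: float = 1.0  # K, smooth fine-grid bias
    coastal_gap_deg: float = 0.3  # fine cells this close to the west coast missing
    cloud_fraction: float = 0.4
    cwv_noise_cm: float = 0.05

    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or not 0 <= self.cloud_fraction <= 1:
            raise ValueError("noise_sd must be >= 0 and cloud_fraction in [0, 1]")
        if self.fine_res_deg <= 0 or self.coarse_factor < 1:
            raise ValueError("grid resolutions must be positive")

    @property
    def days(self) -> list[dt.date]:
        return [self.start_day + dt.timedelta(days=i) for i in range(self.n_days)]


def nonlinear_scenario(seed: int = 0, **overrides) -> "SyntheticConfig":
    """The baseline-comparison scenario: interpolation-dominant conditions
    plus a step covariate effect only a nonlinear learner can recover.

    Three design choices create the regime the residual estimator assumes:
    a dense network over a smooth field makes plain interpolation the
    strongest single predictor; the gridded humidity predictor carries a
    large smooth spatial bias, so a linear blend of grid and interpolation
    gains little (trees, in contrast, can unmix the bias through lon/lat);
    and a step effect of elevation at a scale finer than the station
    spacing is invisible to interpolation, only partly captured by a linear
    elevation term, and fully recoverable by an elevation split. Few days
    per station keep deep trees from memorizing per-station corrections.
    """
    kw = dict(
        n_stations=250,
        n_days=8,
        length_scale_km=200.0,
        elev_scale_km=70.0,
        era5_bias_amp=6.0,
        nonlinear_amp=3.0,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


# ---------------------------------------------------------------------------
# truth field

class TruthField:
    """Deterministic continuous truth: (lon, lat, hour) -> (T, Td) in kelvins.

    ``hour`` counts hours since local midnight of ``cfg.start_day`` in the
    fixed study offset (UTC-6). Vectorized over broadcastable inputs.
    """

    N_BASIS = 8

    def __init__(self, cfg: SyntheticConfig):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
        # random low-frequency plane waves; the 3x factor makes the field's
        # practical variogram range (~90% of sill) equal the configured scale
        k = 2.0 * np.pi / (3.0 * cfg.length_scale_km)
        theta = rng.uniform(0, 2 * np.pi, self.N_BASIS)
        # narrow wavenumber jitter and near-equal weights keep the realized
        # roughness close to the configured scale for every seed
        self._kx = k * np.cos(theta) * rng.uniform(0.9, 1.1, self.N_BASIS)
        self._ky = k * np.sin(theta) * rng.uniform(0.9, 1.1, self.N_BASIS)
        self._phase = rng.uniform(0, 2 * np.pi, self.N_BASIS)
        # weights normalized so the spatial component's SD equals
        # cfg.spatial_amp exactly (each wave contributes a_i^2 / 2)
        w = rng.uniform(0.5, 1.0, self.N_BASIS)
        self._amp = cfg.spatial_amp * np.sqrt(2.0) * w / np.linalg.norm(w)
        self._tphase = rng.uniform(0, 2 * np.pi)
        # independent basis for temperature's extra spatial texture
        self._t_amp = rng.uniform(0.5, 1.0, self.N_BASIS)
        self._lat0 = 0.5 * (cfg.lat_min + cfg.lat_max)
        # elevation: smooth medium-scale terrain, km
        e_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 102]))
        ke = 2.0 * np.pi / (2.0 * cfg.elev_scale_km)
        te = e_rng.uniform(0, 2 * np.pi, 6)
        self._ekx = ke * np.cos(te) * e_rng.uniform(0.7, 1.3, 6)
        self._eky = ke * np.sin(te) * e_rng.uniform(0.7, 1.3, 6)
        self._ephase = e_rng.uniform(0, 2 * np.pi, 6)
        self._eamp = e_rng.dirichlet(np.ones(6)) * 0.8

    # -- covariate surfaces ------------------------------------------------
    def _xy_km(self, lon, lat):
        x = (np.asarray(lon, dtype=float) - self.cfg.lon_min) * KM_PER_DEG \
            * np.cos(np.radians(self._lat0))
        y = (np.asarray(lat, dtype=float) - self.cfg.lat_min) * KM_PER_DEG
        return x, y

    def elevation_km(self, lon, lat):
        """Smooth synthetic terrain in km above a 0.2 km floor."""
        x, y = self._xy_km(lon, lat)
        z = sum(a * np.sin(kx * x + ky * y + p) for a, kx, ky, p in
                zip(self._eamp, self._ekx, self._eky, self._ephase))
        return 0.45 + 0.5 * z

    def distance_water_km(self, lon, lat):
        """Distance to the synthetic coast (the western domain edge)."""
        x, _ = self._xy_km(lon, lat)
        return np.maximum(x, 0.0)

    def covariate_effect(self, lon, lat):
        """The dew-point contribution of the static covariates, in K."""
        cfg = self.cfg
        elev = self.elevation_km(lon, lat)
        dwater = self.distance_water_km(lon, lat)
        eff = (cfg.elev_lapse_k_per_km * (elev - 0.45)
               + cfg.water_effect_k * (1.0 - np.exp(-dwater / cfg.water_scale_km)))
        if cfg.nonlinear_amp:
            eff = eff + cfg.nonlinear_amp * (elev > cfg.nonlinear_elev_km)
        return eff

    # -- fields ------------------------------------------------------------
    def _spatial(self, lon, lat):
        x, y = self._xy_km(lon, lat)
        return sum(a * np.sin(kx * x + ky * y + p) for a, kx, ky, p in
                   zip(self._amp, self._kx, self._ky, self._phase))

    def dew_point(self, lon, lat, hour):
        cfg = self.cfg
        hour = np.asarray(hour, dtype=float)
        seasonal = cfg.temporal_amp * np.sin(
            2.0 * np.pi * hour / (24.0 * cfg.temporal_scale_days) + self._tphase)
        diurnal = cfg.diurnal_amp * np.cos(2.0 * np.pi * (hour % 24.0 - 6.0) / 24.0)
        return (290.0 + self._spatial(lon, lat) + seasonal + diurnal
                + self.covariate_effect(lon, lat))

    def temperature(self, lon, lat, hour):
        """Air temperature with a strong diurnal cycle peaking at 15:00.

        Built as dew point plus a margin of at least 2 K, so the truth never
        supersaturates (noisy observations still may).
        """
        hour = np.asarray(hour, dtype=float)
        x, y = self._xy_km(lon, lat)
        texture = sum(a * w * np.cos(kx * x + ky * y + p) for a, w, kx, ky, p in
                      zip(self._amp, self._t_amp, self._kx, self._ky, self._phase))
        diurnal = 6.0 * np.cos(2.0 * np.pi * (hour % 24.0 - 15.0) / 24.0)
        margin = 8.0 + diurnal + 0.4 * texture
        return self.dew_point(lon, lat, hour) + np.maximum(margin, 2.0)

    def hour_of(self, day: dt.date, hour_of_day: float) -> float:
        return (day - self.cfg.start_day).days * 24.0 + hour_of_day


def generate_truth(cfg: SyntheticConfig) -> TruthField:
    """Build the deterministic continuous truth field for a configuration."""
    return TruthField(cfg)


# ---------------------------------------------------------------------------
# stations and observations

def generate_stations(cfg: SyntheticConfig) -> pd.DataFrame:
    """Station network: ids and coordinates, uniform over the box."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 201]))
    lon = rng.uniform(cfg.lon_min, cfg.lon_max, cfg.n_stations)
    lat = rng.uniform(cfg.lat_min, cfg.lat_max, cfg.n_stations)
    ids = [f"S{i:04d}" for i in range(cfg.n_stations)]
    return pd.DataFrame({"station_id": ids, "lon": lon, "lat": lat})


def generate_observations(
    cfg: SyntheticConfig, truth: TruthField, stations: pd.DataFrame | None = None
) -> list[Observation]:
    """Noisy sub-daily records at every station on a fixed schedule.

    Observation hours are evenly spaced and symmetric to the day
    boundaries (e.g. 1.5, 4.5, ..., 22.5 for 8/day). Observed values are
    truth plus independent Gaussian noise; a configured fraction of records
    loses its dew point to exercise the cleaning path.
    """
    if stations is None:
        stations = generate_stations(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    step = 24.0 / cfg.obs_per_day
    hours_of_day = step / 2.0 + step * np.arange(cfg.obs_per_day)
    obs: list[Observation] = []
    for day_i, day in enumerate(cfg.days):
        for st in stations.itertuples(index=False):
            hrs = day_i * 24.0 + hours_of_day
            td = truth.dew_point(st.lon, st.lat, hrs) + rng.normal(0, cfg.noise_sd, len(hrs))
            tt = truth.temperature(st.lon, st.lat, hrs) + rng.normal(0, cfg.noise_sd, len(hrs))
            drop = rng.random(len(hrs)) < cfg.missing_dewpoint_frac
            midnight = pd.Timestamp(day, tz=STUDY_UTC_OFFSET)
            for h, a, b, dr in zip(hours_of_day, td, tt, drop):
                obs.append(Observation(
                    station_id=st.station_id, lon=st.lon, lat=st.lat,
                    timestamp=midnight + pd.Timedelta(hours=float(h)),
                    temperature=float(b),
                    dew_point=None if dr else float(a)))
    return obs


# ---------------------------------------------------------------------------
# grids

def _grid_axes(cfg: SyntheticConfig, res: float) -> tuple[np.ndarray, np.ndarray]:
    lon = np.arange(cfg.lon_min + res / 2.0, cfg.lon_max, res)
    lat = np.arange(cfg.lat_min + res / 2.0, cfg.lat_max, res)
    return lon, lat


def generate_grids(cfg: SyntheticConfig, truth: TruthField) -> GridBundle:
    """Hourly fine/coarse humidity and temperature grids plus daily CWV.

    The fine grids are truth at cell centers plus a smooth bias field (the
    learnable signal a reanalysis-style predictor carries); in the nonlinear
    scenario the bias also tracks the elevation step. Coarse grids are block
    means of the (unmasked) fine grids. Fine cells within the coastal band
    are missing, exercising the coarse fallback. The CWV proxy is a
    monotone transform of the cell's daily mean dew point, noisy, with QA
    low bits set to the cloudy value on a random cloud mask.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 203]))
    flon, flat = _grid_axes(cfg, cfg.fine_res_deg)
    n_hours = cfg.n_days * 24
    hours = np.arange(n_hours, dtype=float)
    glon, glat = np.meshgrid(flon, flat)  # (nlat, nlon)

    td = truth.dew_point(glon[None], glat[None], hours[:, None, None])
    tt = truth.temperature(glon[None], glat[None], hours[:, None, None])
    # the reanalysis-style product does not resolve the local (step) covariate
    # effect: coarse land-surface models miss sub-grid microclimate
    if cfg.nonlinear_amp:
        step = cfg.nonlinear_amp * (
            truth.elevation_km(glon, glat) > cfg.nonlinear_elev_km)
        td = td - step[None]
        tt = tt - step[None]

    # smooth bias: a mid-frequency sinusoid, constant in time — curved enough
    # that a linear trend cannot absorb it, smooth enough to be learnable
    kb = 2.0 * np.pi / (1.8 * cfg.length_scale_km)
    x = (glon - cfg.lon_min) * KM_PER_DEG * np.cos(np.radians((cfg.lat_min + cfg.lat_max) / 2))
    y = (glat - cfg.lat_min) * KM_PER_DEG
    tb = rng.uniform(0, 2 * np.pi, 2)
    bias = cfg.era5_bias_amp * np.sin(kb * x + tb[0]) * np.cos(kb * y + tb[1])

    td_fine_full = td + bias[None]
    tt_fine_full = tt + bias[None]

    # coarse = block mean of fine (complete)
    f = cfg.coarse_factor
    nlat_c, nlon_c = len(flat) // f, len(flon) // f
    def block_mean(a):
        a = a[:, : nlat_c * f, : nlon_c * f]
        return a.reshape(a.shape[0], nlat_c, f, nlon_c, f).mean(axis=(2, 4))
    clon = flon[: nlon_c * f].reshape(nlon_c, f).mean(axis=1)
    clat = flat[: nlat_c * f].reshape(nlat_c, f).mean(axis=1)
    td_coarse = block_mean(td_fine_full)
    tt_coarse = block_mean(tt_fine_full)

    # coastal band missing in the fine fields
    coastal = flon[None, :] < cfg.lon_min + cfg.coastal_gap_deg
    coastal = np.broadcast_to(coastal, (len(flat), len(flon)))
    td_fine = np.where(coastal[None], np.nan, td_fine_full)
    tt_fine = np.where(coastal[None], np.nan, tt_fine_full)

    times = [pd.Timestamp(cfg.start_day, tz=STUDY_UTC_OFFSET) + pd.Timedelta(hours=h)
             for h in hours]

    def make(lon_ax, lat_ax, vals):
        return GridField(lon=lon_ax, lat=lat_ax, time=list(times), values=vals)

    # daily CWV (cm): monotone in daily-mean dew point, plus noise and clouds
    days = cfg.days
    td_daily = td.reshape(cfg.n_days, 24, *td.shape[1:]).mean(axis=1)
    cwv_clean = np.exp((td_daily - 273.15) / 15.0)
    cwvs = {}
    for tag in ("terra", "aqua"):
        noise = rng.normal(0, cfg.cwv_noise_cm, cwv_clean.shape)
        qa = np.zeros(cwv_clean.shape, dtype=np.int64)
        cloudy = rng.random(cwv_clean.shape) < cfg.cloud_fraction
        qa[cloudy] |= 0b011
        qa |= rng.integers(0, 2, cwv_clean.shape) << 3  # inert high bits
        cwvs[tag] = GridField(lon=flon, lat=flat, time=list(days),
                              values=cwv_clean + noise, qa=qa)

    return GridBundle(
        humidity_fine=make(flon, flat, td_fine),
        temperature_fine=make(flon, flat, tt_fine),
        humidity_coarse=make(clon, clat, td_coarse),
        temperature_coarse=make(clon, clat, tt_coarse),
        cwv_terra=cwvs["terra"],
        cwv_aqua=cwvs["aqua"],
    )


# ---------------------------------------------------------------------------
# statics and regions

def generate_statics_and_regions(
    cfg: SyntheticConfig, truth: TruthField, stations: pd.DataFrame | None = None,
    n_regions: int = 4,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Static covariates per station and a k-way spatial region partition.

    Elevation and distance from water come from the same surfaces the truth
    field uses, so their configured effects are recoverable. Population
    density is log-normal and clustered around a few synthetic cities;
    isolation is each station's true nearest-neighbor distance. The
    remaining registry features are plausible correlates or noise.
    """
    if stations is None:
        stations = generate_stations(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 204]))
    lon = stations["lon"].to_numpy()
    lat = stations["lat"].to_numpy()
    elev_km = np.asarray(truth.elevation_km(lon, lat), dtype=float)
    dwater = np.asarray(truth.distance_water_km(lon, lat), dtype=float)

    # synthetic cities for population clustering
    n_city = 5
    clon = rng.uniform(cfg.lon_min, cfg.lon_max, n_city)
    clat = rng.uniform(cfg.lat_min, cfg.lat_max, n_city)
    d_city = np.min(haversine_km(lon[:, None], lat[:, None],
                                 clon[None, :], clat[None, :]), axis=1)
    log_pop = 3.0 - d_city / 80.0 + rng.normal(0, 0.5, len(lon))
    pop = np.exp(log_pop)

    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(d, np.inf)
    isolation = d.min(axis=1) if len(lon) > 1 else np.zeros(1)

    # finite-difference slope of the elevation surface, m per km
    eps = 0.01
    dzdx = (truth.elevation_km(lon + eps, lat) - elev_km) / (eps * KM_PER_DEG)
    dzdy = (truth.elevation_km(lon, lat + eps) - elev_km) / (eps * KM_PER_DEG)
    slope = 1000.0 * np.hypot(dzdx, dzdy)

    statics = pd.DataFrame({
        "station_id": stations["station_id"],
        "elevation_m": elev_km * 1000.0,
        "distance_water_km": dwater,
        "population_density": pop,
        "isolation_km": isolation,
        "slope_m_per_km": slope,
        "vegetation_index": np.clip(
            0.5 + 0.1 * np.asarray(truth._spatial(lon, lat)) / max(cfg.spatial_amp, 1e-9)
            + rng.normal(0, 0.05, len(lon)), 0.0, 1.0),
        "imperviousness": np.clip(pop / (pop.max() + 1e-9)
                                  + rng.normal(0, 0.05, len(lon)), 0.0, 1.0),
        "distance_urban_km": d_city,
        "water_frac_10km": np.clip(1.0 - dwater / 10.0, 0.0, 1.0),
    })

    # regions: a longitude-slice partition of the box
    edges = np.linspace(cfg.lon_min, cfg.lon_max, n_regions + 1)
    idx = np.clip(np.searchsorted(edges, lon, side="right") - 1, 0, n_regions - 1)
    region_map = {sid: f"R{k}" for sid, k in zip(stations["station_id"], idx)}
    return statics, region_map


# ---------------------------------------------------------------------------
# one-call bundle

@dataclasses.dataclass
class SyntheticBundle:
    cfg: SyntheticConfig
    truth: TruthField
    stations: pd.DataFrame
    observations: list[Observation]
    grids: GridBundle
    statics: pd.DataFrame
    region_map: dict[str, str]


def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate every input the pipeline needs, deterministically."""
    truth = generate_truth(cfg)
    stations = generate_stations(cfg)
    statics, region_map = generate_statics_and_regions(cfg, truth, stations)
    return SyntheticBundle(
        cfg=cfg,
        truth=truth,
        stations=stations,
        observations=generate_observations(cfg, truth, stations),
        grids=generate_grids(cfg, truth),
        statics=statics,
        region_map=region_map,
    )
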