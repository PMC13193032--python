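"""Sub-daily station observations → the three daily dependent variables.

A study day is a midnight-to-midnight interval of the fixed UTC−6 offset
(Central Standard Time, never daylight saving). Each valid station-day is
reduced to three dependent variables (DVs):

- ``humid_min`` — the dew point observed at the observation where the
  station's temperature attains its daily minimum ("T-min humidity"),
- ``humid_mean`` — the time-weighted daily mean dew point,
- ``humid_max`` — the dew point at the daily temperature maximum
  ("T-max humidity"),

with the matching temperature statistics carried alongside. Note the extrema
are *not* the extreme dew points: they are the dew points co-occurring with
the temperature extrema, so that e.g. max temperature and T-max humidity
always describe the same moment.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Fixed study offset: Central Standard Time, UTC-6, no daylight saving.
STUDY_UTC_OFFSET = dt.timezone(dt.timedelta(hours=-6))

OBS_COLUMNS = ["station_id", "lon", "lat", "time", "temperature_k", "dew_point_k"]
STATION_DAY_COLUMNS = [
    "station_id", "day", "lon", "lat",
    "humid_min", "humid_mean", "humid_max",
    "temp_min", "temp_mean", "temp_max",
    "n_obs", "span_hours",
]

_OFFSET_RE = re.compile(r"(Z|[+-]\d{2}:?\d{2})$")


@dataclasses.dataclass(frozen=True)
class Observation:
    """One sub-daily station record."""

    station_id: str
    lon: float
    lat: float
    timestamp: dt.datetime  # must carry an explicit UTC offset
    temperature: float | None  # kelvins
    dew_point: float | None  # kelvins

    def __post_init__(self):
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")


@dataclasses.dataclass(frozen=True)
class StationDay:
    """The three daily DVs plus supporting statistics for one station-day."""

    station_id: str
    day: dt.date
    lon: float
    lat: float
    humid_min: float
    humid_mean: float
    humid_max: float
    temp_min: float
    temp_mean: float
    temp_max: float
    n_obs: int
    span_hours: float


@dataclasses.dataclass(frozen=True)
class CleaningConfig:
    """Record bounds and completeness rules for observation cleaning.

    ``bound_lo``/``bound_hi`` play the role of record historical temperatures:
    dew points outside them are treated as physically impossible and dropped.
    ``min_obs`` and ``min_span_hours`` define when a station-day is complete
    enough for its daily mean to be representative. ``boundary_cap_hours``
    caps the extra weight the first/last observation of a day receives for
    the stretch between it and the day boundary.
    """

    bound_lo: float = 210.0  # kelvins
    bound_hi: float = 310.0
    min_obs: int = 4
    min_span_hours: float = 18.0
    boundary_cap_hours: float = 1.0

    def __post_init__(self):
        if not self.bound_lo < self.bound_hi:
            raise ValueError("bound_lo must be < bound_hi")
        if not 0.0 <= self.min_span_hours <= 24.0:
            raise ValueError("min_span_hours must lie in [0, 24]")


def assign_day(timestamp: dt.datetime | pd.Timestamp) -> dt.date:
    """Calendar date of an instant in the fixed UTC−6 study offset.

    Rejects timestamps without an explicit UTC offset: a naive timestamp is
    ambiguous and silently assuming a zone would misassign days near
    midnight.
    """
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is None:
        raise ValueError(
            "timestamp lacks a UTC offset; study days are defined in UTC-6 "
            "and naive timestamps cannot be placed unambiguously")
    return ts.tz_convert(STUDY_UTC_OFFSET).date()


def supersaturated_count(obs: Iterable[Observation]) -> int:
    """Diagnostic: number of records with dew point above temperature.

    Such records are physically suspect but are *kept* by cleaning; no rule
    forces dew point below temperature.
    """
    return sum(
        1 for o in obs
        if o.dew_point is not None and o.temperature is not None
        and o.dew_point > o.temperature)


def clean_observations(
    obs: Sequence[Observation], cfg: CleaningConfig
) -> tuple[list[Observation], list[tuple[Observation, str]]]:
    """Keep records with paired, finite temperature and in-bounds dew point.

    Returns ``(kept, rejected)`` where each rejection carries a reason code:
    ``no_paired_temperature``, ``missing_dew_point``, ``nonfinite_value`` or
    ``beyond_record_bounds``. Input order is preserved; cleaning is
    idempotent.
    """
    kept: list[Observation] = []
    rejected: list[tuple[Observation, str]] = []
    for o in obs:
        if o.dew_point is None:
            rejected.append((o, "missing_dew_point"))
        elif o.temperature is None:
            rejected.append((o, "no_paired_temperature"))
        elif not (np.isfinite(o.dew_point) and np.isfinite(o.temperature)):
            rejected.append((o, "nonfinite_value"))
        elif not cfg.bound_lo <= o.dew_point <= cfg.bound_hi:
            rejected.append((o, "beyond_record_bounds"))
        else:
            kept.append(o)
    return kept, rejected


def _time_weights(hours: np.ndarray, cap: float) -> np.ndarray:
    """Trapezoidal-interval weights over observation hours within a day.

    Each observation carries half the gap to each temporal neighbor; the
    first and last additionally carry the gap to the day boundary, capped at
    ``cap`` hours so a lone early or late reading cannot dominate the mean.
    """
    n = len(hours)
    w = np.zeros(n)
    if n == 1:
        w[0] = 1.0
        return w
    gaps = np.diff(hours)
    w[:-1] += gaps / 2.0
    w[1:] += gaps / 2.0
    w[0] += min(hours[0] - 0.0, cap)
    w[-1] += min(24.0 - hours[-1], cap)
    return w


def derive_station_day(
    obs: Sequence[Observation], cfg: CleaningConfig
) -> StationDay | None:
    """Reduce one station's cleaned observations for one day to a StationDay.

    ``humid_mean`` (and ``temp_mean``) are weighted means with trapezoidal
    time weights; ``humid_min``/``humid_max`` are the dew points at the
    observations where temperature attains its daily minimum/maximum, the
    earliest such observation on ties. Returns ``None`` for incomplete days
    (fewer than ``cfg.min_obs`` observations or a span below
    ``cfg.min_span_hours``).
    """
    if not obs:
        return None
    sids = {o.station_id for o in obs}
    if len(sids) != 1:
        raise ValueError(f"observations span multiple stations: {sorted(sids)}")
    days = {assign_day(o.timestamp) for o in obs}
    if len(days) != 1:
        raise ValueError(f"observations span multiple study days: {sorted(days)}")
    times = [pd.Timestamp(o.timestamp).tz_convert(STUDY_UTC_OFFSET) for o in obs]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("observations must be sorted by time")

    day = days.pop()
    midnight = pd.Timestamp(day, tz=STUDY_UTC_OFFSET)
    hours = np.array([(t - midnight).total_seconds() / 3600.0 for t in times])
    span = float(hours[-1] - hours[0])
    if len(obs) < cfg.min_obs or span < cfg.min_span_hours:
        return None

    td = np.array([o.dew_point for o in obs], dtype=float)
    tt = np.array([o.temperature for o in obs], dtype=float)
    w = _time_weights(hours, cfg.boundary_cap_hours)
    i_min = int(np.argmin(tt))  # argmin/argmax take the earliest on ties
    i_max = int(np.argmax(tt))
    return StationDay(
        station_id=obs[0].station_id,
        day=day,
        lon=obs[0].lon,
        lat=obs[0].lat,
        humid_min=float(td[i_min]),
        humid_mean=float(np.average(td, weights=w)),
        humid_max=float(td[i_max]),
        temp_min=float(tt[i_min]),
        temp_mean=float(np.average(tt, weights=w)),
        temp_max=float(tt[i_max]),
        n_obs=len(obs),
        span_hours=span,
    )


def derive_station_days(
    obs: Iterable[Observation], cfg: CleaningConfig
) -> pd.DataFrame:
    """Clean, group by (station, study day), and reduce to a StationDay table."""
    kept, rejected = clean_observations(list(obs), cfg)
    if rejected:
        log.info("cleaning dropped %d of %d observations",
                 len(rejected), len(rejected) + len(kept))
    groups: dict[tuple[str, dt.date], list[Observation]] = {}
    for o in kept:
        groups.setdefault((o.station_id, assign_day(o.timestamp)), []).append(o)
    rows = []
    for (sid, day), grp in sorted(groups.items()):
        grp.sort(key=lambda o: pd.Timestamp(o.timestamp).tz_convert(STUDY_UTC_OFFSET))
        sd = derive_station_day(grp, cfg)
        if sd is not None:
            rows.append(dataclasses.asdict(sd))
    df = pd.DataFrame(rows, columns=STATION_DAY_COLUMNS)
    df["day"] = pd.to_datetime(df["day"]).dt.date if len(df) else df["day"]
    return df


# ---------------------------------------------------------------------------
# I/O

def read_observations(path) -> tuple[list[Observation], list[tuple[int, str]]]:
    """Read an observations CSV; malformed rows are logged and skipped.

    Schema: ``station_id,lon,lat,time,temperature_k,dew_point_k`` with RFC
    3339 timestamps (offset required). Returns ``(observations,
    row_rejections)`` where each rejection is ``(row_index, reason)``.
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observations file lacks columns: {missing}")
    out: list[Observation] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw_time = str(row.time)
        if not _OFFSET_RE.search(raw_time):
            bad.append((i, "timestamp_without_offset"))
            continue
        try:
            ts = pd.Timestamp(raw_time)
        except (ValueError, TypeError):
            bad.append((i, "unparseable_timestamp"))
            continue
        try:
            out.append(Observation(
                station_id=str(row.station_id),
                lon=float(row.lon),
                lat=float(row.lat),
                timestamp=ts,
                temperature=None if pd.isna(row.temperature_k) else float(row.temperature_k),
                dew_point=None if pd.isna(row.dew_point_k) else float(row.dew_point_k),
            ))
        except (ValueError, TypeError) as exc:
            bad.append((i, f"invalid_row: {exc}"))
    for i, reason in bad:
        log.warning("skipping observation row %d: %s", i, reason)
    return out, bad


def write_observations(path, obs: Iterable[Observation]) -> None:
    rows = [{
        "station_id": o.station_id, "lon": o.lon, "lat": o.lat,
        "time": pd.Timestamp(o.timestamp).isoformat(),
        "temperature_k": o.temperature, "dew_point_k": o.dew_point,
    } for o in obs]
    pd.DataFrame(rows, columns=OBS_COLUMNS).to_csv(path, index=False)


def write_station_days(path, days: pd.DataFrame) -> None:
    days.to_csv(path, index=False, columns=STATION_DAY_COLUMNS)


def read_station_days(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str})
    df["day"] = pd.to_datetime(df["day"]).dt.date
    return df
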