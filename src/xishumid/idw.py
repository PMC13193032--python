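"""Inverse-distance-weighted daily interpolation over the station network.

IDW supplies the spatial baseline of the estimator: for a query point the
estimate is the distance-weighted mean of same-day station values,
``sum(d_i ** -power * v_i) / sum(d_i ** -power)`` over the ``k`` nearest
in-radius neighbors. For training rows the target's own station is always
excluded ("leave-self-out") so the baseline never sees the value it is
supposed to predict.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

#: Spherical-earth radius used for all distances, km.
EARTH_RADIUS_KM = 6371.0


class NoNeighborsError(ValueError):
    """No station remains after exclusion/radius/k truncation."""


@dataclasses.dataclass(frozen=True)
class IdwConfig:
    """Settings for the inverse-distance-weighted estimate.

    ``power`` is the distance exponent, ``k_neighbors`` the neighborhood
    size (0 = use all stations), ``max_radius_km`` a hard search radius
    (0 = unlimited). Stations within ``exact_hit_epsilon_km`` of the query
    are treated as coincident: their mean value is returned directly, which
    keeps the estimate finite and reordering-invariant at zero distance.
    """

    power: float = 2.0
    k_neighbors: int = 8
    max_radius_km: float = 0.0
    exact_hit_epsilon_km: float = 0.001

    def __post_init__(self):
        if self.power <= 0:
            raise ValueError("power must be positive")
        if self.k_neighbors < 0 or self.exact_hit_epsilon_km < 0:
            raise ValueError("k_neighbors and exact_hit_epsilon_km must be >= 0")


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays of degrees.
    """
    lon1, lat1, lon2, lat2 = (np.asarray(x, dtype=float) for x in (lon1, lat1, lon2, lat2))
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if np.any(np.abs(lon) > 180.0) or np.any(np.abs(lat) > 90.0):
            raise ValueError("coordinates out of range")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def idw_estimate(distances_km, values, cfg: IdwConfig = IdwConfig()):
    """IDW estimate from neighbor distances (km) and values (K).

    Applies the radius cut, then keeps the ``k`` nearest neighbors, then
    forms the weighted mean. Coincident neighbors (distance below the exact-
    hit epsilon) short-circuit to their plain mean. Raises
    :class:`NoNeighborsError` when nothing survives truncation.
    """
    d = np.asarray(distances_km, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.shape != v.shape:
        raise ValueError("distances and values must have the same shape")
    ok = np.isfinite(d) & np.isfinite(v)
    if cfg.max_radius_km > 0:
        ok &= d <= cfg.max_radius_km
    d, v = d[ok], v[ok]
    if d.size == 0:
        raise NoNeighborsError("no neighbors within radius")
    if cfg.k_neighbors and d.size > cfg.k_neighbors:
        # stable partial sort: ties at the k-th distance resolved by input order
        idx = np.argsort(d, kind="stable")[: cfg.k_neighbors]
        d, v = d[idx], v[idx]
    hit = d <= cfg.exact_hit_epsilon_km
    if np.any(hit):
        return float(np.mean(v[hit]))
    w = d ** (-cfg.power)
    return float(np.sum(w * v) / np.sum(w))


def idw_training_features(
    days: pd.DataFrame,
    dv_col: str,
    cfg: IdwConfig = IdwConfig(),
    query: pd.DataFrame | None = None,
    exclude_self: bool = True,
) -> pd.Series:
    """Leave-self-out IDW feature for every row of a station-day table.

    ``days`` must have columns ``station_id, day, lon, lat`` and ``dv_col``.
    When ``query`` is None the feature is computed for the table's own rows
    with each row's station excluded from its neighbor set (the training
    convention). With an explicit ``query`` table (columns
    ``station_id, day, lon, lat``) values come from ``days`` only; stations
    in ``query`` that also appear in ``days`` are excluded from their own
    neighbor sets only if ``exclude_self``.

    Rows with no usable neighbor (e.g. a day observed by a single station)
    get NaN, which downstream models treat as an explicitly missing feature.
    """
    targets = days if query is None else query
    out = np.full(len(targets), np.nan)
    day_groups = {day: g for day, g in days.groupby("day", sort=False)}
    for day, tgt in targets.groupby("day", sort=False):
        src = day_groups.get(day)
        if src is None:
            continue
        sv = src[dv_col].to_numpy(dtype=float)
        slon = src["lon"].to_numpy(dtype=float)
        slat = src["lat"].to_numpy(dtype=float)
        sid = src["station_id"].to_numpy()
        for pos, row in zip(tgt.index, tgt.itertuples(index=False)):
            dmat = haversine_km(row.lon, row.lat, slon, slat)
            mask = np.ones(len(src), dtype=bool)
            if exclude_self:
                mask &= sid != row.station_id
            if not np.any(mask):
                continue
            try:
                est = idw_estimate(dmat[mask], sv[mask], cfg)
            except NoNeighborsError:
                continue
            out[targets.index.get_loc(pos)] = est
    return pd.Series(out, index=targets.index, name="idw")
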