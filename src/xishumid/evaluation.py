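"""Station-level cross-validation, weighted metrics, baselines, subsets.

Folds partition *stations*, not rows, so a model is never evaluated at a
station it trained on. Leakage through the IDW feature is prevented by
recomputing it per fold: training rows use leave-self-out IDW over training
stations only, and validation rows use IDW over training stations only.
Metrics are weighted SD / RMSE / bias; the default weighting down-weights
stations in dense clusters so a single metro network cannot dominate the
domain-wide error.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, Ridge

from . import model as xis_model
from .features import FEATURE_COLUMNS
from .idw import IdwConfig, haversine_km, idw_training_features
from .model import Hyperparameters, XisModel
from .thermo import fahrenheit_to_kelvin

log = logging.getLogger(__name__)

#: Hot station-day threshold: 92 degF expressed in kelvins.
HOT_TEMP_K = float(fahrenheit_to_kelvin(92.0))

#: Isolated-station threshold, km to the nearest other station.
ISOLATION_KM = 12.0


def make_folds(stations: Sequence[str], k: int = 5, seed: int = 0) -> dict[str, int]:
    """Uniform random partition of stations into k folds (sizes differ <= 1)."""
    stations = sorted(set(stations))
    if len(stations) < k:
        raise ValueError(f"need at least {k} stations, got {len(stations)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(stations))
    folds = {}
    for pos, idx in enumerate(order):
        folds[stations[idx]] = pos % k
    return folds


def weighted_metrics(
    observation: np.ndarray, prediction: np.ndarray, weight: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Weighted (SD, RMSE, bias); unit weights give the unweighted forms.

    SD is the weighted standard deviation of the *observations* about their
    weighted mean — the no-skill yardstick the RMSE is compared against.
    """
    obs = np.asarray(observation, dtype=float)
    pred = np.asarray(prediction, dtype=float)
    w = np.ones_like(obs) if weight is None else np.asarray(weight, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    sw = w.sum()
    err = pred - obs
    rmse = float(np.sqrt(np.sum(w * err ** 2) / sw))
    bias = float(np.sum(w * err) / sw)
    mean_obs = np.sum(w * obs) / sw
    sd = float(np.sqrt(np.sum(w * (obs - mean_obs) ** 2) / sw))
    return sd, rmse, bias


def station_weights(
    stations: pd.DataFrame, scheme: str = "inverse_density", radius_km: float = 50.0
) -> pd.Series:
    """Per-station evaluation weights, normalized to mean 1.

    ``uniform`` gives every station-day weight 1. ``inverse_density`` weights
    each station by 1/(1 + number of other stations within ``radius_km``),
    so clustered networks do not dominate the aggregate metrics.
    """
    st = stations.drop_duplicates("station_id").set_index("station_id")
    if scheme == "uniform":
        w = pd.Series(1.0, index=st.index)
    elif scheme == "inverse_density":
        lon = st["lon"].to_numpy(dtype=float)
        lat = st["lat"].to_numpy(dtype=float)
        d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
        counts = (d <= radius_km).sum(axis=1) - 1  # exclude self
        w = pd.Series(1.0 / (1.0 + counts), index=st.index)
        w /= w.mean()
    else:
        raise ValueError(f"unknown weighting scheme: {scheme!r}")
    w.name = "weight"
    return w


def isolated_subset(stations: pd.DataFrame, threshold_km: float = ISOLATION_KM) -> set[str]:
    """Stations whose nearest other station is at least ``threshold_km`` away."""
    st = stations.drop_duplicates("station_id")
    ids = st["station_id"].to_numpy()
    if len(ids) < 2:
        return set(ids)
    lon = st["lon"].to_numpy(dtype=float)
    lat = st["lat"].to_numpy(dtype=float)
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(d, np.inf)
    nearest = d.min(axis=1)
    return set(ids[nearest >= threshold_km])


def hot_subset(station_days: pd.DataFrame, threshold_k: float = HOT_TEMP_K) -> pd.DataFrame:
    """Station-days whose max temperature reaches 92 degF (inclusive)."""
    return station_days[station_days["temp_max"] >= threshold_k]


# ---------------------------------------------------------------------------
# cross-validation

@dataclasses.dataclass
class CVResult:
    """Out-of-fold predictions plus the machinery to summarize them."""

    rows: pd.DataFrame  # input table + fold, cv_idw, prediction, weight
    fold_models: dict[int, XisModel]
    folds: dict[str, int]
    weight_scheme: str

    def metrics(self, mask: np.ndarray | None = None,
                weighted: bool = True) -> dict[str, float]:
        df = self.rows if mask is None else self.rows[mask]
        sd, rmse, bias = weighted_metrics(
            df["y"].to_numpy(), df["prediction"].to_numpy(),
            df["weight"].to_numpy() if weighted else None)
        return {"sd": sd, "rmse": rmse, "bias": bias,
                "n_obs": int(len(df)),
                "n_sites": int(df["station_id"].nunique())}

    def by_region(self, region_map: Mapping[str, str],
                  weighted: bool = True) -> pd.DataFrame:
        regions = self.rows["station_id"].map(region_map)
        if regions.isna().any():
            missing = sorted(self.rows.loc[regions.isna(), "station_id"].unique())
            raise ValueError(f"region map lacks stations: {missing[:10]}")
        out = {}
        for region in sorted(regions.unique()):
            out[region] = self.metrics((regions == region).to_numpy(), weighted)
        return pd.DataFrame(out).T

    def report(self, region_map: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Tidy CV report: overall scope plus optional per-region rows."""
        rows = [{"scope": "overall", **self.metrics()}]
        iso = isolated_subset(self.rows)
        rows.append({"scope": "isolated",
                     **self.metrics(self.rows["station_id"].isin(iso).to_numpy(),
                                    weighted=False)})
        if "temp_max" in self.rows:
            rows.append({"scope": "hot",
                         **self.metrics((self.rows["temp_max"] >= HOT_TEMP_K).to_numpy(),
                                        weighted=False)})
        df = pd.DataFrame(rows)
        if region_map is not None:
            reg = self.by_region(region_map).reset_index(names="scope")
            df = pd.concat([df, reg], ignore_index=True)
        return df


def _fold_idw(table: pd.DataFrame, folds: Mapping[str, int], fold: int,
              idw_cfg: IdwConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute the IDW feature for one fold without leakage.

    Training rows: leave-self-out IDW over training stations. Validation
    rows: IDW over training stations (the validation station is never a
    neighbor of itself because it is absent from the training table).
    """
    fold_of = table["station_id"].map(folds)
    train = table[fold_of != fold].copy()
    valid = table[fold_of == fold].copy()
    train["idw"] = idw_training_features(train, "y", idw_cfg).to_numpy()
    valid["idw"] = idw_training_features(
        train, "y", idw_cfg, query=valid, exclude_self=False).to_numpy()
    return train, valid


def cross_validate(
    table: pd.DataFrame,
    hp: Hyperparameters,
    folds: Mapping[str, int] | None = None,
    seed: int = 0,
    idw_cfg: IdwConfig = IdwConfig(),
    dv_kind: str = "mean",
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
    weight_scheme: str = "inverse_density",
    weight_radius_km: float = 50.0,
) -> CVResult:
    """Station-level k-fold CV of the boosted-residual model.

    ``table`` is an assembled feature table with observed DV column ``y``.
    Every row receives exactly one out-of-fold prediction. Deterministic
    given ``seed`` (which also seeds fold assignment when ``folds`` is
    None).
    """
    if folds is None:
        folds = make_folds(table["station_id"].unique(), seed=seed)
    covered = set(table["station_id"]) - set(folds)
    if covered:
        raise ValueError(f"folds do not cover stations: {sorted(covered)[:10]}")
    out = table.reset_index(drop=True).copy()
    out["fold"] = out["station_id"].map(folds)
    out["prediction"] = np.nan
    out["cv_idw"] = np.nan
    models = {}
    for fold in sorted(set(folds.values())):
        train, valid = _fold_idw(out, folds, fold, idw_cfg)
        m = xis_model.fit(train, hp, seed=seed, dv_kind=dv_kind,
                          feature_columns=feature_columns)
        models[fold] = m
        if len(valid):
            out.loc[valid.index, "prediction"] = xis_model.predict(m, valid)
            out.loc[valid.index, "cv_idw"] = valid["idw"].to_numpy()
    w = station_weights(out, scheme=weight_scheme, radius_km=weight_radius_km)
    out["weight"] = out["station_id"].map(w).to_numpy()
    assert np.isfinite(out["prediction"]).all(), "some rows lack an out-of-fold prediction"
    return CVResult(rows=out, fold_models=models, folds=dict(folds),
                    weight_scheme=weight_scheme)


# ---------------------------------------------------------------------------
# baselines

def _ols_predict(train: pd.DataFrame, valid: pd.DataFrame,
                 feature_columns: Sequence[str]) -> np.ndarray:
    """OLS with the same predictors, per-feature training-median imputation."""
    Xt = train[list(feature_columns)].to_numpy(dtype=float)
    Xv = valid[list(feature_columns)].to_numpy(dtype=float)
    med = np.nanmedian(Xt, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    Xt = np.where(np.isfinite(Xt), Xt, med)
    Xv = np.where(np.isfinite(Xv), Xv, med)
    yt = train["y"].to_numpy(dtype=float)
    reg = LinearRegression().fit(Xt, yt)
    if not np.all(np.isfinite(reg.coef_)):
        warnings.warn("singular OLS design; falling back to ridge", stacklevel=2)
        reg = Ridge(alpha=1e-6).fit(Xt, yt)
    return reg.predict(Xv)


def compare_baselines(
    table: pd.DataFrame,
    hp: Hyperparameters,
    folds: Mapping[str, int] | None = None,
    seed: int = 0,
    idw_cfg: IdwConfig = IdwConfig(),
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
    weight_scheme: str = "inverse_density",
    weight_radius_km: float = 50.0,
) -> dict[str, float]:
    """Weighted CV RMSE of IDW-alone, OLS and the boosted-residual model.

    All three use identical folds, identical per-fold IDW features, and the
    identical weighted-RMSE evaluation; they differ only in the predictor.
    """
    if folds is None:
        folds = make_folds(table["station_id"].unique(), seed=seed)
    cv = cross_validate(table, hp, folds=folds, seed=seed, idw_cfg=idw_cfg,
                        feature_columns=feature_columns,
                        weight_scheme=weight_scheme,
                        weight_radius_km=weight_radius_km)
    out_rows = cv.rows
    preds_ols = np.full(len(out_rows), np.nan)
    for fold in sorted(set(folds.values())):
        train, valid = _fold_idw(out_rows, folds, fold, idw_cfg)
        if len(valid):
            preds_ols[valid.index.to_numpy()] = _ols_predict(
                train, valid, feature_columns)
    y = out_rows["y"].to_numpy()
    w = out_rows["weight"].to_numpy()
    idw_pred = out_rows["cv_idw"].to_numpy()
    # rows with no neighbor at all fall back to the training-mean convention
    idw_pred = np.where(np.isfinite(idw_pred), idw_pred, float(np.mean(y)))
    return {
        "idw_only": weighted_metrics(y, idw_pred, w)[1],
        "ols": weighted_metrics(y, preds_ols, w)[1],
        "xis": weighted_metrics(y, out_rows["prediction"].to_numpy(), w)[1],
    }


# ---------------------------------------------------------------------------
# attribution summaries

def attribution_summary(
    model: XisModel,
    table: pd.DataFrame,
    region_map: Mapping[str, str] | None = None,
    atol: float = 1e-4,
) -> pd.DataFrame:
    """Mean absolute per-feature attribution, overall and per region.

    Verifies additivity first: per row, attributions plus the base value
    must reproduce the ensemble's residual output to ``atol`` kelvins.
    """
    contrib = xis_model.attributions(model, table)
    margin = xis_model.ensemble_margin(model, table)
    gap = np.abs(contrib.sum(axis=1).to_numpy() - margin)
    if gap.max() > atol:
        raise AssertionError(
            f"attribution additivity violated: max gap {gap.max():.2e} K")
    feat = contrib.drop(columns="base").abs()
    rows = {"overall": feat.mean()}
    if region_map is not None:
        regions = table["station_id"].map(region_map)
        for region in sorted(regions.dropna().unique()):
            rows[region] = feat[(regions == region).to_numpy()].mean()
    return pd.DataFrame(rows).T
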