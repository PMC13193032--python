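"""The boosted-residual estimator and its tuning machinery.

The estimator ("XIS": XGBoost–IDW synthesis) models the residual between
observations and their inverse-distance-weighted estimates with gradient-
boosted regression trees, so the final prediction is

    prediction = IDW feature + tree_ensemble(predictor vector).

Each year and dependent variable is modeled separately. Hyperparameter
search draws candidate vectors from a maximin-optimized Latin hypercube and
ranks them by RMSEZ — per-region-per-year weighted RMSEs standardized to
z-scores across candidates, summarized by their mean and max.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from .features import FEATURE_COLUMNS

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class Hyperparameters:
    """XGBoost settings for one dependent variable."""

    nrounds: int = 500
    max_depth: int = 9
    eta: float = 0.078
    gamma: float = 0.38
    lambda_: float = 360.0
    alpha: float = 0.57

    def __post_init__(self):
        if self.nrounds < 0 or self.max_depth < 1:
            raise ValueError("nrounds must be >= 0 and max_depth >= 1")
        if not 0.0 < self.eta <= 1.0:
            raise ValueError("eta must lie in (0, 1]")
        if min(self.gamma, self.lambda_, self.alpha) < 0:
            raise ValueError("gamma, lambda and alpha must be >= 0")

    def to_xgb_params(self, seed: int = 0) -> dict:
        # subsampling/colsampling fixed at 1.0: the tuned set is complete
        return {
            "max_depth": self.max_depth,
            "eta": self.eta,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "alpha": self.alpha,
            "subsample": 1.0,
            "colsample_bytree": 1.0,
            "objective": "reg:squarederror",
            "base_score": 0.0,
            "tree_method": "hist",
            "nthread": 1,
            "seed": int(seed),
        }


#: Tuned hyperparameters per dependent variable. T-min and mean humidity
#: share a vector; T-max humidity uses a gentler learning rate and lighter
#: L2/L1 penalties.
DEFAULT_HYPERPARAMETERS: dict[str, Hyperparameters] = {
    "min": Hyperparameters(500, 9, 0.078, 0.38, 360.0, 0.57),
    "mean": Hyperparameters(500, 9, 0.078, 0.38, 360.0, 0.57),
    "max": Hyperparameters(500, 9, 0.051, 0.37, 120.0, 0.28),
}


def default_hyperparameters(dv_kind: str) -> Hyperparameters:
    """The tuned hyperparameter vector for a dependent variable."""
    try:
        return DEFAULT_HYPERPARAMETERS[dv_kind]
    except KeyError:
        raise ValueError(f"unknown dv_kind: {dv_kind!r}") from None


@dataclasses.dataclass
class XisModel:
    """A fitted boosted-residual model plus everything needed to reapply it."""

    dv_kind: str
    hyperparameters: Hyperparameters
    booster: xgb.Booster
    feature_columns: list[str]
    idw_fallback: float  # substitute for a missing IDW feature: training-mean DV
    idw_config: Mapping | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(d / "ensemble.json")
        meta = {
            "dv_kind": self.dv_kind,
            "hyperparameters": dataclasses.asdict(self.hyperparameters),
            "feature_columns": self.feature_columns,
            "idw_fallback": self.idw_fallback,
            "idw_config": dict(self.idw_config) if self.idw_config else None,
            "metadata": self.metadata,
        }
        (d / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "XisModel":
        d = pathlib.Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        booster = xgb.Booster()
        booster.load_model(d / "ensemble.json")
        return cls(
            dv_kind=meta["dv_kind"],
            hyperparameters=Hyperparameters(**meta["hyperparameters"]),
            booster=booster,
            feature_columns=meta["feature_columns"],
            idw_fallback=meta["idw_fallback"],
            idw_config=meta.get("idw_config"),
            metadata=meta.get("metadata", {}),
        )


def _design_matrix(table: pd.DataFrame, columns: Sequence[str]) -> xgb.DMatrix:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    X = table[list(columns)].to_numpy(dtype=float)
    return xgb.DMatrix(X, feature_names=list(columns), missing=np.nan)


def _idw_with_fallback(table: pd.DataFrame, fallback: float) -> np.ndarray:
    idw = table["idw"].to_numpy(dtype=float)
    return np.where(np.isfinite(idw), idw, fallback)


def fit(
    table: pd.DataFrame,
    hp: Hyperparameters,
    seed: int = 0,
    dv_kind: str = "mean",
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
    idw_config: Mapping | None = None,
) -> XisModel:
    """Fit the tree ensemble to the observation-minus-IDW residual.

    Every row must carry the observed DV in column ``y``. Rows whose IDW
    feature is missing (single-station days) use the training-set mean DV
    as the baseline; the trees still see the missing IDW slot and can react
    to the missingness itself. Deterministic given ``seed``.
    """
    if len(table) == 0:
        raise ValueError("cannot fit on an empty feature table")
    y = table["y"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("observed DV column y contains non-finite values")
    fallback = float(np.mean(y))
    baseline = _idw_with_fallback(table, fallback)
    dtrain = _design_matrix(table, feature_columns)
    dtrain.set_label(y - baseline)
    booster = xgb.train(hp.to_xgb_params(seed), dtrain,
                        num_boost_round=hp.nrounds)
    return XisModel(
        dv_kind=dv_kind,
        hyperparameters=hp,
        booster=booster,
        feature_columns=list(feature_columns),
        idw_fallback=fallback,
        idw_config=idw_config,
        metadata={"n_train": int(len(table)), "seed": int(seed)},
    )


def predict(model: XisModel, table: pd.DataFrame) -> np.ndarray:
    """prediction = IDW feature (or fallback) + ensemble residual."""
    extra = [c for c in table.columns if c in model.feature_columns]
    if set(extra) != set(model.feature_columns):
        raise ValueError(
            "feature table does not match the model's registry snapshot: "
            f"missing {sorted(set(model.feature_columns) - set(table.columns))}")
    baseline = _idw_with_fallback(table, model.idw_fallback)
    margin = ensemble_margin(model, table)
    return baseline + margin


def ensemble_margin(model: XisModel, table: pd.DataFrame) -> np.ndarray:
    """The raw tree-ensemble output (the modeled residual), in kelvins."""
    if model.hyperparameters.nrounds == 0 or model.booster.num_boosted_rounds() == 0:
        return np.zeros(len(table))
    dmat = _design_matrix(table, model.feature_columns)
    return model.booster.predict(dmat).astype(float)


def attributions(model: XisModel, table: pd.DataFrame) -> pd.DataFrame:
    """Per-row additive feature attributions of the residual prediction.

    Exact tree-path attributions: for each row the per-feature columns plus
    ``base`` sum to the ensemble's residual output. A zero-round model
    attributes zero to everything.
    """
    cols = model.feature_columns
    if model.hyperparameters.nrounds == 0 or model.booster.num_boosted_rounds() == 0:
        return pd.DataFrame(np.zeros((len(table), len(cols) + 1)),
                            columns=cols + ["base"], index=table.index)
    dmat = _design_matrix(table, cols)
    contrib = model.booster.predict(dmat, pred_contribs=True)
    return pd.DataFrame(contrib, columns=cols + ["base"], index=table.index)


# ---------------------------------------------------------------------------
# hyperparameter search

#: Default search box for candidate sampling. ``int`` parameters are rounded
#: after scaling; ``log`` parameters are sampled uniformly in log10 space.
DEFAULT_SEARCH_BOUNDS: dict[str, tuple[float, float, str]] = {
    "nrounds": (50, 1000, "int"),
    "max_depth": (2, 12, "int"),
    "eta": (0.01, 0.3, "log"),
    "gamma": (0.0, 2.0, "linear"),
    "lambda_": (1.0, 1000.0, "log"),
    "alpha": (0.0, 2.0, "linear"),
}


def _lhs_unit(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    """One random Latin hypercube on the unit cube: per dimension the n
    points occupy distinct equal-width strata."""
    u = (rng.random((n, dim)) + np.stack(
        [rng.permutation(n) for _ in range(dim)], axis=1)) / n
    return u


def maximin_lhs(n: int, dim: int, seed: int = 0, n_designs: int = 100) -> np.ndarray:
    """Best of ``n_designs`` random Latin hypercubes by maximin criterion.

    Returns the design (shape ``(n, dim)``, unit cube) maximizing the
    minimum pairwise Euclidean distance. Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("need at least 2 candidates")
    rng = np.random.default_rng(seed)
    best, best_score = None, -np.inf
    for _ in range(n_designs):
        u = _lhs_unit(n, dim, rng)
        d2 = np.sum((u[:, None, :] - u[None, :, :]) ** 2, axis=-1)
        score = np.sqrt(d2[np.triu_indices(n, 1)].min())
        if score > best_score:
            best, best_score = u, score
    return best


def sample_candidates(
    n: int,
    bounds: Mapping[str, tuple[float, float, str]] = DEFAULT_SEARCH_BOUNDS,
    seed: int = 0,
    n_designs: int = 100,
) -> list[Hyperparameters]:
    """Draw ``n`` hyperparameter vectors from a maximin Latin hypercube."""
    names = list(bounds)
    u = maximin_lhs(n, len(names), seed=seed, n_designs=n_designs)
    out = []
    for row in u:
        kw = {}
        for x, name in zip(row, names):
            lo, hi, kind = bounds[name]
            if kind == "log":
                val = 10 ** (np.log10(lo) + x * (np.log10(hi) - np.log10(lo)))
            else:
                val = lo + x * (hi - lo)
            kw[name] = int(round(val)) if kind == "int" else float(val)
        out.append(Hyperparameters(**kw))
    return out


def rmsez(scores: pd.DataFrame) -> pd.DataFrame:
    """Standardize a candidate × region-year RMSE matrix into z-scores.

    Each column (one climate region in one tuning year) is standardized to
    mean 0, SD 1 *across candidates* (sample SD, n−1), making candidates
    comparable; a zero-variance column contributes z = 0 with a warning.
    Returns per-candidate ``rmsez_mean`` and ``rmsez_max`` (lower is
    better), indexed like ``scores``.
    """
    if scores.isna().any().any():
        raise ValueError("RMSE matrix has missing cells")
    z = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=float)
    for col in scores.columns:
        sd = scores[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            log.warning("zero-variance RMSE column %r; z-scores set to 0", col)
            z[col] = 0.0
        else:
            z[col] = (scores[col] - scores[col].mean()) / sd
    return pd.DataFrame({
        "rmsez_mean": z.mean(axis=1),
        "rmsez_max": z.max(axis=1),
    })
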