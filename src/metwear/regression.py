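"""Window-level MET regression with tree ensembles.

Three interchangeable regressors — gradient-boosted trees (XGBoost), random
forest, and leaf-wise gradient boosting (LightGBM) — are tuned by seeded
random search over a shared hyperparameter space, scored with grouped
cross-validation on training participants only, and evaluated with MAPE and
MSE.  The split is always at the participant level so windows from one
individual never appear on both sides.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold, KFold

from .features import FEATURE_COLUMNS, TARGET_COLUMN, NormalizationModel, apply_normalizer, fit_normalizer

KINDS = ("gradient_boosted_trees", "random_forest", "light_gradient_boosting")

#: Shared random-search space: tree count, depth, learning rate
#: (log-uniform; ignored by the random forest), and row/column subsampling.
DEFAULT_SEARCH_SPACE = {
    "n_estimators": (100, 600),
    "max_depth": (3, 9),
    "learning_rate": (0.02, 0.3),
    "subsample": (0.6, 1.0),
    "colsample": (0.6, 1.0),
}


class SchemaError(ValueError):
    """Prediction rows do not match the training feature layout."""


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test participant sets from a seeded shuffle."""

    train_ids: tuple
    test_ids: tuple
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test participants overlap")


@dataclass
class RegressorHandle:
    """A fitted model bundle: kind, chosen hyperparameters, the estimator,
    the training normalizer, and the feature layout it expects."""

    kind: str
    hyperparameters: dict
    model: object
    normalizer: NormalizationModel
    feature_columns: tuple = FEATURE_COLUMNS
    fitted: bool = False
    cv_mse: float = math.nan

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "RegressorHandle":
        with open(path, "rb") as fh:
            handle = pickle.load(fh)
        if not isinstance(handle, RegressorHandle):
            raise TypeError(f"{path} does not contain a model bundle")
        return handle


@dataclass(frozen=True)
class EvalMetrics:
    """MAPE (stored as a fraction, not percent) and MSE."""

    mape: float
    mse: float


def split_by_subject(ids, ratio: float = 0.8, seed: int = 0) -> SplitPlan:
    """Seeded uniform shuffle of the participant ids; the first
    ceil(ratio * n) go to training.  Deterministic for a fixed seed."""
    ids = sorted(set(ids))
    if len(ids) < 2:
        raise ValueError("subject-level split needs at least 2 participants")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = math.ceil(ratio * len(ids))
    train = tuple(ids[i] for i in perm[:n_train])
    test = tuple(ids[i] for i in perm[n_train:])
    return SplitPlan(train_ids=train, test_ids=test, ratio=ratio, seed=seed)


def _sample_config(rng: np.random.Generator, space: dict) -> dict:
    lo, hi = space["n_estimators"]
    cfg = {"n_estimators": int(rng.integers(lo, hi + 1))}
    lo, hi = space["max_depth"]
    cfg["max_depth"] = int(rng.integers(lo, hi + 1))
    lo, hi = space["learning_rate"]
    cfg["learning_rate"] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lo, hi = space["subsample"]
    cfg["subsample"] = float(rng.uniform(lo, hi))
    lo, hi = space["colsample"]
    cfg["colsample"] = float(rng.uniform(lo, hi))
    return cfg


def _make_model(kind: str, cfg: dict, seed: int):
    if kind == "gradient_boosted_trees":
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=cfg["n_estimators"],
            max_depth=cfg["max_depth"],
            learning_rate=cfg["learning_rate"],
            subsample=cfg["subsample"],
            colsample_bytree=cfg["colsample"],
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
    if kind == "random_forest":
        return RandomForestRegressor(
            n_estimators=cfg["n_estimators"],
            max_depth=cfg["max_depth"],
            max_samples=cfg["subsample"] if cfg["subsample"] < 1.0 else None,
            max_features=cfg["colsample"],
            random_state=seed,
            n_jobs=1,
        )
    if kind == "light_gradient_boosting":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(
            n_estimators=cfg["n_estimators"],
            max_depth=cfg["max_depth"],
            learning_rate=cfg["learning_rate"],
            subsample=cfg["subsample"],
            subsample_freq=1,
            colsample_bytree=cfg["colsample"],
            random_state=seed,
            n_jobs=1,
            verbose=-1,
        )
    raise ValueError(f"unknown regressor kind {kind!r}; expected one of {KINDS}")


def tune_and_train(
    table: pd.DataFrame,
    plan: SplitPlan,
    kind: str = "gradient_boosted_trees",
    budget: int = 30,
    seed: int = 0,
    search_space: dict = DEFAULT_SEARCH_SPACE,
) -> RegressorHandle:
    """Random-search tuning + final fit on the training participants.

    Each of ``budget`` sampled configurations is scored by grouped k-fold
    cross-validation (k = min(3, number of training participants)) so inner
    validation folds are also subject-disjoint; the configuration with the
    lowest mean validation MSE (first wins ties) is refitted on all training
    rows.  Fully deterministic for fixed seed and inputs.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown regressor kind {kind!r}; expected one of {KINDS}")
    if budget < 1:
        raise ValueError("search budget must be at least 1")
    train = table[table["participant_id"].isin(plan.train_ids)]
    if len(train) < 10:
        raise ValueError(f"need at least 10 training rows, got {len(train)}")
    normalizer = fit_normalizer(train)
    scaled = apply_normalizer(normalizer, train)
    X = scaled[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)
    y = train[TARGET_COLUMN].to_numpy(dtype=np.float64)
    groups = train["participant_id"].to_numpy()

    n_groups = len(np.unique(groups))
    if n_groups >= 2:
        splitter = GroupKFold(n_splits=min(3, n_groups))
        folds = list(splitter.split(X, y, groups))
    else:
        folds = list(KFold(n_splits=3, shuffle=True, random_state=seed).split(X, y))

    rng = np.random.default_rng(seed)
    best_cfg, best_score = None, np.inf
    for _ in range(budget):
        cfg = _sample_config(rng, search_space)
        fold_mse = []
        for tr, va in folds:
            model = _make_model(kind, cfg, seed)
            model.fit(X[tr], y[tr])
            resid = model.predict(X[va]) - y[va]
            fold_mse.append(float(np.mean(resid**2)))
        score = float(np.mean(fold_mse))
        if score < best_score:
            best_cfg, best_score = cfg, score

    final = _make_model(kind, best_cfg, seed)
    final.fit(X, y)
    return RegressorHandle(
        kind=kind,
        hyperparameters=best_cfg,
        model=final,
        normalizer=normalizer,
        feature_columns=FEATURE_COLUMNS,
        fitted=True,
        cv_mse=best_score,
    )


def predict(handle: RegressorHandle, rows: pd.DataFrame) -> np.ndarray:
    """Per-window MET predictions, clipped at 0 (negative MET is
    physically meaningless)."""
    if not handle.fitted:
        raise ValueError("model has not been fitted")
    missing = [c for c in handle.feature_columns if c not in rows.columns]
    if missing:
        raise SchemaError(f"prediction rows are missing feature columns: {missing}")
    if len(rows) == 0:
        return np.empty(0, dtype=np.float64)
    scaled = apply_normalizer(handle.normalizer, rows)
    X = scaled[list(handle.feature_columns)].to_numpy(dtype=np.float64)
    return np.clip(handle.model.predict(X).astype(np.float64), 0.0, None)


def evaluate(y: np.ndarray, y_hat: np.ndarray) -> EvalMetrics:
    """MAPE (as a fraction) and MSE between targets and predictions."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if len(y) == 0 or len(y) != len(y_hat):
        raise ValueError("targets and predictions must share a nonzero length")
    if np.any(y == 0):
        raise ValueError("MAPE is undefined when a target value is 0")
    mape = float(np.mean(np.abs((y_hat - y) / y)))
    mse = float(np.mean((y_hat - y) ** 2))
    return EvalMetrics(mape=mape, mse=mse)
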