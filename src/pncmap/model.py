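"""Gradient-boosted PNC regression with spatial/temporal validation.

The exposure model maps the 14 gridded covariates of a station cell to its
annual-mean PNC. The base learner is XGBoost (configured, not
reimplemented); this module owns the protocol around it: the nested 90/10
train/validation/test split, exhaustive grid search, 10-fold cross
validation, spatial and temporal leave-one-group-out CV, the evaluation
metrics, and population-density-stratified summaries.

All metrics are computed strictly on held-out predictions; each observation
is predicted exactly once per validation scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, LeaveOneGroupOut
from xgboost import XGBRegressor

from .fusion import FEATURE_NAMES, FeatureTable

#: Searched hyperparameter ranges; configurations outside them are rejected.
SEARCH_RANGES = {
    "n_estimators": (30, 250),
    "n_parallel_trees": (1, 10),
    "max_depth": (3, 15),
    "learning_rate": (0.01, 0.5),
    "subsample": (0.3, 1.0),
    "colsample": (0.3, 1.0),
}

#: Default discrete search grid (the searched ranges, discretized).
DEFAULT_GRID = {
    "n_estimators": (30, 100, 250),
    "n_parallel_trees": (1, 5, 10),
    "max_depth": (3, 10, 15),
    "learning_rate": (0.01, 0.03, 0.1, 0.5),
    "subsample": (0.3, 0.75, 1.0),
    "colsample": (0.3, 0.75, 1.0),
}

#: Population-density class limits (people per km^2): rural < 250,
#: suburban 250-800 (inclusive), urban > 800.
POPULATION_LIMITS = (250.0, 800.0)


@dataclass(frozen=True)
class ModelConfig:
    """Tuned XGBoost configuration (defaults = the selected optimum)."""

    n_estimators: int = 250
    n_parallel_trees: int = 1
    max_depth: int = 10
    learning_rate: float = 0.03
    subsample: float = 0.75
    colsample: float = 0.75
    gamma: float = 0.0
    reg_lambda: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in SEARCH_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside the searched range [{lo}, {hi}]")
        if self.gamma < 0 or self.reg_lambda < 0:
            raise ValueError("regularization strengths must be non-negative")

    def make_regressor(self) -> XGBRegressor:
        return XGBRegressor(
            n_estimators=self.n_estimators,
            num_parallel_tree=self.n_parallel_trees,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            subsample=self.subsample,
            colsample_bytree=self.colsample,
            gamma=self.gamma,
            reg_lambda=self.reg_lambda,
            random_state=self.seed,
            objective="reg:squarederror",
            n_jobs=1,
            verbosity=0,
        )


@dataclass(frozen=True)
class TargetScaler:
    """Min-max scaling of the target to [0, 1], fit on the training split."""

    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not self.y_max > self.y_min:
            raise ValueError("constant target: cannot scale")

    def forward(self, y) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_min) / (self.y_max - self.y_min)

    def inverse(self, s) -> np.ndarray:
        return np.asarray(s, dtype=float) * (self.y_max - self.y_min) + self.y_min

    @property
    def span(self) -> float:
        return self.y_max - self.y_min


def scale_target(y: Sequence[float]) -> tuple[np.ndarray, TargetScaler]:
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("need at least two distinct target values")
    scaler = TargetScaler(y_min=float(y.min()), y_max=float(y.max()))
    return scaler.forward(y), scaler


# ---------------------------------------------------------------------------
# Metrics and reports
# ---------------------------------------------------------------------------

def compute_metrics(y: Sequence[float], y_hat: Sequence[float]) -> dict:
    """MAE, RMSE, R^2 and mean percentage error (100*mean|y-yhat|/y)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch between observations and predictions")
    if y.size < 2:
        raise ValueError("need at least two points")
    err = y - y_hat
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    out = {
        "MAE": float(np.mean(np.abs(err))),
        "RMSE": float(np.sqrt(np.mean(err**2))),
        "R2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
    }
    out["mean_pct_error"] = (
        float(100.0 * np.mean(np.abs(err) / y)) if np.all(y > 0) else None
    )
    return out


@dataclass
class EvalReport:
    """Held-out evaluation for one validation scheme."""

    scheme: str
    mae: float
    rmse: float
    r2: float
    mean_pct_error: float | None
    predictions: pd.DataFrame  # columns: station_id, year, y, y_hat

    @classmethod
    def from_predictions(cls, scheme: str, predictions: pd.DataFrame) -> "EvalReport":
        m = compute_metrics(predictions["y"], predictions["y_hat"])
        return cls(
            scheme=scheme,
            mae=m["MAE"],
            rmse=m["RMSE"],
            r2=m["R2"],
            mean_pct_error=m["mean_pct_error"],
            predictions=predictions.reset_index(drop=True),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "scheme": self.scheme,
            "MAE": self.mae,
            "RMSE": self.rmse,
            "R2": self.r2,
            "mean_pct_error": self.mean_pct_error,
            "n": int(len(self.predictions)),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


# ---------------------------------------------------------------------------
# Split protocol and grid search
# ---------------------------------------------------------------------------

def split_protocol(
    table: FeatureTable, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Nested 90/10 splits: test first, then validation from the remainder.

    Returns (train, val, test) as disjoint row subsets whose union is the
    full table; membership is a seeded shuffle.
    """
    n = len(table)
    if n < 20:
        raise ValueError(f"need at least 20 rows to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(0.1 * n))
    n_val = int(round(0.1 * (n - n_test)))
    test_idx = order[:n_test]
    val_idx = order[n_test : n_test + n_val]
    train_idx = order[n_test + n_val :]
    f = table.frame
    return (
        f.iloc[train_idx].reset_index(drop=True),
        f.iloc[val_idx].reset_index(drop=True),
        f.iloc[test_idx].reset_index(drop=True),
    )


def _iter_grid(grid: Mapping[str, Sequence]) -> Iterable[dict]:
    keys = list(grid)
    if not keys or any(len(grid[k]) == 0 for k in keys):
        raise ValueError("empty search grid")
    def rec(i, acc):
        if i == len(keys):
            yield dict(acc)
            return
        for v in grid[keys[i]]:
            acc[keys[i]] = v
            yield from rec(i + 1, acc)
    yield from rec(0, {})


def grid_search(
    train: pd.DataFrame,
    val: pd.DataFrame,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustive search over a discrete grid, scored by validation RMSE.

    Ties are broken by fewer estimators, then shallower trees. Returns the
    winning configuration and the full score table.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    X_tr, y_tr = train[list(FEATURE_NAMES)], train["pnc_annual"]
    X_va, y_va = val[list(FEATURE_NAMES)], val["pnc_annual"]
    rows = []
    for point in _iter_grid(grid):
        cfg = ModelConfig(seed=seed, **point)
        reg = cfg.make_regressor()
        reg.fit(X_tr, y_tr)
        rmse = compute_metrics(y_va, reg.predict(X_va))["RMSE"]
        rows.append({**point, "val_rmse": rmse})
    scores = pd.DataFrame(rows)
    best = scores.sort_values(
        ["val_rmse", "n_estimators", "max_depth"], kind="mergesort"
    ).iloc[0]
    best_cfg = ModelConfig(
        seed=seed, **{k: best[k] for k in grid if k in ModelConfig.__dataclass_fields__}
    )
    return best_cfg, scores


# ---------------------------------------------------------------------------
# Cross-validation schemes
# ---------------------------------------------------------------------------

def _check_no_leakage(train_keys: pd.DataFrame, test_keys: pd.DataFrame) -> None:
    merged = train_keys.merge(test_keys, on=["station_id", "year"], how="inner")
    if len(merged):
        raise AssertionError("(station, year) key leaked between train and test")


def kfold_cv(
    table: FeatureTable, config: ModelConfig, k: int = 10, seed: int = 0
) -> EvalReport:
    """Random k-fold CV: each row predicted exactly once while held out."""
    n = len(table)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    f = table.frame
    preds = pd.Series(index=f.index, dtype=float)
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True, random_state=seed).split(f):
        _check_no_leakage(
            f.iloc[train_idx][["station_id", "year"]],
            f.iloc[test_idx][["station_id", "year"]],
        )
        reg = config.make_regressor()
        reg.fit(f.iloc[train_idx][list(FEATURE_NAMES)], f.iloc[train_idx]["pnc_annual"])
        preds.iloc[test_idx] = reg.predict(f.iloc[test_idx][list(FEATURE_NAMES)])
    out = f[["station_id", "year"]].copy()
    out["y"] = f["pnc_annual"]
    out["y_hat"] = preds
    return EvalReport.from_predictions(f"{k}-fold CV", out)


def group_loocv(
    table: FeatureTable, config: ModelConfig, group_key: str
) -> EvalReport:
    """Leave-one-group-out CV by station (spatial) or year (temporal)."""
    if group_key not in ("station_id", "year"):
        raise ValueError("group_key must be 'station_id' or 'year'")
    f = table.frame
    groups = f[group_key].to_numpy()
    if np.unique(groups).size < 3:
        raise ValueError("need at least 3 distinct groups")
    preds = pd.Series(index=f.index, dtype=float)
    for train_idx, test_idx in LeaveOneGroupOut().split(f, groups=groups):
        assert not set(groups[train_idx]) & set(groups[test_idx])
        reg = config.make_regressor()
        reg.fit(f.iloc[train_idx][list(FEATURE_NAMES)], f.iloc[train_idx]["pnc_annual"])
        preds.iloc[test_idx] = reg.predict(f.iloc[test_idx][list(FEATURE_NAMES)])
    out = f[["station_id", "year"]].copy()
    out["y"] = f["pnc_annual"]
    out["y_hat"] = preds
    scheme = "spatial LOOCV" if group_key == "station_id" else "temporal LOOCV"
    return EvalReport.from_predictions(scheme, out)


# ---------------------------------------------------------------------------
# Population-stratified summaries
# ---------------------------------------------------------------------------

def classify_population(density, limits: tuple[float, float] = POPULATION_LIMITS):
    """Rural < limits[0]; suburban in [limits[0], limits[1]]; urban above."""
    d = np.asarray(density, dtype=float)
    cls = np.where(d < limits[0], "rural", np.where(d <= limits[1], "suburban", "urban"))
    return cls


def stratify_population(
    report: EvalReport,
    interval_widths: Sequence[float],
    pop_density: Sequence[float],
    limits: tuple[float, float] = POPULATION_LIMITS,
) -> pd.DataFrame:
    """Per population class: mean PNC, mean interval width +/- s.e.,
    mean percentage error +/- s.e. Empty classes are simply absent."""
    f = report.predictions
    if len(interval_widths) != len(f) or len(pop_density) != len(f):
        raise ValueError("interval widths and densities must match the report rows")
    df = f.copy()
    df["ci"] = np.asarray(interval_widths, dtype=float)
    df["pct_err"] = 100.0 * np.abs(df["y"] - df["y_hat"]) / df["y"]
    df["class"] = classify_population(pop_density, limits)

    def se(x):
        x = np.asarray(x, dtype=float)
        return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")

    rows = []
    for cls in ("rural", "suburban", "urban"):
        g = df[df["class"] == cls]
        if g.empty:
            continue
        rows.append(
            {
                "class": cls,
                "n": len(g),
                "mean_pnc": float(g["y"].mean()),
                "mean_ci": float(g["ci"].mean()),
                "se_ci": se(g["ci"]),
                "mean_pct_error": float(g["pct_err"].mean()),
                "se_pct_error": se(g["pct_err"]),
            }
        )
    return pd.DataFrame(rows)
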