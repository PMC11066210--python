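"""Regression models for AV-score estimation.

One pipeline is shared by all three model kinds: z-score normalization
fitted on training rows only, correlation-threshold feature selection
(multiple linear regression and support-vector regression only — the
boosted-tree model does its own feature weighting), then the regressor.
Hyperparameters for SVR and the gradient-boosted trees are chosen by an
exhaustive grid search scored on a single shuffled 80/20 train/validation
split of the training rows, with ties broken toward the least complex
model; the winner is refit on the full training fold.

The linear model is solved from first principles as an
orthogonal-decomposition least-squares problem (minimum-norm solution under
rank deficiency); SVR and the boosted trees are delegated to scikit-learn
and xgboost respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "Normalizer",
    "SelectionResult",
    "select_features",
    "prune_redundant",
    "MLRModel",
    "fit_mlr",
    "default_grid",
    "validate_hyperparameters",
    "grid_search",
    "TrainedModel",
    "train_model",
    "predict",
]

MODEL_KINDS = ("mlr", "svr", "gbt")

#: discrete grids spanning the documented search ranges
SVR_GRID: tuple[dict[str, Any], ...] = tuple(
    {"kernel": k, "C": c, "epsilon": e}
    for k in ("linear", "rbf")
    for c in (0.1, 1.0, 10.0)
    for e in (0.01, 0.05, 0.1, 0.2)
)
GBT_GRID: tuple[dict[str, Any], ...] = tuple(
    {"n_estimators": n, "max_depth": d, "colsample_bytree": s}
    for n in range(10, 201, 20)
    for d in (3, 5, 7, 9)
    for s in (0.1, 0.2, 0.3, 0.4, 0.5)
)


@dataclass
class Normalizer:
    """Per-feature z-scoring with statistics learned from training rows only.

    Zero-variance features pass through unscaled (sd treated as 1) so
    degenerate columns never produce non-finite values.
    """

    mean: pd.Series
    sd: pd.Series

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "Normalizer":
        if len(X) < 2:
            raise InvalidParameterError("Normalizer needs >= 2 training rows")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd = sd.where(sd > 0, 1.0)
        return cls(mean=mean, sd=sd)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.mean.index if c not in X.columns]
        if missing:
            raise InvalidParameterError(f"missing feature columns {missing}")
        X = X[self.mean.index]
        return (X - self.mean) / self.sd


def _abs_correlations(X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """|Pearson r| of each feature column with the target; constant → 0."""
    y = np.asarray(y, dtype=float)
    xv = X.to_numpy(dtype=float)
    xc = xv - xv.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * yc[:, None]).sum(axis=0) / denom, 0.0)
    return pd.Series(np.abs(r), index=X.columns)


@dataclass
class SelectionResult:
    """Outcome of correlation-threshold feature selection on one fold."""

    names: list[str]
    n_above_threshold: int
    fallback_used: bool


def select_features(
    X: pd.DataFrame, y: np.ndarray, threshold: float = 0.7
) -> SelectionResult:
    """Keep features with |Pearson r(feature, AV)| above ``threshold``.

    Computed on training rows only, preserving feature-table order. An
    empty selection falls back to the single highest-|r| feature (with a
    warning) so small folds never abort the pipeline.
    """
    if len(X) < 3:
        raise InvalidParameterError("feature selection needs >= 3 rows")
    r = _abs_correlations(X, y)
    names = [c for c in X.columns if r[c] > threshold]
    if names:
        return SelectionResult(names=names, n_above_threshold=len(names),
                               fallback_used=False)
    best = str(r.idxmax())
    warnings.warn(
        f"no feature exceeded |r| > {threshold}; falling back to {best!r}",
        stacklevel=2,
    )
    return SelectionResult(names=[best], n_above_threshold=0, fallback_used=True)


def prune_redundant(
    names: list[str],
    X: pd.DataFrame,
    y: np.ndarray,
    redundancy_threshold: float = 0.9,
) -> list[str]:
    """Greedy redundancy pruning among selected features.

    Visit features in descending |r(feature, AV)|; drop any feature whose
    |r| with an already-kept feature exceeds the redundancy threshold.
    """
    if not names:
        return []
    rel = _abs_correlations(X[names], y)
    order = sorted(names, key=lambda c: (-rel[c], names.index(c)))
    kept: list[str] = []
    for cand in order:
        redundant = False
        for k in kept:
            r = _abs_correlations(X[[cand]], X[k].to_numpy(float))[cand]
            if r > redundancy_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(cand)
    return [c for c in names if c in kept]


@dataclass
class MLRModel:
    """Multiple linear regression Y = β0 + β·X + ε, fit by least squares."""

    intercept: float
    coef: pd.Series  # aligned to selected feature names
    residual_sd: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.coef.index if c not in X.columns]
        if missing:
            raise InvalidParameterError(f"missing feature columns {missing}")
        return (
            self.intercept
            + X[self.coef.index].to_numpy(float) @ self.coef.to_numpy(float)
        )


def fit_mlr(X: pd.DataFrame, y: np.ndarray) -> MLRModel:
    """Ordinary least squares via orthogonal decomposition (numpy lstsq).

    Returns the minimum-norm solution (with a warning) when the design is
    rank-deficient; residuals are orthogonal to the design columns.
    """
    y = np.asarray(y, dtype=float)
    if len(X) < 2:
        raise InvalidParameterError("fit_mlr needs >= 2 rows")
    A = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            "rank-deficient design; using minimum-norm least-squares solution",
            stacklevel=2,
        )
    resid = y - A @ beta
    residual_sd = float(np.std(resid, ddof=1)) if len(y) > 1 else 0.0
    return MLRModel(
        intercept=float(beta[0]),
        coef=pd.Series(beta[1:], index=list(X.columns)),
        residual_sd=residual_sd,
    )


def default_grid(kind: str) -> list[dict[str, Any]]:
    if kind == "svr":
        return [dict(p) for p in SVR_GRID]
    if kind == "gbt":
        return [dict(p) for p in GBT_GRID]
    if kind == "mlr":
        return [{}]
    raise InvalidParameterError(f"unknown model kind {kind!r}")


def validate_hyperparameters(kind: str, hp: dict[str, Any]) -> None:
    """Check a hyperparameter point against the documented search ranges."""
    if kind == "svr":
        if hp.get("kernel") not in ("linear", "rbf"):
            raise InvalidParameterError(f"SVR kernel {hp.get('kernel')!r}")
        if not 0.1 <= float(hp.get("C", -1)) <= 10.0:
            raise InvalidParameterError("SVR C must lie in [0.1, 10]")
        if not 0.01 <= float(hp.get("epsilon", -1)) <= 0.2:
            raise InvalidParameterError("SVR epsilon must lie in [0.01, 0.2]")
    elif kind == "gbt":
        if not 10 <= int(hp.get("n_estimators", -1)) <= 200:
            raise InvalidParameterError("GBT n_estimators must lie in [10, 200]")
        if not 3 <= int(hp.get("max_depth", -1)) <= 10:
            raise InvalidParameterError("GBT max_depth must lie in [3, 10]")
        if not 0.1 <= float(hp.get("colsample_bytree", -1)) <= 0.5:
            raise InvalidParameterError(
                "GBT feature subsample rate must lie in [0.1, 0.5]"
            )
    elif kind == "mlr":
        if hp:
            raise InvalidParameterError("MLR takes no hyperparameters")
    else:
        raise InvalidParameterError(f"unknown model kind {kind!r}")


def _build_estimator(kind: str, hp: dict[str, Any], seed: int):
    validate_hyperparameters(kind, hp)
    if kind == "svr":
        from sklearn.svm import SVR

        return SVR(kernel=hp["kernel"], C=hp["C"], epsilon=hp["epsilon"])
    if kind == "gbt":
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=hp["n_estimators"],
            max_depth=hp["max_depth"],
            colsample_bytree=hp["colsample_bytree"],
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    raise InvalidParameterError(f"unknown backend kind {kind!r}")


def _complexity_key(kind: str, hp: dict[str, Any]) -> tuple:
    """Tie-break ordering: prefer the least complex model."""
    if kind == "gbt":
        return (hp["n_estimators"], hp["max_depth"], hp["colsample_bytree"])
    if kind == "svr":
        kernel_rank = 0 if hp["kernel"] == "linear" else 1
        return (hp["C"], -hp["epsilon"], kernel_rank)
    return ()


def _fit_backend(kind, hp, X, y, seed):
    if kind == "mlr":
        return fit_mlr(X, y)
    est = _build_estimator(kind, hp, seed)
    est.fit(X.to_numpy(dtype=float), np.asarray(y, dtype=float))
    return est


def _backend_predict(kind, model, X: pd.DataFrame) -> np.ndarray:
    if kind == "mlr":
        return model.predict(X)
    return np.asarray(model.predict(X.to_numpy(dtype=float)), dtype=float)


def grid_search(
    X: pd.DataFrame,
    y: np.ndarray,
    kind: str,
    grid: list[dict[str, Any]] | None = None,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[dict[str, Any], float]:
    """Pick hyperparameters on one shuffled train/validation split.

    Every grid point is fit on the (1 − ``val_fraction``) part and scored by
    validation MAE; the minimiser wins, ties broken toward lower complexity.
    Returns (best hyperparameters, validation MAE). Deterministic per seed.
    """
    if grid is None:
        grid = default_grid(kind)
    if not grid:
        raise InvalidParameterError("hyperparameter grid is empty")
    y = np.asarray(y, dtype=float)
    n = len(X)
    n_val = max(2, int(round(val_fraction * n)))
    if n - n_val < 2:
        raise InvalidParameterError("too few rows for an 80/20 split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_idx, fit_idx = order[:n_val], order[n_val:]
    X_fit, y_fit = X.iloc[fit_idx], y[fit_idx]
    X_val, y_val = X.iloc[val_idx], y[val_idx]

    best_hp, best_mae, best_key = None, np.inf, None
    for hp in sorted(grid, key=lambda h: _complexity_key(kind, h)):
        model = _fit_backend(kind, hp, X_fit, y_fit, seed)
        mae = float(np.mean(np.abs(y_val - _backend_predict(kind, model, X_val))))
        key = _complexity_key(kind, hp)
        if mae < best_mae - 1e-12 or (
            abs(mae - best_mae) <= 1e-12 and best_key is not None and key < best_key
        ):
            best_hp, best_mae, best_key = hp, mae, key
    return dict(best_hp), best_mae


@dataclass
class TrainedModel:
    """A fitted pipeline: normalizer → feature selection → regressor."""

    kind: str
    normalizer: Normalizer
    selected: list[str]
    model: Any
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    validation_mae: float = float("nan")
    selection: SelectionResult | None = None


def train_model(
    X: pd.DataFrame,
    y: np.ndarray,
    kind: str,
    selection_threshold: float = 0.7,
    prune_threshold: float | None = None,
    grid: list[dict[str, Any]] | None = None,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> TrainedModel:
    """Fit the full pipeline on one training fold.

    Normalization statistics, the feature selection and the grid-search
    split are all functions of the training rows only. ``prune_threshold``
    optionally enables redundancy pruning among the selected features.
    """
    if kind not in MODEL_KINDS:
        raise InvalidParameterError(f"unknown model kind {kind!r}")
    y = np.asarray(y, dtype=float)
    normalizer = Normalizer.fit(X)
    Xn = normalizer.transform(X)

    selection: SelectionResult | None = None
    if kind in ("mlr", "svr"):
        selection = select_features(Xn, y, threshold=selection_threshold)
        names = selection.names
        if prune_threshold is not None:
            names = prune_redundant(names, Xn, y, prune_threshold)
        selected = names
    else:  # boosted trees select internally
        selected = list(Xn.columns)
    Xs = Xn[selected]

    if kind == "mlr":
        hp: dict[str, Any] = {}
        # report a validation MAE from the same 80/20 protocol
        _, val_mae = grid_search(
            Xs, y, "mlr", [{}], val_fraction=val_fraction, seed=seed
        )
    else:
        hp, val_mae = grid_search(
            Xs, y, kind, grid, val_fraction=val_fraction, seed=seed
        )
    model = _fit_backend(kind, hp, Xs, y, seed)
    return TrainedModel(
        kind=kind,
        normalizer=normalizer,
        selected=selected,
        model=model,
        hyperparameters=hp,
        validation_mae=val_mae,
        selection=selection,
    )


def predict(trained: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Predict AV (inches/second): normalizer → selection → model."""
    Xn = trained.normalizer.transform(X)
    Xs = Xn[trained.selected]
    out = _backend_predict(trained.kind, trained.model, Xs)
    if not np.all(np.isfinite(out)):
        raise InvalidParameterError("model produced non-finite predictions")
    return out
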