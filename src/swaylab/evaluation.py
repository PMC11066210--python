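"""Subject-wise cross-validated evaluation of the AV-estimation pipeline.

Two subject-grouped protocols are supported — leave-one-subject-out (LOSO)
and grouped 5-fold — so no subject ever contributes rows to both the
training and the test side of a fold. One model serves all four balance
conditions. Test correlation is computed on the predictions pooled across
folds (the only well-defined choice under LOSO, where a fold holds four
points); per-fold MAEs are averaged with their standard deviation, and
per-condition MAE and MAPE (as a fraction) are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .errors import InvalidParameterError
from .features import FEATURE_NAMES
from .types import CONDITIONS

__all__ = [
    "loso_splits",
    "grouped_kfold",
    "mae",
    "pearson_r",
    "mape",
    "CVResult",
    "evaluate_pipeline",
    "feature_correlation_report",
]


def loso_splits(subjects: Sequence[str]) -> list[tuple[list[str], list[str]]]:
    """Leave-one-subject-out folds: one (train, test) pair per subject."""
    unique = list(dict.fromkeys(subjects))
    if len(unique) < 2:
        raise InvalidParameterError("LOSO needs >= 2 subjects")
    return [
        ([s for s in unique if s != test], [test]) for test in unique
    ]


def grouped_kfold(
    subjects: Sequence[str], k: int = 5, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Subject-grouped k-fold: shuffle subjects, split into k near-equal groups.

    Group sizes differ by at most one and every subject's rows share a fold.
    """
    unique = list(dict.fromkeys(subjects))
    if k < 2 or k > len(unique):
        raise InvalidParameterError(
            f"k must lie in [2, n_subjects]; got k={k}, n={len(unique)}"
        )
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    groups = [list(g) for g in np.array_split(order, k)]
    return [
        (sorted(s for g in groups[:i] + groups[i + 1 :] for s in g), sorted(groups[i]))
        for i in range(k)
    ]


def mae(truth: np.ndarray, pred: np.ndarray) -> float:
    truth, pred = np.asarray(truth, float), np.asarray(pred, float)
    if truth.size == 0 or truth.size != pred.size:
        raise InvalidParameterError("mae needs equal nonzero lengths")
    return float(np.mean(np.abs(truth - pred)))


def pearson_r(truth: np.ndarray, pred: np.ndarray) -> float:
    """Pearson correlation; NaN if either input is constant (undefined)."""
    truth, pred = np.asarray(truth, float), np.asarray(pred, float)
    if truth.size < 2 or truth.size != pred.size:
        raise InvalidParameterError("pearson_r needs equal lengths >= 2")
    if np.std(truth) == 0 or np.std(pred) == 0:
        return float("nan")
    return float(np.corrcoef(truth, pred)[0, 1])


def mape(truth: np.ndarray, pred: np.ndarray) -> float:
    """Mean absolute percentage error as a fraction; zero truths excluded."""
    truth, pred = np.asarray(truth, float), np.asarray(pred, float)
    if truth.size == 0 or truth.size != pred.size:
        raise InvalidParameterError("mape needs equal nonzero lengths")
    keep = truth != 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-truth rows from MAPE",
            stacklevel=2,
        )
    if not keep.any():
        raise InvalidParameterError("mape undefined: all truths are zero")
    return float(np.mean(np.abs(truth[keep] - pred[keep]) / truth[keep]))


@dataclass
class CVResult:
    """Predictions and aggregate metrics of one cross-validated evaluation."""

    cv_kind: str
    placements: list[str]
    model_kind: str
    predictions: pd.DataFrame  # subject_id, condition, fold, truth, pred
    test_mae_mean: float
    test_mae_sd: float
    test_r: float
    validation_mae_mean: float
    validation_mae_sd: float
    per_condition_mae: dict[str, float]
    per_condition_mape: dict[str, float]
    fold_details: list[dict[str, Any]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "cv_kind": self.cv_kind,
            "placements": self.placements,
            "model_kind": self.model_kind,
            "test_mae_mean": self.test_mae_mean,
            "test_mae_sd": self.test_mae_sd,
            "test_r": self.test_r,
            "validation_mae_mean": self.validation_mae_mean,
            "validation_mae_sd": self.validation_mae_sd,
            "per_condition_mae": self.per_condition_mae,
            "per_condition_mape": self.per_condition_mape,
            "folds": self.fold_details,
        }


def _model_matrix(
    features: pd.DataFrame, placements: Sequence[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Wide design matrix: one row per subject × condition.

    Sensor blocks (placement + role) are concatenated horizontally with
    placement-role-prefixed column names; missing subject × condition ×
    sensor combinations raise with the list of gaps.
    """
    sub = features[features["placement"].isin(placements)]
    if sub.empty:
        raise InvalidParameterError(f"no rows for placements {list(placements)}")
    sensors = sorted(set(zip(sub["placement"], sub["role"])))
    pieces = []
    for placement, role in sensors:
        block = sub[(sub["placement"] == placement) & (sub["role"] == role)]
        wide = block.set_index(["subject_id", "condition"])[list(FEATURE_NAMES)]
        dup = wide.index.duplicated()
        if dup.any():
            raise InvalidParameterError(
                f"duplicate rows for sensor {placement}/{role}"
            )
        wide.columns = [f"{placement}_{role}__{c}" for c in wide.columns]
        pieces.append(wide)
    X = pd.concat(pieces, axis=1)
    if X.isna().any().any():
        gaps = X[X.isna().any(axis=1)].index.tolist()
        raise InvalidParameterError(
            f"incomplete sensor coverage for rows {gaps[:5]}"
        )
    y = (
        sub.drop_duplicates(["subject_id", "condition"])
        .set_index(["subject_id", "condition"])["av_in_per_s"]
        .reindex(X.index)
    )
    if y.isna().any():
        raise InvalidParameterError("missing AV ground truth for some rows")
    return X.sort_index(), y.reindex(X.sort_index().index)


def evaluate_pipeline(
    features: pd.DataFrame,
    placements: str | Sequence[str],
    model_kind: str,
    cv_kind: str = "loso",
    k: int = 5,
    selection_threshold: float = 0.7,
    prune_threshold: float | None = None,
    grid: list[dict[str, Any]] | None = None,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> CVResult:
    """Cross-validate one placement set × model kind over a feature table.

    Per fold: fit the normalizer, select features (MLR/SVR), grid-search
    hyperparameters on a shuffled 80/20 split of the training rows, refit
    the winner on the whole training fold, predict the held-out subjects.
    Fully reproducible given the seed.
    """
    if isinstance(placements, str):
        placements = [placements]
    X, y = _model_matrix(features, placements)
    subjects = [s for s, _ in X.index]
    if cv_kind == "loso":
        folds = loso_splits(subjects)
    elif cv_kind in ("kfold", "grouped-5-fold"):
        folds = grouped_kfold(subjects, k=k, seed=seed)
    else:
        raise InvalidParameterError(f"unknown cv kind {cv_kind!r}")

    rows = []
    fold_details = []
    fold_maes, val_maes = [], []
    for fold_id, (train_subjects, test_subjects) in enumerate(folds):
        train_mask = np.array([s in set(train_subjects) for s, _ in X.index])
        test_mask = np.array([s in set(test_subjects) for s, _ in X.index])
        trained = _models.train_model(
            X[train_mask],
            y[train_mask].to_numpy(),
            model_kind,
            selection_threshold=selection_threshold,
            prune_threshold=prune_threshold,
            grid=grid,
            val_fraction=val_fraction,
            seed=seed + fold_id,
        )
        pred = _models.predict(trained, X[test_mask])
        truth = y[test_mask].to_numpy()
        fold_maes.append(mae(truth, pred))
        val_maes.append(trained.validation_mae)
        for (subj, cond), t, p in zip(X.index[test_mask], truth, pred):
            rows.append(
                {
                    "subject_id": subj,
                    "condition": cond,
                    "fold": fold_id,
                    "truth_av": float(t),
                    "pred_av": float(p),
                }
            )
        fold_details.append(
            {
                "fold": fold_id,
                "test_subjects": list(test_subjects),
                "selected_features": list(trained.selected),
                "n_above_threshold": (
                    trained.selection.n_above_threshold
                    if trained.selection is not None
                    else None
                ),
                "hyperparameters": dict(trained.hyperparameters),
                "validation_mae": trained.validation_mae,
                "test_mae": fold_maes[-1],
            }
        )

    preds = pd.DataFrame(rows)
    per_cond_mae, per_cond_mape = {}, {}
    for cond in CONDITIONS:
        c = preds[preds["condition"] == cond]
        if not c.empty:
            per_cond_mae[cond] = mae(c["truth_av"], c["pred_av"])
            per_cond_mape[cond] = mape(c["truth_av"], c["pred_av"])
    return CVResult(
        cv_kind=cv_kind,
        placements=list(placements),
        model_kind=model_kind,
        predictions=preds,
        test_mae_mean=float(np.mean(fold_maes)),
        test_mae_sd=float(np.std(fold_maes, ddof=1)) if len(fold_maes) > 1 else 0.0,
        test_r=pearson_r(preds["truth_av"], preds["pred_av"]),
        validation_mae_mean=float(np.mean(val_maes)),
        validation_mae_sd=(
            float(np.std(val_maes, ddof=1)) if len(val_maes) > 1 else 0.0
        ),
        per_condition_mae=per_cond_mae,
        per_condition_mape=per_cond_mape,
        fold_details=fold_details,
    )


def feature_correlation_report(
    features: pd.DataFrame, placement: str, threshold: float = 0.7
) -> pd.DataFrame:
    """Per-feature |r| with AV for one placement, with a significance flag.

    Rows of all sensors at the placement are pooled, giving one table of the
    42 canonical features ordered as extracted; ``significant`` marks
    |r| > ``threshold``.
    """
    sub = features[features["placement"] == placement]
    if sub.empty:
        raise InvalidParameterError(f"no rows for placement {placement!r}")
    r = _models._abs_correlations(
        sub[list(FEATURE_NAMES)], sub["av_in_per_s"].to_numpy()
    )
    return pd.DataFrame(
        {
            "feature": list(FEATURE_NAMES),
            "abs_r": [float(r[c]) for c in FEATURE_NAMES],
            "significant": [bool(r[c] > threshold) for c in FEATURE_NAMES],
        }
    )
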