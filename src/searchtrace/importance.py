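"""Permutation feature importance with AUC as the model score.

The importance of a feature is the drop in validation-fold AUC when that
feature's column is randomly shuffled: ``baseline AUC − mean AUC over
n_repeats shuffles``.  Importances are computed on each cross-validation
fold's held-out rows with that fold's fitted model and scaler, then averaged
across the 5 folds and rank-ordered.

The permutation stream is drawn feature-major (all repeats of feature 0,
then feature 1, ...) from one seeded generator, so results are reproducible
and independently re-computable.  Re-scoring is batched: the ``n_repeats``
shuffled copies of the validation matrix are stacked into a single predict
call, which changes nothing numerically but matters for wall time.

Each ranked feature carries a direction annotation (higher/lower in the
clinical class), derived from the class-conditional means of the raw,
unpermuted feature — not from the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .model import CVResults, decision_scores, subseed

HIGHER = "higher_in_positive"
LOWER = "lower_in_positive"


class ImportanceError(ValueError):
    """Importance requested on an invalid validation set."""


@dataclass
class ImportanceTable:
    """Rank-ordered permutation importances, one row per feature."""

    table: pd.DataFrame  # columns: feature, mean_importance, sd_importance, direction
    model_kind: str
    n_repeats: int
    positive_label: str

    def __post_init__(self) -> None:
        imp = self.table["mean_importance"].to_numpy()
        if not (np.diff(imp) <= 1e-12).all():
            raise ImportanceError("importance rows must be sorted descending")

    def top(self, k: int = 20) -> pd.DataFrame:
        return self.table.head(k).reset_index(drop=True)

    def report(self, top_k: int = 20) -> pd.DataFrame:
        """Human-readable report: rank, feature, direction phrase, importance
        to 4 decimals (the shape of the published importance tables)."""
        rows = []
        for rank, row in enumerate(self.top(top_k).itertuples(index=False), start=1):
            phrase = (
                f"higher in {self.positive_label}"
                if row.direction == HIGHER
                else f"lower in {self.positive_label}"
            )
            rows.append(
                {
                    "rank": rank,
                    "feature": row.feature,
                    "direction": phrase,
                    "mean_importance": f"{row.mean_importance:.4f}",
                }
            )
        return pd.DataFrame(rows, columns=["rank", "feature", "direction", "mean_importance"])


def permutation_importance(
    model,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Per-feature importance on one validation fold.

    ``X_val`` must already be transformed the way the model was trained
    (i.e. pass it through the fold's scaler first); ``y_val`` is binary with
    1 for the positive class.  Returns ``baseline AUC − mean shuffled AUC``
    per feature, in column order.
    """
    y_val = np.asarray(y_val)
    if len(np.unique(y_val)) < 2:
        raise ImportanceError("validation set must contain both classes")
    X_val = np.asarray(X_val, dtype=float)
    n, p = X_val.shape
    baseline = roc_auc_score(y_val, decision_scores(model, X_val))
    rng = np.random.default_rng(seed)
    importances = np.empty(p)
    for j in range(p):
        perms = [rng.permutation(n) for _ in range(n_repeats)]
        stacked = np.tile(X_val, (n_repeats, 1))
        for r, perm in enumerate(perms):
            stacked[r * n : (r + 1) * n, j] = X_val[perm, j]
        scores = decision_scores(model, stacked)
        aucs = [
            roc_auc_score(y_val, scores[r * n : (r + 1) * n]) for r in range(n_repeats)
        ]
        importances[j] = baseline - float(np.mean(aucs))
    return importances


def feature_directions(
    X_raw: np.ndarray, y: np.ndarray, positive_label: str
) -> np.ndarray:
    """Direction of each raw feature: higher or lower in the positive class."""
    pos = np.asarray(y) == positive_label
    mean_pos = X_raw[pos].mean(axis=0)
    mean_neg = X_raw[~pos].mean(axis=0)
    return np.where(mean_pos >= mean_neg, HIGHER, LOWER)


def cross_fold_importance(
    cv_result: CVResults,
    n_repeats: int = 10,
    seed: int = 0,
    top_k: int | None = None,
) -> ImportanceTable:
    """Average the per-fold permutation importances and rank features.

    Folds whose held-out rows contain a single class carry no defined AUC
    and are skipped with a warning.  Ties in mean importance are broken by
    feature name for deterministic output; ``top_k`` truncates the table.
    """
    ybin = (cv_result.y == cv_result.positive_label).astype(int)
    per_fold = []
    for f, model, scaler in zip(cv_result.folds, cv_result.models_, cv_result.scalers_):
        y_val = ybin[f.test_idx]
        if len(np.unique(y_val)) < 2:
            warnings.warn(f"fold {f.fold}: single-class validation rows, skipped in importance")
            continue
        X_val = scaler.transform(cv_result.X_raw[f.test_idx])
        per_fold.append(
            permutation_importance(
                model, X_val, y_val, n_repeats=n_repeats, seed=subseed(seed, "perm", f.fold)
            )
        )
    if not per_fold:
        raise ImportanceError("no fold had both classes in its validation rows")
    imp = np.vstack(per_fold)
    directions = feature_directions(cv_result.X_raw, cv_result.y, cv_result.positive_label)
    table = pd.DataFrame(
        {
            "feature": list(cv_result.feature_names),
            "mean_importance": imp.mean(axis=0),
            "sd_importance": imp.std(axis=0),
            "direction": directions,
        }
    )
    table = table.sort_values(
        ["mean_importance", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_k is not None:
        table = table.head(top_k).reset_index(drop=True)
    return ImportanceTable(
        table=table,
        model_kind=cv_result.model_kind,
        n_repeats=n_repeats,
        positive_label=cv_result.positive_label,
    )
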