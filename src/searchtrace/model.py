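"""Cross-validated diagnostic and relapse classifiers.

The central object is :class:`SearchActivityClassifier`, a model built from
a window × feature matrix plus binary labels, in the style of a statistical
modelling package: construct (``from_dataframe`` for feature-matrix
DataFrames), call :meth:`~SearchActivityClassifier.fit`, and receive a
:class:`CVResults` carrying per-fold metrics, their aggregates, a
``summary()`` table, and permutation feature importance.

Evaluation follows a stratified 5-fold cross-validation: within each fold
the behavioral features are z-scored on the training rows only, a small
hyperparameter grid is tuned by AUC on an inner held-out validation split of
the training rows, the winning model is refit on the full training rows, and
the test fold is scored with the model's continuous output (class
probability or decision-function value) for AUC.  For the relapse task,
folds can be grouped by participant so that no participant's windows span
train and test.

Metrics (AUC, accuracy, F1 of the clinical/positive class, per-class
precision and recall) are computed per fold and averaged — never pooled.
Class imbalance is left as-is; AUC is the primary, imbalance-agnostic score.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import (
    GroupShuffleSplit,
    StratifiedGroupKFold,
    StratifiedKFold,
    StratifiedShuffleSplit,
)
from sklearn.svm import SVC

from .features import META_COLUMNS, BehavioralScaler

MODEL_KINDS = ("SVM", "RF", "GB")
MODEL_ORDER = ("SVM", "RF", "GB")  # report row order
MODEL_DISPLAY = {
    "SVM": "Support vector machine",
    "RF": "Random forest",
    "GB": "Gradient boost",
}

# Small fixed tuning grids; the RBF kernel is fixed for the SVM.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "RF": [
        {"n_estimators": 200, "max_depth": None},
        {"n_estimators": 200, "max_depth": 8},
    ],
    "SVM": [{"C": 0.5}, {"C": 2.0}, {"C": 8.0}],
    "GB": [
        {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 2},
        {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
    ],
}

N_SPLITS = 5


class ModelingError(ValueError):
    """Invalid modeling input (e.g. a single-class label vector)."""


def subseed(*parts) -> int:
    """Deterministic sub-seed (< 2**31) derived from arbitrary labeled parts."""
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def make_estimator(model_kind: str, params: dict, random_state: int):
    if model_kind == "RF":
        return RandomForestClassifier(random_state=random_state, **params)
    if model_kind == "SVM":
        return SVC(kernel="rbf", gamma="scale", random_state=random_state, **params)
    if model_kind == "GB":
        return GradientBoostingClassifier(random_state=random_state, **params)
    raise ModelingError(f"unknown model kind {model_kind!r}")


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores for AUC: positive-class probability when available,
    otherwise the decision-function value."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass
class FoldResult:
    fold: int
    auc: float  # nan when the test fold has one class
    accuracy: float
    f1_positive: float
    precision: dict[str, float]
    recall: dict[str, float]
    best_params: dict
    test_idx: np.ndarray


@dataclass
class CVResults:
    """Per-fold and aggregated cross-validation results.

    ``models_`` and ``scalers_`` retain the fitted per-fold pipelines so
    that permutation importance can re-score the exact validation folds.
    """

    model_kind: str
    folds: list[FoldResult]
    seed: int
    positive_label: str
    classes: tuple[str, str]  # (negative, positive)
    feature_names: tuple[str, ...]
    X_raw: np.ndarray
    y: np.ndarray
    fold_assignments: np.ndarray
    models_: list = field(default_factory=list, repr=False)
    scalers_: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        aucs = np.array([f.auc for f in self.folds], dtype=float)
        self.mean_auc = float(np.nanmean(aucs))
        self.sd_auc = float(np.nanstd(aucs))
        self.mean_accuracy = float(np.mean([f.accuracy for f in self.folds]))
        self.mean_f1 = float(np.mean([f.f1_positive for f in self.folds]))

    @property
    def per_fold(self) -> pd.DataFrame:
        neg, pos = self.classes
        return pd.DataFrame(
            {
                "fold": [f.fold for f in self.folds],
                "auc": [f.auc for f in self.folds],
                "accuracy": [f.accuracy for f in self.folds],
                "f1_positive": [f.f1_positive for f in self.folds],
                f"precision_{neg}": [f.precision[neg] for f in self.folds],
                f"precision_{pos}": [f.precision[pos] for f in self.folds],
                f"recall_{neg}": [f.recall[neg] for f in self.folds],
                f"recall_{pos}": [f.recall[pos] for f in self.folds],
            }
        )

    def summary(self) -> pd.DataFrame:
        """One report row: classifier, mean F1, per-class precision/recall,
        mean accuracy, and "mean (SD)" AUC formatted to 2 decimals."""
        neg, pos = self.classes
        mp = {c: float(np.mean([f.precision[c] for f in self.folds])) for c in (neg, pos)}
        mr = {c: float(np.mean([f.recall[c] for f in self.folds])) for c in (neg, pos)}
        return pd.DataFrame(
            [
                {
                    "classifier": MODEL_DISPLAY[self.model_kind],
                    "mean_f1": round(self.mean_f1, 2),
                    f"precision_{neg}": round(mp[neg], 2),
                    f"precision_{pos}": round(mp[pos], 2),
                    f"recall_{neg}": round(mr[neg], 2),
                    f"recall_{pos}": round(mr[pos], 2),
                    "mean_accuracy": round(self.mean_accuracy, 2),
                    "mean_sd_auc": f"{self.mean_auc:.2f} ({self.sd_auc:.2f})",
                }
            ]
        )

    def permutation_importance(self, n_repeats: int = 10, seed: int = 0, top_k: int | None = None):
        from .importance import cross_fold_importance

        return cross_fold_importance(self, n_repeats=n_repeats, seed=seed, top_k=top_k)

    def plot_roc(self, ax=None):
        """Per-fold ROC curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for f, model, scaler in zip(self.folds, self.models_, self.scalers_):
            Xt = scaler.transform(self.X_raw[f.test_idx])
            ybin = (self.y[f.test_idx] == self.positive_label).astype(int)
            if len(np.unique(ybin)) < 2:
                continue
            fpr, tpr, _ = roc_curve(ybin, decision_scores(model, Xt))
            ax.plot(fpr, tpr, label=f"fold {f.fold} (AUC {f.auc:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend()
        return ax


def _infer_positive(labels: np.ndarray) -> str:
    uniq = set(np.unique(labels))
    for clinical in ("SSD", "illness"):
        if clinical in uniq:
            return clinical
    # fall back to the minority class
    vals, counts = np.unique(labels, return_counts=True)
    return str(vals[np.argmin(counts)])


class SearchActivityClassifier:
    """A diagnostic or relapse classifier over window feature vectors.

    Parameters
    ----------
    X : ndarray or DataFrame of shape (n_windows, n_features)
        Raw (unstandardized) feature matrix.
    y : array-like of str
        Window labels; ``positive_label`` is the clinical class (SSD or
        illness) used for F1 and AUC orientation.
    groups : array-like, optional
        Participant ids; when given, folds never split one participant's
        windows across train and test.
    """

    def __init__(
        self,
        X,
        y,
        feature_names: Sequence[str] | None = None,
        positive_label: str | None = None,
        model_kind: str = "RF",
        groups: Sequence | None = None,
        seed: int = 0,
        n_splits: int = N_SPLITS,
        grids: dict[str, list[dict]] | None = None,
    ):
        if model_kind not in MODEL_KINDS:
            raise ModelingError(f"unknown model kind {model_kind!r}")
        if isinstance(X, pd.DataFrame):
            feature_names = tuple(X.columns) if feature_names is None else tuple(feature_names)
            X = X.to_numpy(dtype=float)
        elif feature_names is None:
            feature_names = tuple(f"x{i}" for i in range(np.asarray(X).shape[1]))
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(str)
        self.feature_names = tuple(feature_names)
        classes, counts = np.unique(self.y, return_counts=True)
        if len(classes) != 2:
            raise ModelingError(f"need exactly 2 classes, got {list(classes)}")
        if counts.min() < 2:
            raise ModelingError("need at least 2 rows per class")
        self.positive_label = positive_label or _infer_positive(self.y)
        if self.positive_label not in classes:
            raise ModelingError(f"positive label {self.positive_label!r} not in labels")
        neg = [c for c in classes if c != self.positive_label][0]
        self.classes = (str(neg), str(self.positive_label))
        self.model_kind = model_kind
        self.groups = None if groups is None else np.asarray(groups)
        self.seed = int(seed)
        self.n_splits = int(n_splits)
        self.grids = grids or DEFAULT_GRIDS

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        model_kind: str = "RF",
        label_col: str = "label",
        group_col: str | None = None,
        positive_label: str | None = None,
        seed: int = 0,
        **kwargs,
    ) -> "SearchActivityClassifier":
        """Build from a feature-matrix DataFrame as written by
        :func:`searchtrace.features.feature_matrix` (metadata columns are
        recognized and dropped from the feature block)."""
        feature_cols = [c for c in df.columns if c not in META_COLUMNS and c != label_col]
        groups = df[group_col].to_numpy() if group_col else None
        return cls(
            df[feature_cols],
            df[label_col].to_numpy(),
            positive_label=positive_label,
            model_kind=model_kind,
            groups=groups,
            seed=seed,
            **kwargs,
        )

    # -- fitting ---------------------------------------------------------

    def _outer_splits(self):
        ybin = (self.y == self.positive_label).astype(int)
        if self.groups is not None:
            cv = StratifiedGroupKFold(n_splits=self.n_splits, shuffle=True, random_state=self.seed)
            return list(cv.split(self.X, ybin, groups=self.groups))
        cv = StratifiedKFold(n_splits=self.n_splits, shuffle=True, random_state=self.seed)
        return list(cv.split(self.X, ybin))

    def _inner_split(self, train_idx: np.ndarray, fold: int):
        """Held-out validation split of the training rows for tuning."""
        ybin = (self.y[train_idx] == self.positive_label).astype(int)
        rs = subseed(self.seed, "inner", fold)
        if self.groups is not None:
            gss = GroupShuffleSplit(n_splits=1, test_size=0.25, random_state=rs)
            sub, val = next(gss.split(train_idx, ybin, groups=self.groups[train_idx]))
            if len(np.unique(ybin[val])) == 2 and len(np.unique(ybin[sub])) == 2:
                return train_idx[sub], train_idx[val]
        sss = StratifiedShuffleSplit(n_splits=1, test_size=0.25, random_state=rs)
        sub, val = next(sss.split(train_idx, ybin))
        return train_idx[sub], train_idx[val]

    def fit(self) -> CVResults:
        """Run the stratified 5-fold cross-validation and return results."""
        ybin = (self.y == self.positive_label).astype(int)
        neg, pos = self.classes
        folds: list[FoldResult] = []
        models, scalers = [], []
        fold_assignments = np.full(len(self.y), -1, dtype=int)

        for fold, (train_idx, test_idx) in enumerate(self._outer_splits()):
            fold_assignments[test_idx] = fold
            sub_idx, val_idx = self._inner_split(train_idx, fold)

            # tune on the inner held-out split by AUC
            best_params, best_auc = None, -np.inf
            sub_scaler = BehavioralScaler(self.feature_names).fit(self.X[sub_idx])
            X_sub = sub_scaler.transform(self.X[sub_idx])
            X_val = sub_scaler.transform(self.X[val_idx])
            for params in self.grids[self.model_kind]:
                est = make_estimator(self.model_kind, params, subseed(self.seed, "tune", fold))
                est.fit(X_sub, ybin[sub_idx])
                auc = roc_auc_score(ybin[val_idx], decision_scores(est, X_val))
                if auc > best_auc:
                    best_auc, best_params = auc, params

            # refit on the full training rows; standardization fit on train only
            scaler = BehavioralScaler(self.feature_names).fit(self.X[train_idx])
            model = make_estimator(self.model_kind, best_params, subseed(self.seed, "fit", fold))
            model.fit(scaler.transform(self.X[train_idx]), ybin[train_idx])

            X_test = scaler.transform(self.X[test_idx])
            y_test = ybin[test_idx]
            y_pred = model.predict(X_test)
            if len(np.unique(y_test)) < 2:
                warnings.warn(
                    f"fold {fold}: single-class test fold, AUC undefined and excluded from the mean"
                )
                auc = float("nan")
            else:
                auc = float(roc_auc_score(y_test, decision_scores(model, X_test)))
            folds.append(
                FoldResult(
                    fold=fold,
                    auc=auc,
                    accuracy=float(accuracy_score(y_test, y_pred)),
                    f1_positive=float(f1_score(y_test, y_pred, pos_label=1, zero_division=0)),
                    precision={
                        neg: float(precision_score(y_test, y_pred, pos_label=0, zero_division=0)),
                        pos: float(precision_score(y_test, y_pred, pos_label=1, zero_division=0)),
                    },
                    recall={
                        neg: float(recall_score(y_test, y_pred, pos_label=0, zero_division=0)),
                        pos: float(recall_score(y_test, y_pred, pos_label=1, zero_division=0)),
                    },
                    best_params=dict(best_params),
                    test_idx=np.asarray(test_idx),
                )
            )
            models.append(model)
            scalers.append(scaler)

        return CVResults(
            model_kind=self.model_kind,
            folds=folds,
            seed=self.seed,
            positive_label=self.positive_label,
            classes=self.classes,
            feature_names=self.feature_names,
            X_raw=self.X,
            y=self.y,
            fold_assignments=fold_assignments,
            models_=models,
            scalers_=scalers,
        )


def run_cv(
    features,
    labels,
    model_kind: str = "RF",
    seed: int = 0,
    groups=None,
    positive_label: str | None = None,
    grids: dict[str, list[dict]] | None = None,
) -> CVResults:
    """Functional wrapper: build a :class:`SearchActivityClassifier` and fit it."""
    return SearchActivityClassifier(
        features,
        labels,
        positive_label=positive_label,
        model_kind=model_kind,
        groups=groups,
        seed=seed,
        grids=grids,
    ).fit()


def summarize(results: CVResults | Sequence[CVResults]) -> pd.DataFrame:
    """Stack summary rows, ordered SVM, RF, GB (the standard report order)."""
    if isinstance(results, CVResults):
        results = [results]
    results = list(results)
    if not results:
        return pd.DataFrame()
    order = {k: i for i, k in enumerate(MODEL_ORDER)}
    results = sorted(results, key=lambda r: order.get(r.model_kind, 99))
    return pd.concat([r.summary() for r in results], ignore_index=True)


def repeat_control_sampling(
    ssd_archives,
    ssd_timelines,
    hv_archives,
    lexicon,
    n_iter: int = 10,
    model_kind: str = "RF",
    seed: int = 0,
) -> tuple[list[CVResults], dict]:
    """Re-draw every healthy-volunteer control window ``n_iter`` times,
    rebuild the diagnostic feature matrix, and rerun the CV each time.

    Returns all :class:`CVResults` plus a dispersion summary (the SD of the
    mean AUC across iterations) — the stability check for random control
    placement.
    """
    from .features import feature_matrix
    from .windowing import ExclusionNotice, control_window, diagnostic_window

    ssd_windows = []
    for archive, timeline in zip(ssd_archives, ssd_timelines):
        win = diagnostic_window(archive, timeline)
        if not isinstance(win, ExclusionNotice):
            ssd_windows.append(win)

    results: list[CVResults] = []
    for it in range(n_iter):
        windows = list(ssd_windows)
        for archive in hv_archives:
            win = control_window(archive, subseed(seed, "control", it, archive.participant_id))
            if not isinstance(win, ExclusionNotice):
                windows.append(win)
        matrix = feature_matrix(windows, lexicon)
        results.append(
            SearchActivityClassifier.from_dataframe(
                matrix, model_kind=model_kind, seed=subseed(seed, "cv", it)
            ).fit()
        )
    mean_aucs = np.array([r.mean_auc for r in results])
    dispersion = {
        "mean_auc_per_iteration": mean_aucs.tolist(),
        "sd_mean_auc": float(np.std(mean_aucs)),
    }
    return results, dispersion
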