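"""Behavioral and linguistic features of one observation window.

The 123-dimension feature vector concatenates, in fixed order:

====  =========================================================
  24  hourly histogram of query length (summed words per hour)
  24  hourly histogram of query frequency (count per hour)
   8  4-day-bin histogram of query length over a 32-day lookback
   8  4-day-bin histogram of query frequency over the same lookback
   1  SD of the 4-day frequency bins
   1  SD of the 4-day length bins
   1  mean of the derivative of the 4-day frequency bins
   1  mean of the derivative of the 4-day length bins
   1  SD of the derivative of the 4-day frequency bins
   1  SD of the derivative of the 4-day length bins
  51  lexicon category proportions
   1  total number of queries in the window
   1  average query length (words) in the window
====  =========================================================

Query "length" is the token count of :func:`~searchtrace.lexicon.tokenize`.
Hourly histograms bin by the local-time hour of each timestamp and aggregate
over the 28 window days.  The 4-day bins count backwards from the window
end: bin 0 covers 0–3 days prior, bin 7 covers 28–31 days prior (the window
plus its 4-day lookback).  Derivatives run in time order, oldest bin to
newest, so a decline toward the anchor yields a negative mean.  All standard
deviations are population (divide-by-n) SDs, and degenerate statistics (no
queries) are 0 by convention.

Lexicon proportions are already volume-normalized; the remaining
("behavioral") columns are z-scored by :func:`standardize`, fitting the mean
and SD on a caller-chosen row subset (training folds only, during CV).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lexicon import Lexicon, category_profile, tokenize
from .windowing import ObservationWindow

N_HOUR_BINS = 24
N_FOURDAY_BINS = 8
META_COLUMNS = ["participant_id", "task", "label", "anchor"]


@dataclass
class FeatureVector:
    """Named, ordered feature values for one window."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def _pop_sd(x: np.ndarray) -> float:
    return float(np.std(x)) if len(x) else 0.0


def query_length(text: str) -> int:
    """Word (token) count of one query."""
    return len(tokenize(text))


def hourly_histograms(window: ObservationWindow) -> tuple[np.ndarray, np.ndarray]:
    """(frequency, length) 24-bin histograms over the window's 28 days.

    Bin ``h`` of frequency counts queries whose local-time hour is ``h``;
    the length histogram sums their word counts instead.
    """
    freq = np.zeros(N_HOUR_BINS)
    length = np.zeros(N_HOUR_BINS)
    for q in window.queries:
        h = q.timestamp.hour
        freq[h] += 1
        length[h] += query_length(q.text)
    return freq, length


def fourday_histograms(window: ObservationWindow) -> tuple[np.ndarray, np.ndarray]:
    """(frequency, length) 8-bin histograms over a 32-day lookback.

    Bin ``k`` covers days ``[4k, 4k+4)`` prior to the window end, so bin 0
    is "3–0 days prior" and bin 7 is "31–28 days prior"; bins 0–6 lie inside
    the window and bin 7 in the 4-day lookback before it.
    """
    freq = np.zeros(N_FOURDAY_BINS)
    length = np.zeros(N_FOURDAY_BINS)
    for q in list(window.queries) + list(window.lookback_queries):
        day = int((window.end - q.timestamp).total_seconds() // 86400)
        if 0 <= day < 4 * N_FOURDAY_BINS:
            k = day // 4
            freq[k] += 1
            length[k] += query_length(q.text)
    return freq, length


def derivative_stats(bins: Sequence[float]) -> tuple[float, float]:
    """Mean and population SD of the successive differences of the 4-day
    bins taken in time order (oldest bin first, newest last)."""
    b = np.asarray(bins, dtype=float)[::-1]  # bin 7 is oldest
    diff = np.diff(b)
    if len(diff) == 0:
        return 0.0, 0.0
    return float(diff.mean()), _pop_sd(diff)


def scalar_features(
    window: ObservationWindow,
    fourday_freq: np.ndarray | None = None,
    fourday_len: np.ndarray | None = None,
) -> tuple[int, float, float, float]:
    """(total_queries, mean_query_length, sd_freq_bins, sd_len_bins)."""
    if fourday_freq is None or fourday_len is None:
        fourday_freq, fourday_len = fourday_histograms(window)
    total = window.n_queries
    words = sum(query_length(q.text) for q in window.queries)
    mean_len = words / total if total else 0.0
    return total, mean_len, _pop_sd(fourday_freq), _pop_sd(fourday_len)


def feature_names(lexicon: Lexicon) -> tuple[str, ...]:
    """Stable, unique names of the full feature vector, in assembly order."""
    names: list[str] = []
    names += [f"hour_len_{h:02d}" for h in range(N_HOUR_BINS)]
    names += [f"hour_freq_{h:02d}" for h in range(N_HOUR_BINS)]
    names += [f"day4_len_{4 * k + 3:02d}_{4 * k:02d}d_prior" for k in range(N_FOURDAY_BINS)]
    names += [f"day4_freq_{4 * k + 3:02d}_{4 * k:02d}d_prior" for k in range(N_FOURDAY_BINS)]
    names += [
        "sd_day4_freq",
        "sd_day4_len",
        "mean_deriv_day4_freq",
        "mean_deriv_day4_len",
        "sd_deriv_day4_freq",
        "sd_deriv_day4_len",
    ]
    names += [f"liwc_{c}" for c in lexicon.category_names]
    names += ["total_queries", "mean_query_length"]
    return tuple(names)


def assemble(window: ObservationWindow, lexicon: Lexicon) -> FeatureVector:
    """The full feature vector of one window (123 values with the standard
    51-category lexicon)."""
    hour_freq, hour_len = hourly_histograms(window)
    d4_freq, d4_len = fourday_histograms(window)
    mean_df, sd_df = derivative_stats(d4_freq)
    mean_dl, sd_dl = derivative_stats(d4_len)
    total, mean_len, sd_f, sd_l = scalar_features(window, d4_freq, d4_len)
    profile = category_profile(window, lexicon)
    values = np.concatenate(
        [
            hour_len,
            hour_freq,
            d4_len,
            d4_freq,
            [sd_f, sd_l, mean_df, mean_dl, sd_df, sd_dl],
            profile.values,
            [total, mean_len],
        ]
    )
    return FeatureVector(feature_names(lexicon), values)


def feature_matrix(
    windows: Sequence[ObservationWindow], lexicon: Lexicon
) -> pd.DataFrame:
    """One row per window: metadata columns plus the full feature block."""
    names = feature_names(lexicon)
    records = []
    for w in windows:
        fv = assemble(w, lexicon)
        rec = {
            "participant_id": w.participant_id,
            "task": w.task,
            "label": w.label,
            "anchor": w.anchor.isoformat(),
        }
        rec.update(dict(zip(names, fv.values)))
        records.append(rec)
    return pd.DataFrame(records, columns=META_COLUMNS + list(names))


def is_behavioral(name: str) -> bool:
    """Behavioral columns are z-scored; lexicon proportions pass through."""
    return not name.startswith("liwc_")


class BehavioralScaler:
    """Z-scores the behavioral columns using statistics from the fit rows.

    Lexicon-proportion columns pass through unchanged (they are already
    normalized by window word volume); behavioral columns with zero SD on
    the fit rows map to 0.
    """

    def __init__(self, names: Sequence[str]):
        self.names = tuple(names)
        self.mask = np.array([is_behavioral(n) for n in self.names])
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "BehavioralScaler":
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("cannot fit scaler on zero rows")
        self.mean_ = X[:, self.mask].mean(axis=0)
        self.sd_ = X[:, self.mask].std(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("scaler is not fitted")
        X = np.asarray(X, dtype=float).copy()
        sd = np.where(self.sd_ > 0, self.sd_, 1.0)
        Z = (X[:, self.mask] - self.mean_) / sd
        Z[:, self.sd_ == 0] = 0.0
        X[:, self.mask] = Z
        return X

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def standardize(
    matrix: pd.DataFrame | np.ndarray,
    names: Sequence[str] | None = None,
    fit_rows: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize a windows × features matrix.

    Behavioral columns are z-scored with mean/SD estimated on ``fit_rows``
    only (all rows when ``None``); lexicon columns pass through.  Returns
    ``(standardized matrix, fitted means, fitted SDs)`` where the fitted
    statistics cover the behavioral columns in order.
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns) if names is None else list(names)
        X = matrix[names].to_numpy(dtype=float)
    else:
        if names is None:
            raise ValueError("names are required with an ndarray input")
        X = np.asarray(matrix, dtype=float)
    rows = np.arange(X.shape[0]) if fit_rows is None else np.asarray(fit_rows)
    if len(rows) == 0:
        raise ValueError("fit_rows must be nonempty")
    scaler = BehavioralScaler(names).fit(X[rows])
    return scaler.transform(X), scaler.mean_.copy(), scaler.sd_.copy()
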