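"""Histogram, derivative, scalar and assembly behavior of the feature stage."""

import random
from datetime import datetime, timedelta

import numpy as np
import pytest

from searchtrace.archive_io import SearchArchive
from searchtrace.features import (
    BehavioralScaler,
    assemble,
    derivative_stats,
    feature_matrix,
    feature_names,
    fourday_histograms,
    hourly_histograms,
    scalar_features,
    standardize,
)
from searchtrace.lexicon import tokenize
from searchtrace.synthetic import CohortSpec, generate_cohort
from searchtrace.windowing import ObservationWindow, control_window
from tests.conftest import UTC, WINDOW_START, make_window, sq

END = WINDOW_START + timedelta(days=28)


def oracle_hourly(window):
    freq, length = [0.0] * 24, [0.0] * 24
    for q in window.queries:
        freq[q.timestamp.hour] += 1
        length[q.timestamp.hour] += len(tokenize(q.text))
    return freq, length


def oracle_fourday(window):
    freq, length = [0.0] * 8, [0.0] * 8
    for q in list(window.queries) + list(window.lookback_queries):
        days_prior = (window.end - q.timestamp).total_seconds() / 86400.0
        for k in range(8):
            if 4 * k <= int(days_prior) < 4 * (k + 1):
                freq[k] += 1
                length[k] += len(tokenize(q.text))
    return freq, length


class TestHourlyHistograms:
    def test_binning_example(self):
        win = make_window(
            [
                sq(WINDOW_START.replace(hour=8, minute=15), "a b"),
                sq(WINDOW_START.replace(hour=8, minute=40), "c d e"),
                sq(WINDOW_START.replace(hour=23, minute=59), "f"),
            ]
        )
        freq, length = hourly_histograms(win)
        assert freq[8] == 2 and freq[23] == 1 and freq.sum() == 3
        assert length[8] == 5 and length[23] == 1

    def test_empty_window_gives_zero_vectors(self):
        freq, length = hourly_histograms(make_window([]))
        assert not freq.any() and not length.any()

    def test_matches_bruteforce_oracle_on_synthetic_window(self, synthetic_window):
        freq, length = hourly_histograms(synthetic_window)
        of, ol = oracle_hourly(synthetic_window)
        np.testing.assert_allclose(freq, of, atol=1e-9)
        np.testing.assert_allclose(length, ol, atol=1e-9)


class TestFourdayHistograms:
    def test_recent_query_lands_in_bin_zero(self):
        win = make_window([sq(END - timedelta(days=2), "x")])
        freq, _ = fourday_histograms(win)
        assert freq[0] == 1 and freq.sum() == 1

    def test_lookback_query_30_days_prior_lands_in_bin_seven(self):
        win = make_window([], lookback=[sq(END - timedelta(days=30), "x")])
        freq, _ = fourday_histograms(win)
        assert freq[7] == 1 and freq.sum() == 1

    def test_uniform_one_query_per_day_over_32_days_fills_all_bins(self):
        queries = [sq(END - timedelta(days=d, hours=12), "x") for d in range(28)]
        lookback = [sq(END - timedelta(days=d, hours=12), "x") for d in range(28, 32)]
        win = make_window(queries, lookback=lookback)
        freq, _ = fourday_histograms(win)
        assert list(freq) == [4.0] * 8

    def test_matches_bruteforce_oracle_on_synthetic_window(self, synthetic_window):
        freq, length = fourday_histograms(synthetic_window)
        of, ol = oracle_fourday(synthetic_window)
        np.testing.assert_allclose(freq, of, atol=1e-9)
        np.testing.assert_allclose(length, ol, atol=1e-9)


class TestDerivativeStats:
    def test_constant_bins_give_zero(self):
        assert derivative_stats([3.0] * 8) == (0.0, 0.0)

    def test_arithmetic_progression_in_time_order(self):
        # oldest (bin 7) = 0 rising to newest (bin 0) = 7: slope 1, no spread
        bins = [7, 6, 5, 4, 3, 2, 1, 0]
        assert derivative_stats(bins) == (1.0, 0.0)

    def test_decline_toward_anchor_is_negative(self):
        mean, _ = derivative_stats([0, 1, 2, 3, 4, 5, 6, 7])
        assert mean == -1.0

    def test_matches_oracle_on_random_bins(self):
        rng = np.random.default_rng(5)
        bins = rng.integers(0, 20, 8).astype(float)
        series = bins[::-1]
        diffs = [series[i + 1] - series[i] for i in range(7)]
        mean = sum(diffs) / 7
        sd = (sum((d - mean) ** 2 for d in diffs) / 7) ** 0.5
        got = derivative_stats(bins)
        assert got[0] == pytest.approx(mean, abs=1e-9)
        assert got[1] == pytest.approx(sd, abs=1e-9)


class TestScalarFeatures:
    def test_totals_and_mean_length(self):
        win = make_window(
            [
                sq(WINDOW_START, "a b"),
                sq(WINDOW_START + timedelta(hours=1), "a b c d"),
                sq(WINDOW_START + timedelta(hours=2), "a b c d e f"),
            ]
        )
        total, mean_len, sd_f, sd_l = scalar_features(win)
        assert total == 3 and mean_len == 4.0

    def test_empty_window_degenerates_to_zero(self):
        assert scalar_features(make_window([])) == (0, 0.0, 0.0, 0.0)

    def test_sd_features_match_population_sd_of_bins(self, synthetic_window):
        freq, length = fourday_histograms(synthetic_window)
        _, _, sd_f, sd_l = scalar_features(synthetic_window)
        assert sd_f == pytest.approx(float(np.std(freq)), abs=1e-9)
        assert sd_l == pytest.approx(float(np.std(length)), abs=1e-9)


class TestAssemble:
    def test_123_unique_names(self, lex51, synthetic_window):
        fv = assemble(synthetic_window, lex51)
        assert len(fv) == 123
        assert len(set(fv.names)) == 123

    def test_empty_window_is_all_zero(self, lex51):
        fv = assemble(make_window([]), lex51)
        assert not fv.values.any()

    def test_identical_windows_give_identical_vectors(self, lex51, synthetic_window):
        a = assemble(synthetic_window, lex51)
        b = assemble(synthetic_window, lex51)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invariant_to_query_storage_order(self, lex51, synthetic_window):
        w = synthetic_window
        shuffled = list(w.queries)
        random.Random(3).shuffle(shuffled)
        w2 = ObservationWindow(
            w.participant_id, w.task, w.label, w.anchor, w.start, w.end,
            shuffled, list(w.lookback_queries),
        )
        np.testing.assert_array_equal(
            assemble(w, lex51).values, assemble(w2, lex51).values
        )

    def test_hourly_frequency_sums_to_total_queries(self, lex51, synthetic_window):
        fv = assemble(synthetic_window, lex51).to_series()
        hourly = fv[[f"hour_freq_{h:02d}" for h in range(24)]].sum()
        assert hourly == fv["total_queries"] == synthetic_window.n_queries

    def test_fourday_frequency_inside_window_sums_to_total(self, lex51, synthetic_window):
        fv = assemble(synthetic_window, lex51).to_series()
        inside = fv[[f"day4_freq_{4*k+3:02d}_{4*k:02d}d_prior" for k in range(7)]].sum()
        extra = len(synthetic_window.lookback_queries)
        bin7 = fv["day4_freq_31_28d_prior".replace("31", "31")]
        assert inside + bin7 == fv["total_queries"] + extra


class TestStandardize:
    def make_matrix(self, lex51, n=12, seed=0):
        rng = np.random.default_rng(seed)
        names = feature_names(lex51)
        X = rng.normal(3, 2, size=(n, len(names)))
        X[:, [i for i, n_ in enumerate(names) if n_.startswith("liwc_")]] = rng.uniform(
            0, 1, size=(n, 51)
        )
        return X, names

    def test_fit_on_all_rows_zscores_behavioral_columns(self, lex51):
        X, names = self.make_matrix(lex51)
        Z, mean, sd = standardize(X, names)
        behav = [i for i, n in enumerate(names) if not n.startswith("liwc_")]
        np.testing.assert_allclose(Z[:, behav].mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(Z[:, behav].std(axis=0), 1, atol=1e-9)

    def test_lexicon_columns_pass_through(self, lex51):
        X, names = self.make_matrix(lex51)
        Z, _, _ = standardize(X, names)
        liwc = [i for i, n in enumerate(names) if n.startswith("liwc_")]
        np.testing.assert_array_equal(Z[:, liwc], X[:, liwc])

    def test_constant_column_maps_to_zero(self, lex51):
        X, names = self.make_matrix(lex51)
        X[:, 0] = 5.0
        Z, _, _ = standardize(X, names)
        assert not Z[:, 0].any()

    def test_held_out_rows_use_training_statistics(self, lex51):
        X, names = self.make_matrix(lex51, n=20)
        train = list(range(12))
        Z, mean, sd = standardize(X, names, fit_rows=train)
        behav = [i for i, n in enumerate(names) if not n.startswith("liwc_")]
        j = behav[5]
        jj = behav.index(j)
        mu = X[train, j].mean()
        sigma = X[train, j].std()
        expected = (X[15, j] - mu) / sigma
        assert Z[15, j] == pytest.approx(expected, abs=1e-9)
        assert mean[jj] == pytest.approx(mu) and sd[jj] == pytest.approx(sigma)


def test_feature_matrix_has_meta_and_feature_columns(lex51, synthetic_window):
    df = feature_matrix([synthetic_window], lex51)
    assert df.shape == (1, 4 + 123)
    assert list(df.columns[:4]) == ["participant_id", "task", "label", "anchor"]


@pytest.fixture(scope="module")
def synthetic_window(lex51_module):
    """A realistic ~300-query control window drawn from the generator."""
    spec = CohortSpec(n_ssd=0, n_hv=1, archive_span_days=60, seed=11)
    archives, _, _ = generate_cohort(spec, lex51_module)
    win = control_window(archives[0], rng_seed=4)
    assert win.n_queries > 100
    return win


@pytest.fixture(scope="module")
def lex51_module():
    from searchtrace.synthetic import fixture_lexicon

    return fixture_lexicon()
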