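"""Window labels, forest training, median filtering, event assembly,
and per-dog threshold individualization."""
import numpy as np
import pandas as pd
import pytest

from epicollar import (
    EvalReport,
    ProbabilitySeries,
    RFConfig,
    SeizureDetector,
    WindowGrid,
    individualize_threshold,
    label_windows,
    median_filter5,
    threshold_and_merge,
)
from epicollar.detector import truth_event_peaks
from epicollar.simulate import SeizureEvent

from conftest import T0, at, iv


def grid_of(n_windows, window_s=4.0, stride_s=4.0, fs=100.0):
    return WindowGrid(T0, fs, n_windows, window_s, stride_s)


def series_of(values, filtered=None, **kw):
    values = np.asarray(values, dtype=float)
    return ProbabilitySeries(values, grid_of(values.size, **kw), filtered=filtered)


def median5_oracle(x):
    """Brute-force 5-neighborhood median with reflected edges, NaN-aware."""
    n = x.size
    ext = np.pad(x, 2, mode="reflect" if n > 1 else "edge")
    out = np.empty(n)
    for i in range(n):
        neigh = ext[i : i + 5]
        vals = neigh[~np.isnan(neigh)]
        out[i] = np.median(vals) if vals.size else np.nan
    return out


def runs_oracle(above, merge_gap):
    """Run enumeration: maximal above-threshold runs, gap-merged."""
    runs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    return merged


class TestLabelWindows:
    def test_overlap_rules(self):
        grid = grid_of(5)
        fully = [SeizureEvent(at(4.0), at(8.0))]
        assert list(label_windows(grid, fully)) == [0, 1, 0, 0, 0]
        none = [SeizureEvent(at(100.0), at(130.0))]
        assert list(label_windows(grid, none)) == [0, 0, 0, 0, 0]

    def test_fractional_overlap_threshold(self):
        # event covers 2 s of window 0 (0-4 s)
        ev = [SeizureEvent(at(2.0), at(6.0))]
        grid = grid_of(2)
        assert label_windows(grid, ev, overlap_frac=0.5)[0] == 1
        assert label_windows(grid, ev, overlap_frac=0.6)[0] == 0

    def test_focal_events_ignored(self):
        ev = [SeizureEvent(at(0.0), at(8.0), kind="focal")]
        assert label_windows(grid_of(2), ev).sum() == 0


class TestTraining:
    @staticmethod
    def toy_features(rng, n=200, shift=3.0):
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 2))
        x[y == 1] += shift
        df = pd.DataFrame(x, columns=["f0", "f1"])
        df.attrs["layout_version"] = "toy"
        return df, y

    def test_separable_training_probabilities(self, rng):
        df, y = self.toy_features(rng)
        res = SeizureDetector(df, y, RFConfig(seed=0)).fit()
        p = res.predict_probabilities(df)
        assert np.all(p[y == 1] > 0.5)

    def test_deterministic_given_seed(self, rng):
        df, y = self.toy_features(rng)
        p1 = SeizureDetector(df, y, RFConfig(seed=5)).fit().predict_probabilities(df)
        p2 = SeizureDetector(df, y, RFConfig(seed=5)).fit().predict_probabilities(df)
        np.testing.assert_array_equal(p1, p2)

    def test_heldout_accuracy_vs_nearest_centroid(self, rng):
        """On a well-separated 2-feature toy set the forest matches the
        nearest-centroid oracle (>= 0.95 held-out accuracy)."""
        df, y = self.toy_features(rng, n=400)
        tr = np.arange(0, 400, 2)
        te = np.arange(1, 400, 2)
        dtr = df.iloc[tr].reset_index(drop=True)
        dtr.attrs["layout_version"] = "toy"
        res = SeizureDetector(dtr, y[tr], RFConfig(seed=1)).fit()
        p = res.predict_probabilities(df.iloc[te].reset_index(drop=True))
        acc = np.mean((p > 0.5).astype(int) == y[te])
        c0 = df.iloc[tr].to_numpy()[y[tr] == 0].mean(axis=0)
        c1 = df.iloc[tr].to_numpy()[y[tr] == 1].mean(axis=0)
        xte = df.iloc[te].to_numpy()
        oracle = (
            np.linalg.norm(xte - c1, axis=1) < np.linalg.norm(xte - c0, axis=1)
        ).astype(int)
        assert np.mean(oracle == y[te]) >= 0.95
        assert acc >= 0.95

    def test_single_class_rejected(self, rng):
        df, y = self.toy_features(rng)
        with pytest.raises(ValueError, match="both classes"):
            SeizureDetector(df, np.zeros_like(y))

    def test_single_tree_probabilities_binary(self, rng):
        df, y = self.toy_features(rng)
        res = SeizureDetector(df, y, RFConfig(n_trees=1, seed=0)).fit()
        p = res.predict_probabilities(df)
        assert set(np.unique(p)) <= {0.0, 1.0}

    def test_layout_mismatch_rejected(self, rng):
        df, y = self.toy_features(rng)
        res = SeizureDetector(df, y).fit()
        other = df.copy()
        other.attrs["layout_version"] = "different"
        with pytest.raises(ValueError, match="layout"):
            res.predict_probabilities(other)

    def test_invalid_windows_predict_nan_not_zero(self, rng):
        df, y = self.toy_features(rng, n=20)
        res = SeizureDetector(df, y).fit()
        valid = np.ones(20, bool)
        valid[3] = False
        p = res.predict_probabilities(df, valid=valid)
        assert np.isnan(p[3])
        assert np.isfinite(np.delete(p, 3)).all()


class TestMedianFilter:
    def test_constant_unchanged(self):
        x = np.full(11, 0.4)
        np.testing.assert_array_equal(median_filter5(x), x)

    def test_isolated_spike_removed(self):
        np.testing.assert_array_equal(
            median_filter5(np.array([0, 0, 1.0, 0, 0])), np.zeros(5)
        )

    def test_three_consecutive_survive(self):
        x = np.array([0, 0, 0.9, 0.9, 0.9, 0, 0])
        out = median_filter5(x)
        assert np.all(out[2:5] == 0.9)

    def test_matches_brute_force_randomized(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 30))
            x = rng.uniform(size=n)
            x[rng.uniform(size=n) < 0.2] = np.nan
            got = median_filter5(x)
            np.testing.assert_array_equal(np.isnan(got), np.isnan(median5_oracle(x)))
            np.testing.assert_allclose(got[~np.isnan(got)],
                                       median5_oracle(x)[~np.isnan(median5_oracle(x))])

    def test_output_drawn_from_neighborhood(self, rng):
        """The filter never invents values: each output is an order
        statistic (median) of its raw 5-neighborhood."""
        x = rng.uniform(size=50)
        out = median_filter5(x)
        ext = np.pad(x, 2, mode="reflect")
        for i, v in enumerate(out):
            neigh = np.sort(ext[i : i + 5])
            assert v in neigh or v == pytest.approx((neigh[1] + neigh[2]) / 2) \
                or v == pytest.approx((neigh[2] + neigh[3]) / 2)

    def test_series_wrapper_sets_filtered(self):
        s = median_filter5(series_of([0.1, 0.9, 0.1]))
        assert s.filtered is not None and s.filtered.shape == (3,)


class TestThresholdAndMerge:
    def test_all_below_threshold_empty(self):
        s = series_of([0.1, 0.4, 0.5], filtered=np.array([0.1, 0.4, 0.5]))
        assert threshold_and_merge(s, 0.5) == []

    def test_single_run_times(self):
        filt = np.array([0.2, 0.6, 0.7, 0.3])
        s = series_of(filt, filtered=filt)
        (ev,) = threshold_and_merge(s, 0.5)
        assert ev.start == at(4.0) and ev.end == at(12.0)
        assert ev.peak_probability == pytest.approx(0.7)
        assert ev.n_windows == 2

    def test_merge_gap_boundary(self):
        filt = np.array([0.9, 0, 0.9, 0, 0, 0.9])
        s = series_of(filt, filtered=filt)
        assert len(threshold_and_merge(s, 0.5, merge_gap_windows=1)) == 2
        assert len(threshold_and_merge(s, 0.5, merge_gap_windows=2)) == 1

    def test_matches_run_length_oracle_randomized(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 60))
            filt = rng.uniform(size=n)
            filt[rng.uniform(size=n) < 0.1] = np.nan
            gap = int(rng.integers(0, 3))
            s = series_of(np.zeros(n), filtered=filt)
            events = threshold_and_merge(s, 0.5, gap)
            above = np.nan_to_num(filt, nan=0.0) > 0.5
            want = runs_oracle(above, gap)
            assert len(events) == len(want)
            for ev, (lo, hi) in zip(events, want):
                assert ev.start == at(lo * 4.0)
                assert ev.end == at(hi * 4.0 + 4.0)

    def test_raising_threshold_refines_coverage(self, rng):
        """Events at a higher threshold cover a subset of the time covered
        at a lower threshold."""
        for _ in range(50):
            filt = rng.uniform(size=40)
            s = series_of(np.zeros(40), filtered=filt)
            lo_ev = threshold_and_merge(s, 0.4, 1)
            hi_ev = threshold_and_merge(s, 0.7, 1)
            for ev in hi_ev:
                # every hi window lies within some lo event's span
                assert any(l.start <= ev.start and ev.end <= l.end for l in lo_ev)

    def test_invalid_threshold_rejected(self):
        s = series_of([0.1], filtered=np.array([0.1]))
        with pytest.raises(ValueError):
            threshold_and_merge(s, 0.0)


def make_report(n_fp=0, n_fn=0, n_tp=1, days=30.0):
    n_total = n_tp + n_fn
    sens = round(100.0 * n_tp / n_total, 1) if n_total else None
    return EvalReport(
        dog_id="d", phase=1, n_seizures_total=n_total, n_excluded_nonwear=0,
        n_tp=n_tp, n_fn=n_fn, n_fp=n_fp,
        sensitivity=sens,
        ci95=(0.0, 100.0) if n_total else None,
        phase_days=days, corrected_days=days, fdr_per_day=n_fp / days,
    )


class TestIndividualizeThreshold:
    def test_clean_dog_unchanged(self):
        r = make_report(n_fp=0, n_fn=0, n_tp=2)
        assert individualize_threshold(r, [0.9, 0.8], []) == 0.5

    def test_fp_prone_raises_below_weakest_tp(self):
        r = make_report(n_fp=30, n_tp=2, days=30.0)  # 1 FP/day
        t = individualize_threshold(r, [0.55, 0.80], [])
        assert t == pytest.approx(0.95 * 0.55)

    def test_fp_prone_never_drops_below_default(self):
        r = make_report(n_fp=30, n_tp=1)
        assert individualize_threshold(r, [0.51], []) == 0.5

    def test_fn_prone_lowers_toward_strongest_miss(self):
        r = make_report(n_fp=0, n_fn=5, n_tp=1)
        t = individualize_threshold(r, [0.9], [0.40, 0.25])
        assert t == pytest.approx(0.95 * 0.40)

    def test_no_phase1_information_unchanged(self):
        r = make_report(n_fp=0, n_fn=0, n_tp=0)
        assert individualize_threshold(r, [], []) == 0.5

    def test_fp_replay_removes_weak_fps_keeps_tps(self):
        """Replay oracle: re-running event assembly at the individualized
        threshold removes every FP run peaking below it and keeps TPs."""
        filt = np.array([0, 0.52, 0.52, 0.52, 0,      # FP run, peak 0.52
                         0, 0.85, 0.9, 0.85, 0,       # TP run (truth below)
                         0, 0.60, 0.60, 0.60, 0,      # TP run
                         0, 0.54, 0.54, 0, 0])        # FP run, peak 0.54
        s = series_of(np.zeros(filt.size), filtered=filt)
        truth = [SeizureEvent(at(24.0), at(36.0)), SeizureEvent(at(44.0), at(56.0))]
        before = threshold_and_merge(s, 0.5, 1)
        assert len(before) == 4
        tp_peaks = truth_event_peaks(s, truth, tolerance_s=0.0)
        r = make_report(n_fp=2, n_tp=2, days=1.0)
        t2 = individualize_threshold(r, tp_peaks, [])
        assert t2 == pytest.approx(0.95 * 0.60)
        after = threshold_and_merge(s, t2, 1)
        assert len(after) == 2  # both weak FP runs gone
        for ev, tr in zip(after, truth):
            assert ev.start <= tr.end and tr.start <= ev.end

    def test_fn_replay_recovers_missed_seizures(self):
        filt = np.array([0, 0.35, 0.40, 0.35, 0, 0, 0.30, 0.30, 0, 0])
        s = series_of(np.zeros(filt.size), filtered=filt)
        truth = [SeizureEvent(at(4.0), at(16.0)), SeizureEvent(at(24.0), at(32.0))]
        assert threshold_and_merge(s, 0.5, 1) == []
        missed_peaks = truth_event_peaks(s, truth, tolerance_s=0.0)
        r = make_report(n_fp=0, n_fn=2, n_tp=0)
        t2 = individualize_threshold(r, [], missed_peaks)
        assert t2 == pytest.approx(0.95 * 0.40)
        after = threshold_and_merge(s, t2, 1)
        assert len(after) == 1  # the 0.40-peak seizure is now detected
        assert after[0].start <= truth[0].end and truth[0].start <= after[0].end
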