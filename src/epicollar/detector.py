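"""Window classification and event assembly.

A random forest maps each 4-second feature vector to a seizure
probability; the per-window probability series is smoothed with a
5-point median filter; maximal runs of filtered values strictly above
the threshold (default 0.5) become detection events; and after phase 1
the threshold is individualized per dog — raised to slightly below the
weakest true positive for false-alarm-prone dogs, lowered toward the
strongest missed seizure for miss-prone dogs.

Organized as a model/results pair: :class:`SeizureDetector` holds the
training data and hyperparameters; its :meth:`~SeizureDetector.fit`
returns a :class:`SeizureDetectorResults` that predicts, detects, and
summarizes itself.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .evaluation import EvalReport
from .features import FeatureOptions, FeatureSet, WindowGrid, compute_features
from .intervals import Interval, overlap_seconds, within_tolerance
from .orientation import orient_to_dog_frame
from .simulate import AccelTrace


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters (recorded in the model manifest)."""

    n_trees: int = 200
    max_depth: int | None = None
    seed: int = 0
    class_weight: str | None = "balanced"


@dataclass(frozen=True)
class IndividualizationPolicy:
    """What counts as "numerous" false positives / "many" misses, and how
    far below (above) the relevant peak probability the new threshold
    sits.  The study adjusted thresholds manually; these are the
    codified equivalents, all tunable."""

    fp_many_per_day: float = 0.2
    fn_many: int = 3
    fn_frac_many: float = 0.5
    margin: float = 0.95
    t_min: float = 0.05


@dataclass
class ProbabilitySeries:
    """Per-window seizure probabilities aligned to a window grid.

    ``values`` uses NaN as the missing marker for invalid (gap) windows
    — never 0, which would be a confident prediction.  ``filtered`` is
    the median-smoothed series, same shape.
    """

    values: np.ndarray
    grid: WindowGrid
    filtered: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.shape[0] != self.grid.n_windows:
            raise ValueError("values must be 1-D and aligned to the grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class DetectionEvent:
    """One predicted seizure: a run of supra-threshold windows."""

    start: datetime
    end: datetime
    peak_probability: float
    n_windows: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("detection start must precede end")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


def label_windows(
    grid: WindowGrid, truth_events, overlap_frac: float = 0.5
) -> np.ndarray:
    """Binary training labels: 1 iff a window overlaps a generalized
    seizure by at least ``overlap_frac`` of the window length."""
    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must lie in (0, 1]")
    need = overlap_frac * grid.window_s
    events = [
        ev for ev in truth_events if getattr(ev, "kind", "generalized") == "generalized"
    ]
    labels = np.zeros(grid.n_windows, dtype=int)
    for i in range(grid.n_windows):
        iv = grid.window_interval(i)
        if any(overlap_seconds(iv, (ev.start, ev.end)) >= need for ev in events):
            labels[i] = 1
    return labels


def median_filter5(series: np.ndarray | ProbabilitySeries) -> np.ndarray | ProbabilitySeries:
    """Centered 5-point median filter with reflected edges.

    Missing (NaN) values are excluded from each neighborhood's median;
    a neighborhood that is entirely missing stays missing.  Given a
    :class:`ProbabilitySeries`, returns a new one with ``filtered`` set.
    """
    if isinstance(series, ProbabilitySeries):
        filt = median_filter5(series.values)
        return ProbabilitySeries(series.values, series.grid, filtered=filt)
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("series must be 1-D and non-empty")
    padded = np.pad(x, 2, mode="reflect" if x.size > 1 else "edge")
    neigh = np.lib.stride_tricks.sliding_window_view(padded, 5)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = np.nanmedian(neigh, axis=1)
    out[np.all(np.isnan(neigh), axis=1)] = np.nan
    return out


def threshold_and_merge(
    series: ProbabilitySeries,
    threshold: float = 0.5,
    merge_gap_windows: int = 1,
) -> list[DetectionEvent]:
    """Assemble detection events from the filtered probability series.

    Maximal runs of windows with filtered value strictly above the
    threshold become events; runs separated by at most
    ``merge_gap_windows`` sub-threshold windows are merged (clonic
    pauses).  Missing windows count as sub-threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    filt = series.filtered
    if filt is None:
        raise ValueError("series has no filtered values; apply median_filter5 first")
    above = np.zeros(filt.shape, dtype=bool)
    finite = np.isfinite(filt)
    above[finite] = filt[finite] > threshold

    runs: list[list[int]] = []  # [first_idx, last_idx]
    for i in np.flatnonzero(above):
        if runs and i - runs[-1][1] - 1 <= merge_gap_windows:
            runs[-1][1] = i
        else:
            runs.append([i, i])

    grid = series.grid
    events = []
    for lo, hi in runs:
        start = grid.window_interval(lo)[0]
        end = grid.window_interval(hi)[1]
        span = filt[lo : hi + 1]
        peak = float(np.nanmax(span))
        n_sup = int(np.sum(above[lo : hi + 1]))
        events.append(DetectionEvent(start, end, peak, n_sup))
    return events


def truth_event_peaks(
    series: ProbabilitySeries, truth_events, tolerance_s: float = 60.0
) -> list[float]:
    """Peak filtered probability near each truth event (NaN if none)."""
    filt = series.filtered if series.filtered is not None else series.values
    peaks = []
    for ev in truth_events:
        vals = [
            filt[i]
            for i in range(series.grid.n_windows)
            if np.isfinite(filt[i])
            and within_tolerance(series.grid.window_interval(i), (ev.start, ev.end), tolerance_s)
        ]
        peaks.append(float(np.max(vals)) if vals else float("nan"))
    return peaks


def individualize_threshold(
    phase1_report: EvalReport,
    tp_peaks: list[float],
    missed_peaks: list[float],
    policy: IndividualizationPolicy = IndividualizationPolicy(),
    current_threshold: float = 0.5,
) -> float:
    """Per-dog phase-2 threshold from phase-1 performance.

    Dogs with numerous false positives get the threshold raised to just
    below their weakest phase-1 true positive (never below the default);
    dogs with many misses and an acceptable false-positive rate get it
    lowered toward their strongest missed seizure, floored at ``t_min``;
    otherwise the threshold is unchanged.
    """
    tp_peaks = [p for p in tp_peaks if np.isfinite(p)]
    missed_peaks = [p for p in missed_peaks if np.isfinite(p)]
    n_eval = phase1_report.n_evaluable
    fp_prone = phase1_report.fdr_per_day > policy.fp_many_per_day
    fn_prone = phase1_report.n_fn > policy.fn_many or (
        n_eval > 0 and phase1_report.n_fn / n_eval > policy.fn_frac_many
    )
    if fp_prone and tp_peaks:
        new = max(current_threshold, policy.margin * min(tp_peaks))
    elif fn_prone and not fp_prone and missed_peaks:
        new = max(policy.t_min, policy.margin * max(missed_peaks))
    else:
        return current_threshold
    return float(min(max(new, 1e-6), 1 - 1e-6))


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class SeizureDetector:
    """Random-forest window classifier (model object).

    Built from a feature matrix and binary labels; ``fit`` trains the
    forest and returns a :class:`SeizureDetectorResults`.  Class
    imbalance (seizure windows are rare) is handled by balanced class
    weights rather than resampling.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: np.ndarray,
        rf_config: RFConfig = RFConfig(),
        feature_options: FeatureOptions = FeatureOptions(),
    ):
        labels = np.asarray(labels, dtype=int)
        if len(features) != labels.shape[0]:
            raise ValueError("features and labels must align")
        if len(np.unique(labels)) < 2:
            raise ValueError("training set must contain both classes")
        if features.isna().any().any():
            raise ValueError("training features contain invalid (NaN) windows")
        self.features = features
        self.labels = labels
        self.rf_config = rf_config
        self.feature_options = feature_options
        self.layout_version = features.attrs.get("layout_version", "unversioned")

    @classmethod
    def from_records(
        cls,
        records,
        phase: int = 1,
        rf_config: RFConfig = RFConfig(),
        feature_options: FeatureOptions = FeatureOptions(),
        overlap_frac: float = 0.5,
        orient: bool = True,
        max_negatives_per_record: int | None = None,
    ) -> "SeizureDetector":
        """Assemble training data from dog study records' given phase.

        Seizure windows are a tiny minority of a months-long recording;
        ``max_negatives_per_record`` optionally subsamples each record's
        non-seizure windows (deterministically, from the forest seed)
        while keeping every seizure window.
        """
        frames, labels = [], []
        rng = np.random.default_rng(rf_config.seed)
        for rec in records:
            pr = rec.phase(phase)
            trace = orient_to_dog_frame(pr.trace) if orient else pr.trace
            fs = compute_features(trace, feature_options)
            y = label_windows(fs.grid, pr.events, overlap_frac)
            frame, yv = fs.frame.loc[fs.valid], y[fs.valid]
            neg = np.flatnonzero(yv == 0)
            if max_negatives_per_record is not None and neg.size > max_negatives_per_record:
                keep_neg = rng.choice(neg, size=max_negatives_per_record, replace=False)
                keep = np.sort(np.concatenate([np.flatnonzero(yv == 1), keep_neg]))
                frame, yv = frame.iloc[keep], yv[keep]
            frames.append(frame)
            labels.append(yv)
        feats = pd.concat(frames, ignore_index=True)
        feats.attrs["layout_version"] = frames[0].attrs.get("layout_version", "unversioned")
        return cls(feats, np.concatenate(labels), rf_config, feature_options)

    def fit(self) -> "SeizureDetectorResults":
        est = RandomForestClassifier(
            n_estimators=self.rf_config.n_trees,
            max_depth=self.rf_config.max_depth,
            class_weight=self.rf_config.class_weight,
            random_state=self.rf_config.seed,
            n_jobs=1,
        )
        est.fit(self.features.to_numpy(), self.labels)
        return SeizureDetectorResults(self, est)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_training_windows(self) -> int:
        return int(len(self.features))

    @property
    def n_seizure_windows(self) -> int:
        return int(self.labels.sum())


class _LoadedDetectorModel:
    """Stand-in for a SeizureDetector reconstructed from a manifest."""

    def __init__(self, manifest: dict):
        self.rf_config = RFConfig(**manifest["rf_config"])
        fo = dict(manifest["feature_options"])
        self.feature_options = FeatureOptions(**fo)
        self.layout_version = manifest["layout_version"]
        self.feature_names = list(manifest.get("feature_names", []))
        self.n_training_windows = manifest["n_training_windows"]
        self.n_seizure_windows = manifest["n_seizure_windows"]


@dataclass
class SeizureDetectorResults:
    """A fitted window classifier plus the detection post-processing."""

    model: SeizureDetector
    estimator: RandomForestClassifier
    _seizure_col: int = field(init=False)

    def __post_init__(self) -> None:
        self._seizure_col = int(np.flatnonzero(self.estimator.classes_ == 1)[0])

    @property
    def layout_version(self) -> str:
        return self.model.layout_version

    def predict_probabilities(
        self, features: FeatureSet | pd.DataFrame, valid: np.ndarray | None = None,
        grid: WindowGrid | None = None,
    ) -> ProbabilitySeries | np.ndarray:
        """Per-window seizure probability; invalid windows yield NaN."""
        if isinstance(features, FeatureSet):
            frame, valid, grid = features.frame, features.valid, features.grid
            lv = features.layout_version
        else:
            frame = features
            lv = frame.attrs.get("layout_version", "unversioned")
        if lv != self.layout_version:
            raise ValueError(
                f"feature layout {lv!r} does not match model layout {self.layout_version!r}"
            )
        values = np.full(len(frame), np.nan)
        mask = np.ones(len(frame), bool) if valid is None else np.asarray(valid, bool)
        if mask.any():
            proba = self.estimator.predict_proba(frame.to_numpy()[mask])
            values[mask] = proba[:, self._seizure_col]
        if grid is None:
            return values
        return ProbabilitySeries(values, grid)

    def detect(
        self,
        trace: AccelTrace,
        threshold: float = 0.5,
        merge_gap_windows: int = 1,
        orient: bool = True,
    ) -> tuple[list[DetectionEvent], ProbabilitySeries]:
        """Full detection pipeline on a raw trace.

        Orients the trace, extracts features, predicts per-window
        probabilities, median-filters them, and assembles events.
        """
        oriented = orient_to_dog_frame(trace) if orient else trace
        fs = compute_features(oriented, self.model.feature_options)
        series = self.predict_probabilities(fs)
        series = median_filter5(series)
        events = threshold_and_merge(series, threshold, merge_gap_windows)
        return events, series

    def manifest(self) -> dict:
        """Reproducibility manifest: hyperparameters, seed, layout."""
        return {
            "model": "random_forest",
            "rf_config": asdict(self.model.rf_config),
            "feature_options": asdict(self.model.feature_options),
            "layout_version": self.layout_version,
            "feature_names": list(self.model.feature_names),
            "n_training_windows": self.model.n_training_windows,
            "n_seizure_windows": self.model.n_seizure_windows,
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)

    def save(self, path) -> None:
        """Persist the fitted forest plus its manifest (joblib)."""
        import joblib

        joblib.dump({"estimator": self.estimator, "manifest": self.manifest()}, path)

    @classmethod
    def load(cls, path) -> "SeizureDetectorResults":
        import joblib

        blob = joblib.load(path)
        return cls(_LoadedDetectorModel(blob["manifest"]), blob["estimator"])

    def summary(self) -> str:
        m = self.manifest()
        lines = [
            "Seizure detector (random forest)",
            "=" * 40,
            f"trees:             {m['rf_config']['n_trees']}",
            f"max depth:         {m['rf_config']['max_depth']}",
            f"seed:              {m['rf_config']['seed']}",
            f"class weight:      {m['rf_config']['class_weight']}",
            f"feature layout:    {m['layout_version']}",
            f"training windows:  {m['n_training_windows']}"
            f" ({m['n_seizure_windows']} seizure)",
        ]
        names = self.model.feature_names
        if names:
            imp = self.estimator.feature_importances_
            top = np.argsort(imp)[::-1][:5]
            lines.append("top features:")
            for i in top:
                lines.append(f"  {names[i]:<24s} {imp[i]:.3f}")
        return "\n".join(lines)
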