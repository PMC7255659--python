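"""Per-window time- and frequency-domain features.

Each 4-second window of oriented acceleration yields, per axis:

* the 5th, 10th, 25th, 50th, 75th, 90th and 95th quantiles (linear
  interpolation convention), carrying posture and sustained offsets;
* the band-averaged log power spectral density (Welch, mean-detrended),
  carrying rhythm;
* the normalized spectral entropy of the PSD, low for narrowband
  (rhythmic) motion and high for broadband motion.

Windows are detrended (mean removed) before the PSD but not before the
quantiles.  The feature layout is fixed and versioned so a trained
classifier can refuse mismatched inputs.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy import signal

from .intervals import Interval, intersects
from .simulate import AccelTrace

QUANTILE_LEVELS = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)
AXIS_NAMES = ("cranial", "lateral", "ventral")
_CHUNK_WINDOWS = 20_000  # bounds float64 temporaries on long traces


@dataclass(frozen=True)
class FeatureOptions:
    """Windowing and spectral-feature knobs.

    ``spectrum_mode``: "banded" averages log-PSD over ``n_bands`` equal
    bands of (0, Nyquist]; "per_bin" keeps the log-PSD of every non-DC
    Welch bin (the Welch average over sub-windows is the averaging).
    """

    window_s: float = 4.0
    stride_s: float = 4.0
    n_bands: int = 12
    eps: float = 1e-12
    spectrum_mode: str = "banded"

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.stride_s <= 0:
            raise ValueError("window_s and stride_s must be positive")
        if self.stride_s > self.window_s:
            raise ValueError("stride_s must not exceed window_s")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if self.spectrum_mode not in ("banded", "per_bin"):
            raise ValueError(f"unknown spectrum_mode {self.spectrum_mode!r}")


@dataclass(frozen=True)
class WindowGrid:
    """Mapping between window indices and absolute time."""

    start_time: datetime
    sample_rate_hz: float
    n_windows: int
    window_s: float = 4.0
    stride_s: float = 4.0

    def __post_init__(self) -> None:
        if self.stride_s > self.window_s:
            raise ValueError("stride_s must not exceed window_s")
        if self.window_s <= 0 or self.stride_s <= 0:
            raise ValueError("window_s and stride_s must be positive")

    @classmethod
    def for_trace(
        cls, trace: AccelTrace, window_s: float = 4.0, stride_s: float = 4.0
    ) -> "WindowGrid":
        spw = int(round(window_s * trace.sample_rate_hz))
        ssm = int(round(stride_s * trace.sample_rate_hz))
        if trace.n_samples < spw:
            raise ValueError("trace shorter than one window")
        n_windows = (trace.n_samples - spw) // ssm + 1
        return cls(trace.start_time, trace.sample_rate_hz, n_windows, window_s, stride_s)

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.sample_rate_hz))

    @property
    def stride_samples(self) -> int:
        return int(round(self.stride_s * self.sample_rate_hz))

    def window_slice(self, i: int) -> slice:
        i0 = i * self.stride_samples
        return slice(i0, i0 + self.window_samples)

    def window_interval(self, i: int) -> Interval:
        lo = self.start_time + timedelta(seconds=i * self.stride_s)
        return (lo, lo + timedelta(seconds=self.window_s))

    def intervals(self) -> list[Interval]:
        return [self.window_interval(i) for i in range(self.n_windows)]


def valid_windows(grid: WindowGrid, wear_mask: list[Interval]) -> np.ndarray:
    """Boolean mask: True for windows free of non-collection overlap."""
    valid = np.ones(grid.n_windows, dtype=bool)
    if not wear_mask:
        return valid
    for i in range(grid.n_windows):
        iv = grid.window_interval(i)
        if any(intersects(iv, g) for g in wear_mask):
            valid[i] = False
    return valid


def segment_windows(
    trace: AccelTrace, grid: WindowGrid | None = None
) -> tuple[np.ndarray, np.ndarray, WindowGrid]:
    """Windowed view of a trace.

    Returns ``(windows, valid, grid)`` with ``windows`` of shape
    (n_windows, window_samples, 3) — a strided view, no copy — and
    ``valid`` flagging windows that do not overlap a wear-mask gap.
    """
    if grid is None:
        grid = WindowGrid.for_trace(trace)
    spw, ssm = grid.window_samples, grid.stride_samples
    x = np.asarray(trace.samples)
    view = np.lib.stride_tricks.sliding_window_view(x, spw, axis=0)
    windows = view[:: ssm][: grid.n_windows].transpose(0, 2, 1)
    return windows, valid_windows(grid, trace.wear_mask), grid


# ---------------------------------------------------------------------------
# per-window primitives
# ---------------------------------------------------------------------------

def axis_quantiles(values: np.ndarray) -> np.ndarray:
    """The seven feature quantiles of one axis (linear interpolation)."""
    values = np.asarray(values)
    if values.size < 2:
        raise ValueError("need at least 2 samples for quantiles")
    return np.quantile(values.astype(np.float64), QUANTILE_LEVELS)


def _welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with the pipeline's fixed convention.

    Hann window, ``nperseg = min(len, 256)``, 50% overlap, mean
    detrending.  ``x`` may be 1-D or (n_windows, n_samples).
    """
    n = x.shape[-1]
    nperseg = min(n, 256)
    return signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant", axis=-1,
    )


def band_edges(n_bands: int, nyquist_hz: float) -> np.ndarray:
    """Equal-width band edges partitioning (0, Nyquist]."""
    return np.linspace(0.0, nyquist_hz, n_bands + 1)


def _band_index(freqs: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Band index per non-DC frequency bin; DC (f == 0) gets -1."""
    idx = np.clip(np.searchsorted(edges, freqs, side="left") - 1, 0, len(edges) - 2)
    idx[freqs <= 0] = -1
    return idx


def banded_log_spectrum(
    values: np.ndarray, fs: float, n_bands: int = 12, eps: float = 1e-12
) -> np.ndarray:
    """Band-averaged log PSD of one axis over (0, Nyquist].

    Per band, the mean of ``log(PSD + eps)`` over the band's bins; the
    additive floor keeps all-zero windows finite (every band collapses
    to ``log(eps)``).  Natural log; units log(g^2/Hz).
    """
    freqs, psd = _welch_psd(np.asarray(values, dtype=np.float64), fs)
    return _bands_from_psd(freqs, psd, n_bands, eps, fs / 2.0)


def _bands_from_psd(freqs, psd, n_bands, eps, nyquist) -> np.ndarray:
    edges = band_edges(n_bands, nyquist)
    idx = _band_index(freqs, edges)
    logp = np.log(psd + eps)
    out = np.full(psd.shape[:-1] + (n_bands,), np.log(eps))
    for b in range(n_bands):
        sel = idx == b
        if sel.any():
            out[..., b] = logp[..., sel].mean(axis=-1)
    return out


def entropy_from_psd(psd: np.ndarray) -> float:
    """Normalized Shannon entropy of a PSD treated as a probability mass.

    Returns a value in [0, 1]; a zero-power spectrum is defined as 1.0
    (maximally uninformative).
    """
    psd = np.asarray(psd, dtype=np.float64)
    total = psd.sum()
    if not np.isfinite(total) or total <= 0:
        return 1.0
    p = psd / total
    nz = p > 0
    h = -(p[nz] * np.log(p[nz])).sum()
    return float(h / np.log(psd.size)) if psd.size > 1 else 1.0


def spectral_entropy(values: np.ndarray, fs: float) -> float:
    """Normalized spectral entropy of one axis (DC bin excluded)."""
    freqs, psd = _welch_psd(np.asarray(values, dtype=np.float64), fs)
    return entropy_from_psd(psd[..., freqs > 0])


def _entropy_rows(psd_nodc: np.ndarray) -> np.ndarray:
    """Row-wise normalized entropy for a (n_windows, n_bins) PSD block."""
    total = psd_nodc.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, psd_nodc / np.where(total > 0, total, 1.0), 0.0)
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=-1)
    n_bins = psd_nodc.shape[-1]
    out = h / np.log(n_bins) if n_bins > 1 else np.ones_like(h)
    out[total[..., 0] <= 0] = 1.0
    return out


# ---------------------------------------------------------------------------
# feature vectors
# ---------------------------------------------------------------------------

def _n_spectral_features(options: FeatureOptions, window_samples: int) -> int:
    if options.spectrum_mode == "banded":
        return options.n_bands
    nperseg = min(window_samples, 256)
    return nperseg // 2  # non-DC rfft bins of the Welch segment


def feature_names(options: FeatureOptions, window_samples: int) -> list[str]:
    """Column names of the documented layout: per axis, quantiles then
    spectrum then entropy."""
    n_spec = _n_spectral_features(options, window_samples)
    names = []
    for ax in AXIS_NAMES:
        names += [f"{ax}_q{int(q * 100):02d}" for q in QUANTILE_LEVELS]
        names += [f"{ax}_logspec_b{b:02d}" for b in range(n_spec)]
        names.append(f"{ax}_spec_entropy")
    return names


def layout_version(options: FeatureOptions, window_samples: int) -> str:
    n_spec = _n_spectral_features(options, window_samples)
    return f"fv1:q7+{options.spectrum_mode}{n_spec}+ent"


def build_feature_vector(
    window: np.ndarray, fs: float, options: FeatureOptions = FeatureOptions()
) -> np.ndarray:
    """Feature vector of one (window_samples, 3) window.

    Length is always ``3 * (7 + n_spectral + 1)``; identical windows map
    to identical vectors.
    """
    window = np.asarray(window)
    if window.ndim != 2 or window.shape[1] != 3:
        raise ValueError("window must have shape (n_samples, 3)")
    parts = []
    for ax in range(3):
        x = window[:, ax].astype(np.float64)
        parts.append(axis_quantiles(x))
        freqs, psd = _welch_psd(x, fs)
        if options.spectrum_mode == "banded":
            parts.append(_bands_from_psd(freqs, psd, options.n_bands, options.eps, fs / 2.0))
        else:
            parts.append(np.log(psd[freqs > 0] + options.eps))
        parts.append(np.atleast_1d(entropy_from_psd(psd[freqs > 0])))
    return np.concatenate(parts)


@dataclass
class FeatureSet:
    """Feature matrix aligned to a window grid, with validity flags."""

    frame: pd.DataFrame
    valid: np.ndarray
    grid: WindowGrid
    layout_version: str

    def valid_frame(self) -> pd.DataFrame:
        return self.frame.loc[self.valid]


def compute_features(
    trace: AccelTrace,
    options: FeatureOptions = FeatureOptions(),
    grid: WindowGrid | None = None,
) -> FeatureSet:
    """Vectorized feature extraction over a whole trace.

    Rows for every window on the grid are computed; windows overlapping
    a wear-mask gap are flagged invalid (no prediction should be emitted
    for them).  Numerically identical to ``build_feature_vector`` run
    per window.
    """
    windows, valid, grid = segment_windows(
        trace, grid or WindowGrid.for_trace(trace, options.window_s, options.stride_s)
    )
    nw, spw, _ = windows.shape
    fs = grid.sample_rate_hz
    names = feature_names(options, spw)
    n_spec = _n_spectral_features(options, spw)
    per_axis = 7 + n_spec + 1
    out = np.empty((nw, 3 * per_axis), dtype=np.float64)

    for c0 in range(0, nw, _CHUNK_WINDOWS):
        c1 = min(c0 + _CHUNK_WINDOWS, nw)
        chunk = np.ascontiguousarray(windows[c0:c1])  # (m, spw, 3)
        for ax in range(3):
            x = np.ascontiguousarray(chunk[:, :, ax])
            base = ax * per_axis
            q = np.quantile(x, QUANTILE_LEVELS, axis=1)  # (7, m)
            out[c0:c1, base : base + 7] = q.T
            freqs, psd = _welch_psd(x, fs)
            if options.spectrum_mode == "banded":
                out[c0:c1, base + 7 : base + 7 + n_spec] = _bands_from_psd(
                    freqs, psd, options.n_bands, options.eps, fs / 2.0
                )
            else:
                out[c0:c1, base + 7 : base + 7 + n_spec] = np.log(
                    psd[..., freqs > 0] + options.eps
                )
            out[c0:c1, base + 7 + n_spec] = _entropy_rows(psd[..., freqs > 0])

    frame = pd.DataFrame(out, columns=names)
    lv = layout_version(options, spw)
    frame.attrs["layout_version"] = lv
    return FeatureSet(frame=frame, valid=valid, grid=grid, layout_version=lv)
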