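"""Field-study accuracy accounting and quality-of-life scoring.

Implements the study bookkeeping: seizures that fell inside device
non-collection periods are excluded before sensitivity is computed;
sensitivity gets a Wald 95% binomial interval; the false-detection-rate
denominator drops one day for every whole 24-hour non-collection
period.  QoL sheets (15 bipolar items, 1-5) are standardized so high is
always favorable and summed to a 15-75 composite.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .intervals import Interval, intersects, within_tolerance

#: Item indices (0-based) whose raw 1-5 response is reverse-coded (a raw
#: 1 means the most favorable answer).  The real questionnaire's key is
#: not public; this synthetic stand-in set is fixed so scoring is
#: well-defined and reproducible.
REVERSE_CODED_DEFAULT: frozenset[int] = frozenset({1, 4, 6, 9, 12})

N_QOL_ITEMS = 15
Z_95 = 1.96


@dataclass(frozen=True)
class QoLResponse:
    """One 15-item quality-of-life sheet on the 1-5 bipolar scale."""

    items: tuple[int, ...]
    reverse_coded: frozenset[int] = REVERSE_CODED_DEFAULT

    def __post_init__(self) -> None:
        if len(self.items) != N_QOL_ITEMS:
            raise ValueError(f"expected {N_QOL_ITEMS} items, got {len(self.items)}")
        for i, v in enumerate(self.items):
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 5):
                raise ValueError(f"item {i} out of range 1..5: {v!r}")
        if not all(0 <= i < N_QOL_ITEMS for i in self.reverse_coded):
            raise ValueError("reverse_coded indices out of range")

    def standardized(self) -> tuple[int, ...]:
        """Item values mapped so a high value is always favorable."""
        return tuple(
            6 - v if i in self.reverse_coded else v for i, v in enumerate(self.items)
        )


def qol_composite(resp: QoLResponse) -> int:
    """Composite QoL score: sum of standardized items, range 15-75."""
    return int(sum(resp.standardized()))


# ---------------------------------------------------------------------------
# event accounting
# ---------------------------------------------------------------------------

def _as_interval(ev) -> Interval:
    if isinstance(ev, tuple):
        return ev
    return (ev.start, ev.end)


def exclude_nonwear_seizures(truth_events, wear_mask) -> tuple[list, list]:
    """Split truth events into (kept, excluded) by non-collection overlap.

    A seizure is excluded iff its interval intersects any non-collection
    interval: if the device was not recording for any part of the
    seizure it cannot be scored.
    """
    kept, excluded = [], []
    for ev in truth_events:
        iv = _as_interval(ev)
        if any(intersects(iv, g) for g in wear_mask):
            excluded.append(ev)
        else:
            kept.append(ev)
    return kept, excluded


@dataclass
class MatchResult:
    n_tp: int
    n_fn: int
    n_fp: int
    detected_truth: list = field(default_factory=list)
    missed_truth: list = field(default_factory=list)
    false_detections: list = field(default_factory=list)


def match_events(detections, kept_truth, tolerance_s: float = 60.0) -> MatchResult:
    """Greedy chronological matching of detections to truth seizures.

    A truth event counts as detected (one TP, however many detections
    land on it) iff at least one detection overlaps it or lies within
    ``tolerance_s``.  Every detection that matches no truth event is one
    false positive.
    """
    truth = sorted(kept_truth, key=lambda e: _as_interval(e))
    dets = sorted(detections, key=lambda e: _as_interval(e))
    det_matched = [False] * len(dets)
    detected, missed = [], []
    for ev in truth:
        iv = _as_interval(ev)
        hit = False
        for j, d in enumerate(dets):
            if within_tolerance(iv, _as_interval(d), tolerance_s):
                det_matched[j] = True
                hit = True
        (detected if hit else missed).append(ev)
    false_dets = [d for j, d in enumerate(dets) if not det_matched[j]]
    return MatchResult(
        n_tp=len(detected),
        n_fn=len(missed),
        n_fp=len(false_dets),
        detected_truth=detected,
        missed_truth=missed,
        false_detections=false_dets,
    )


def sensitivity_ci(
    n_tp: int, n_eval: int, method: str = "wald"
) -> tuple[float, float, float]:
    """Sensitivity in percent with a 95% binomial CI, to one decimal.

    The Wald interval (p +/- 1.96 sqrt(p(1-p)/n), clipped to [0, 100])
    is the default; Wilson is available as an option.
    """
    if n_eval < 1:
        raise ValueError("sensitivity undefined: no evaluable seizures")
    if not 0 <= n_tp <= n_eval:
        raise ValueError("n_tp must lie in [0, n_eval]")
    p = n_tp / n_eval
    if method == "wald":
        half = Z_95 * math.sqrt(p * (1.0 - p) / n_eval)
        lo, hi = p - half, p + half
    elif method == "wilson":
        z2 = Z_95**2
        denom = 1.0 + z2 / n_eval
        center = (p + z2 / (2 * n_eval)) / denom
        half = (Z_95 / denom) * math.sqrt(p * (1 - p) / n_eval + z2 / (4 * n_eval**2))
        lo, hi = center - half, center + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    lo = min(max(lo, 0.0), 1.0)
    hi = min(max(hi, 0.0), 1.0)
    return round(100 * p, 1), round(100 * lo, 1), round(100 * hi, 1)


def corrected_phase_days(
    phase_days: float, wear_mask, rule: str = "floor"
) -> float:
    """Study-phase days after the 24-hour non-collection correction.

    ``floor`` subtracts one day per whole 24-hour unit within each
    contiguous gap; ``total`` subtracts the summed gap time / 24 h.
    """
    if rule == "floor":
        lost = sum(
            math.floor((g[1] - g[0]).total_seconds() / 86400.0) for g in wear_mask
        )
    elif rule == "total":
        lost = sum((g[1] - g[0]).total_seconds() for g in wear_mask) / 86400.0
    else:
        raise ValueError(f"unknown gap-day rule {rule!r}")
    return phase_days - lost


def false_detection_rate(
    n_fp: int, phase_days: float, wear_mask, rule: str = "floor"
) -> tuple[float, float]:
    """False detections per day over gap-corrected phase days.

    Returns ``(rate_per_day, corrected_days)``.
    """
    if phase_days <= 0:
        raise ValueError("phase_days must be positive")
    corrected = corrected_phase_days(phase_days, wear_mask, rule)
    if corrected <= 0:
        raise ValueError("corrected phase length is not positive; phase uninterpretable")
    return n_fp / corrected, corrected


@dataclass
class EvalReport:
    """Per-dog, per-phase accuracy report."""

    dog_id: str
    phase: int
    n_seizures_total: int
    n_excluded_nonwear: int
    n_tp: int
    n_fn: int
    n_fp: int
    sensitivity: float | None  # percent; None when no evaluable seizures
    ci95: tuple[float, float] | None
    phase_days: float
    corrected_days: float
    fdr_per_day: float
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_tp + self.n_fn != self.n_seizures_total - self.n_excluded_nonwear:
            raise ValueError("TP + FN must equal total minus excluded seizures")
        if self.sensitivity is not None:
            if not 0.0 <= self.sensitivity <= 100.0:
                raise ValueError("sensitivity out of [0, 100]")
            lo, hi = self.ci95
            if not lo <= self.sensitivity <= hi:
                raise ValueError("CI must contain the point estimate")
        if self.corrected_days > self.phase_days + 1e-9:
            raise ValueError("corrected_days cannot exceed phase_days")
        if self.fdr_per_day < 0:
            raise ValueError("fdr_per_day must be non-negative")

    @property
    def n_evaluable(self) -> int:
        return self.n_seizures_total - self.n_excluded_nonwear


def evaluate_phase(
    dog_id: str,
    phase: int,
    truth_events,
    detections,
    wear_mask,
    phase_days: float,
    *,
    tolerance_s: float = 60.0,
    gap_day_rule: str = "floor",
    ci_method: str = "wald",
    threshold: float = 0.5,
) -> EvalReport:
    """Full accuracy accounting for one dog-phase."""
    kept, excluded = exclude_nonwear_seizures(truth_events, wear_mask)
    match = match_events(detections, kept, tolerance_s)
    if len(kept) >= 1:
        sens, lo, hi = sensitivity_ci(match.n_tp, len(kept), ci_method)
        ci = (lo, hi)
    else:
        sens, ci = None, None
    rate, corrected = false_detection_rate(match.n_fp, phase_days, wear_mask, gap_day_rule)
    return EvalReport(
        dog_id=dog_id,
        phase=phase,
        n_seizures_total=len(truth_events),
        n_excluded_nonwear=len(excluded),
        n_tp=match.n_tp,
        n_fn=match.n_fn,
        n_fp=match.n_fp,
        sensitivity=sens,
        ci95=ci,
        phase_days=phase_days,
        corrected_days=corrected,
        fdr_per_day=rate,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# cohort-level statistics
# ---------------------------------------------------------------------------

@dataclass
class PairedStats:
    mean_initial: float
    mean_final: float
    t_stat: float
    p_value: float
    n: int
    degenerate: bool = False


def paired_change_stats(initial, final) -> PairedStats:
    """Paired t test on composite scores between study initiation and end."""
    a = np.asarray(initial, dtype=float)
    b = np.asarray(final, dtype=float)
    if a.shape != b.shape:
        raise ValueError("initial and final must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = b - a
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return PairedStats(float(a.mean()), float(b.mean()), 0.0, 1.0, a.size)
        # constant nonzero shift: t is unbounded, flag rather than fabricate
        t = math.inf if diff.mean() > 0 else -math.inf
        return PairedStats(float(a.mean()), float(b.mean()), t, 0.0, a.size, degenerate=True)
    t, p = stats.ttest_rel(b, a)
    return PairedStats(float(a.mean()), float(b.mean()), float(t), float(p), a.size)


def change_correlation(dqol, dexercise) -> tuple[float, float]:
    """Pearson correlation between paired per-dog changes, two-sided p."""
    x = np.asarray(dqol, dtype=float)
    y = np.asarray(dexercise, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pooled_sensitivity(reports: list[EvalReport], ci_method: str = "wald"):
    """Pooled sensitivity on summed counts plus the mean of per-dog values.

    Pooling sums TP and evaluable-seizure counts across dogs; the mean
    per-dog sensitivity (dogs with no evaluable seizures excluded) is a
    different quantity and both are reported, since with heterogeneous
    per-dog seizure counts they diverge.
    """
    n_tp = sum(r.n_tp for r in reports)
    n_eval = sum(r.n_evaluable for r in reports)
    pooled = sensitivity_ci(n_tp, n_eval, ci_method) if n_eval >= 1 else None
    per_dog = [r.sensitivity for r in reports if r.sensitivity is not None]
    mean_per_dog = float(np.mean(per_dog)) if per_dog else None
    return {
        "n_tp": n_tp,
        "n_eval": n_eval,
        "pooled": pooled,
        "mean_per_dog_sensitivity": mean_per_dog,
    }
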