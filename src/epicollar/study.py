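"""Two-phase field-study orchestration.

Mirrors the study protocol: every dog is evaluated over phase 1 with the
predefined 0.5 threshold, thresholds are then individualized per dog
from the phase-1 performance, and phase 2 is evaluated with the
individualized thresholds.  Results are reported per dog and pooled —
pooled sensitivity on summed counts alongside the mean of per-dog
sensitivities, which differ whenever per-dog seizure counts are
heterogeneous — together with the QoL paired comparison.

:class:`TwoPhaseStudy` is the model-like entry point; :meth:`fit`
returns a :class:`StudyResults` carrying the tables and a ``summary()``.
Cohorts may be passed materialized (small studies, tests) or described
by a :class:`~epicollar.simulate.SimulationConfig`, in which case each
dog-phase is regenerated from its own RNG substream on demand and
discarded after use, keeping memory flat for long simulated studies.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .detector import (
    IndividualizationPolicy,
    RFConfig,
    SeizureDetector,
    SeizureDetectorResults,
    individualize_threshold,
    truth_event_peaks,
)
from .evaluation import (
    EvalReport,
    PairedStats,
    evaluate_phase,
    exclude_nonwear_seizures,
    match_events,
    paired_change_stats,
    pooled_sensitivity,
    qol_composite,
)
from .features import FeatureOptions
from .simulate import (
    DEFAULT_START,
    DogStudyRecord,
    PhaseRecord,
    SimulationConfig,
    derive_seed,
    generate_qol_pair,
    simulate_dog_phase,
)


@dataclass(frozen=True)
class StudyPolicy:
    """Detection and evaluation policy for a study run."""

    threshold: float = 0.5
    merge_gap_windows: int = 1
    overlap_frac: float = 0.5
    match_tolerance_s: float = 60.0
    gap_day_rule: str = "floor"
    ci_method: str = "wald"
    individualization: IndividualizationPolicy = IndividualizationPolicy()


class TwoPhaseStudy:
    """The full pipeline over a cohort of dogs.

    Parameters
    ----------
    cohort
        Materialized list of :class:`DogStudyRecord`, or None to
        generate dogs on demand from ``config``.
    config, n_dogs, per_dog_overrides
        Streaming mode: simulation config, cohort size, and optional
        per-dog config overrides (heterogeneous seizure phenotypes).
    train_dogs
        Number of leading dogs (or explicit list of dog ids) whose
        phase-1 data trains the classifier; the study's classifier was
        built from only two dogs, which is the default here too.
    detector_results
        A pre-trained detector to reuse; skips training.
    """

    def __init__(
        self,
        cohort: list[DogStudyRecord] | None = None,
        *,
        config: SimulationConfig | None = None,
        n_dogs: int | None = None,
        per_dog_overrides: dict[str, dict] | None = None,
        policy: StudyPolicy = StudyPolicy(),
        feature_options: FeatureOptions = FeatureOptions(),
        rf_config: RFConfig = RFConfig(),
        train_dogs: int | list[str] = 2,
        train_max_negatives: int | None = 30_000,
        detector_results: SeizureDetectorResults | None = None,
        start_time: datetime = DEFAULT_START,
    ):
        if cohort is None and (config is None or n_dogs is None):
            raise ValueError("provide either a cohort or config + n_dogs")
        self.cohort = cohort
        self.config = config
        self.per_dog_overrides = per_dog_overrides or {}
        self.policy = policy
        self.feature_options = feature_options
        self.rf_config = rf_config
        self.train_max_negatives = train_max_negatives
        self.detector_results = detector_results
        self.start_time = start_time
        if cohort is not None:
            self.dog_ids = [rec.dog_id for rec in cohort]
            self._by_id = {rec.dog_id: rec for rec in cohort}
        else:
            self.dog_ids = [f"dog-{i:02d}" for i in range(n_dogs)]
            self._by_id = {}
        if isinstance(train_dogs, int):
            self.train_ids = self.dog_ids[:train_dogs]
        else:
            unknown = set(train_dogs) - set(self.dog_ids)
            if unknown:
                raise ValueError(f"unknown training dogs: {sorted(unknown)}")
            self.train_ids = list(train_dogs)

    # -- cohort access ------------------------------------------------

    def _dog_config(self, dog_id: str) -> SimulationConfig:
        from dataclasses import replace

        cfg = self.config
        if dog_id in self.per_dog_overrides:
            cfg = replace(cfg, **self.per_dog_overrides[dog_id])
        return cfg

    def _phase_record(self, dog_id: str, phase: int) -> PhaseRecord:
        if self._by_id:
            return self._by_id[dog_id].phase(phase)
        return simulate_dog_phase(self._dog_config(dog_id), dog_id, phase, self.start_time)

    def _qol_pair(self, dog_id: str):
        if self._by_id:
            rec = self._by_id[dog_id]
            return rec.qol_initial, rec.qol_final
        cfg = self._dog_config(dog_id)
        rng = np.random.default_rng(derive_seed(cfg.seed, "qol", dog_id))
        return generate_qol_pair(rng, cfg.qol_improvement_shift)

    # -- pipeline stages ----------------------------------------------

    def train_detector(self) -> SeizureDetectorResults:
        """Train the window classifier on the training dogs' phase 1."""
        records = [_SinglePhaseView(d, self._phase_record(d, 1)) for d in self.train_ids]
        model = SeizureDetector.from_records(
            records,
            phase=1,
            rf_config=self.rf_config,
            feature_options=self.feature_options,
            overlap_frac=self.policy.overlap_frac,
            max_negatives_per_record=self.train_max_negatives,
        )
        return model.fit()

    def _evaluate_dog_phase(
        self, det: SeizureDetectorResults, dog_id: str, phase: int, threshold: float
    ) -> tuple[EvalReport, list[float], list[float]]:
        pol = self.policy
        pr = self._phase_record(dog_id, phase)
        detections, series = det.detect(
            pr.trace, threshold=threshold, merge_gap_windows=pol.merge_gap_windows
        )
        truth = [ev for ev in pr.events if ev.kind == "generalized"]
        report = evaluate_phase(
            dog_id,
            phase,
            truth,
            detections,
            pr.trace.wear_mask,
            pr.trace.duration_s / 86400.0,
            tolerance_s=pol.match_tolerance_s,
            gap_day_rule=pol.gap_day_rule,
            ci_method=pol.ci_method,
            threshold=threshold,
        )
        kept, _ = exclude_nonwear_seizures(truth, pr.trace.wear_mask)
        match = match_events(detections, kept, pol.match_tolerance_s)
        tp_peaks = truth_event_peaks(series, match.detected_truth, pol.match_tolerance_s)
        missed_peaks = truth_event_peaks(series, match.missed_truth, pol.match_tolerance_s)
        return report, tp_peaks, missed_peaks

    def fit(self) -> "StudyResults":
        """Run training, both phases, individualization, and pooling."""
        det = self.detector_results or self.train_detector()
        reports: list[EvalReport] = []
        thresholds: dict[str, float] = {}
        for dog_id in self.dog_ids:
            r1, tp_peaks, missed_peaks = self._evaluate_dog_phase(
                det, dog_id, 1, self.policy.threshold
            )
            t2 = individualize_threshold(
                r1, tp_peaks, missed_peaks, self.policy.individualization, self.policy.threshold
            )
            thresholds[dog_id] = t2
            r2, _, _ = self._evaluate_dog_phase(det, dog_id, 2, t2)
            reports += [r1, r2]

        qol_init, qol_fin = [], []
        for dog_id in self.dog_ids:
            qi, qf = self._qol_pair(dog_id)
            if qi is not None and qf is not None:
                qol_init.append(qol_composite(qi))
                qol_fin.append(qol_composite(qf))
        qol_stats = (
            paired_change_stats(qol_init, qol_fin) if len(qol_init) >= 2 else None
        )
        return StudyResults(
            study=self,
            detector=det,
            reports=reports,
            thresholds=thresholds,
            qol_stats=qol_stats,
            qol_composites=(qol_init, qol_fin),
        )


class _SinglePhaseView:
    """Lightweight record exposing only phase 1 (training path)."""

    def __init__(self, dog_id: str, phase1: PhaseRecord):
        self.dog_id = dog_id
        self._phase1 = phase1

    def phase(self, which: int) -> PhaseRecord:
        if which != 1:
            raise ValueError("training view only carries phase 1")
        return self._phase1


@dataclass
class StudyResults:
    """Per-dog and pooled outcome of a two-phase study run."""

    study: TwoPhaseStudy
    detector: SeizureDetectorResults
    reports: list[EvalReport]
    thresholds: dict[str, float]
    qol_stats: PairedStats | None
    qol_composites: tuple[list[int], list[int]] = field(default_factory=lambda: ([], []))

    def phase_reports(self, phase: int) -> list[EvalReport]:
        return [r for r in self.reports if r.phase == phase]

    def pooled(self, phase: int) -> dict:
        """Pooled sensitivity (summed counts), mean per-dog sensitivity,
        mean per-dog false-detection rate, pooled FP / corrected days."""
        reps = self.phase_reports(phase)
        out = pooled_sensitivity(reps, self.study.policy.ci_method)
        out["n_fp"] = sum(r.n_fp for r in reps)
        out["corrected_days"] = sum(r.corrected_days for r in reps)
        out["mean_fdr_per_day"] = (
            float(np.mean([r.fdr_per_day for r in reps])) if reps else None
        )
        out["pooled_fdr_per_day"] = (
            out["n_fp"] / out["corrected_days"] if out["corrected_days"] > 0 else None
        )
        return out

    @property
    def per_dog(self) -> pd.DataFrame:
        """Flat table: one row per dog-phase."""
        rows = []
        for r in self.reports:
            lo, hi = r.ci95 if r.ci95 else (None, None)
            rows.append(
                {
                    "dog_id": r.dog_id,
                    "phase": r.phase,
                    "threshold": r.threshold,
                    "n_seizures_total": r.n_seizures_total,
                    "n_excluded_nonwear": r.n_excluded_nonwear,
                    "n_tp": r.n_tp,
                    "n_fn": r.n_fn,
                    "n_fp": r.n_fp,
                    "sensitivity_pct": r.sensitivity,
                    "ci95_lo_pct": lo,
                    "ci95_hi_pct": hi,
                    "phase_days": r.phase_days,
                    "corrected_days": r.corrected_days,
                    "fdr_per_day": r.fdr_per_day,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable study summary table."""
        lines = ["Two-phase collar-accelerometer study", "=" * 60]
        for phase in (1, 2):
            p = self.pooled(phase)
            label = "predefined 0.5" if phase == 1 else "individualized"
            lines.append(f"Phase {phase} (threshold: {label})")
            if p["pooled"] is not None:
                s, lo, hi = p["pooled"]
                lines.append(
                    f"  pooled sensitivity : {s:.1f}% (95% CI [{lo:.1f}%, {hi:.1f}%]) "
                    f"on {p['n_tp']}/{p['n_eval']} evaluable seizures"
                )
            else:
                lines.append("  pooled sensitivity : undefined (no evaluable seizures)")
            if p["mean_per_dog_sensitivity"] is not None:
                lines.append(
                    f"  mean per-dog sens. : {p['mean_per_dog_sensitivity']:.1f}%"
                )
            lines.append(
                f"  false detections   : {p['n_fp']} over {p['corrected_days']:.1f}"
                f" corrected days (mean {p['mean_fdr_per_day']:.3f}/day)"
            )
        lines.append("Individualized thresholds:")
        for dog_id, t in self.thresholds.items():
            tag = "" if abs(t - self.study.policy.threshold) < 1e-12 else "  (adjusted)"
            lines.append(f"  {dog_id}: {t:.4f}{tag}")
        if self.qol_stats is not None:
            q = self.qol_stats
            lines.append(
                f"QoL composite: {q.mean_initial:.2f} -> {q.mean_final:.2f} "
                f"(paired t = {q.t_stat:.2f}, p = {q.p_value:.4f}, n = {q.n})"
            )
        return "\n".join(lines)

    def to_markdown(self) -> str:
        """Cohort summary as a Markdown table (one row per dog-phase)."""
        df = self.per_dog
        cols = [
            "dog_id", "phase", "threshold", "n_tp", "n_fn", "n_fp",
            "sensitivity_pct", "fdr_per_day",
        ]
        return df[cols].to_markdown(index=False, floatfmt=".3f")

    def plot_performance(self, path=None):
        """Per-dog sensitivity and false-detection rate across phases."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        for dog_id in self.study.dog_ids:
            reps = {r.phase: r for r in self.reports if r.dog_id == dog_id}
            phases = sorted(reps)
            sens = [reps[p].sensitivity for p in phases]
            fdr = [reps[p].fdr_per_day for p in phases]
            ax1.plot(phases, sens, marker="o", label=dog_id)
            ax2.plot(phases, fdr, marker="o", label=dog_id)
        ax1.set_xlabel("study phase"), ax1.set_ylabel("sensitivity (%)")
        ax2.set_xlabel("study phase"), ax2.set_ylabel("false detections / day")
        ax1.set_xticks([1, 2]), ax2.set_xticks([1, 2])
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def run_two_phase_study(
    cohort: list[DogStudyRecord] | None = None,
    policy: StudyPolicy = StudyPolicy(),
    **kwargs,
) -> StudyResults:
    """Convenience wrapper: build a :class:`TwoPhaseStudy` and fit it."""
    return TwoPhaseStudy(cohort, policy=policy, **kwargs).fit()
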