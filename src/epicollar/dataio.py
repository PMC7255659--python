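"""Readers and writers for every on-disk dialect the pipeline touches.

Trace CSV: ``timestamp,ax_g,ay_g,az_g`` with ISO-8601 UTC timestamps,
one row per sample.  Events and wear masks are JSON interval lists
(half-open, sorted on write).  Run configuration is YAML, strictly
validated: unknown keys are rejected so typos cannot silently fall back
to defaults, and a config round-trips losslessly.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

from .detector import DetectionEvent, IndividualizationPolicy, RFConfig
from .features import FeatureOptions
from .intervals import Interval, check_disjoint_sorted, sort_intervals
from .simulate import AccelTrace, SeizureEvent, SimulationConfig
from .study import StudyPolicy

TRACE_COLUMNS = ["timestamp", "ax_g", "ay_g", "az_g"]


def _iso(t: datetime) -> str:
    return t.astimezone(timezone.utc).isoformat().replace("+00:00", "Z")


def parse_iso(s: str) -> datetime:
    t = datetime.fromisoformat(s.replace("Z", "+00:00"))
    if t.tzinfo is None:
        t = t.replace(tzinfo=timezone.utc)
    return t.astimezone(timezone.utc)


# ---------------------------------------------------------------------------
# trace CSV
# ---------------------------------------------------------------------------

def write_trace_csv(trace: AccelTrace, path) -> None:
    times = pd.Timestamp(trace.start_time) + pd.to_timedelta(
        np.arange(trace.n_samples) / trace.sample_rate_hz, unit="s"
    )
    df = pd.DataFrame(
        {
            "timestamp": times.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3] + "Z",
            "ax_g": trace.samples[:, 0],
            "ay_g": trace.samples[:, 1],
            "az_g": trace.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace_csv(path) -> AccelTrace:
    """Parse a trace CSV; malformed rows are reported with line numbers.

    The wear mask is not part of the CSV dialect; attach one from a mask
    JSON after loading.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trace file") from None
    if list(df.columns) != TRACE_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {TRACE_COLUMNS}, found {list(df.columns)}"
        )
    if len(df) == 0:
        raise ValueError(f"{path}: no samples")

    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise ValueError(f"{path}: malformed timestamp at line {bad[0] + 2}")
    vals = np.empty((len(df), 3), dtype=np.float64)
    for j, col in enumerate(TRACE_COLUMNS[1:]):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(v.isna().to_numpy())
        if bad.size:
            raise ValueError(f"{path}: malformed {col} at line {bad[0] + 2}")
        vals[:, j] = v.to_numpy()

    tns = ts.astype("int64").to_numpy()
    dt = np.diff(tns)
    if len(dt) and (dt <= 0).any():
        line = int(np.flatnonzero(dt <= 0)[0]) + 3
        raise ValueError(f"{path}: non-monotone timestamp at line {line}")
    if len(dt):
        step = np.median(dt)
        if np.abs(dt - step).max() > max(0.01 * step, 1000):
            raise ValueError(f"{path}: non-uniform sampling interval")
        rate = 1e9 / step
    else:
        rate = 1.0
    start = ts.iloc[0].to_pydatetime()
    return AccelTrace(start, float(rate), vals, wear_mask=[])


# ---------------------------------------------------------------------------
# events / detections / mask JSON
# ---------------------------------------------------------------------------

def write_events_json(events, path) -> None:
    recs = []
    for ev in sorted(events, key=lambda e: e.start):
        recs.append({"start": _iso(ev.start), "end": _iso(ev.end),
                     "kind": ev.kind, "source": ev.source})
    with open(path, "w") as fh:
        json.dump(recs, fh, indent=2)


def read_events_json(path) -> list[SeizureEvent]:
    with open(path) as fh:
        recs = json.load(fh)
    return [
        SeizureEvent(parse_iso(r["start"]), parse_iso(r["end"]),
                     r.get("kind", "generalized"), r.get("source", "diary"))
        for r in recs
    ]


def write_detections_json(detections: list[DetectionEvent], path) -> None:
    recs = [
        {
            "start": _iso(d.start),
            "end": _iso(d.end),
            "kind": "detection",
            "source": "detector",
            "peak_probability": d.peak_probability,
            "n_windows": d.n_windows,
        }
        for d in sorted(detections, key=lambda d: d.start)
    ]
    with open(path, "w") as fh:
        json.dump(recs, fh, indent=2)


def read_detections_json(path) -> list[DetectionEvent]:
    with open(path) as fh:
        recs = json.load(fh)
    return [
        DetectionEvent(parse_iso(r["start"]), parse_iso(r["end"]),
                       float(r.get("peak_probability", 1.0)), int(r.get("n_windows", 1)))
        for r in recs
    ]


def write_mask_json(mask: list[Interval], path) -> None:
    ivs = sort_intervals(mask)
    check_disjoint_sorted(ivs)
    with open(path, "w") as fh:
        json.dump([{"start": _iso(a), "end": _iso(b)} for a, b in ivs], fh, indent=2)


def read_mask_json(path) -> list[Interval]:
    with open(path) as fh:
        recs = json.load(fh)
    ivs = sort_intervals([(parse_iso(r["start"]), parse_iso(r["end"])) for r in recs])
    check_disjoint_sorted(ivs)  # overlapping non-collection intervals are malformed
    return ivs


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """One study run: cohort, simulation, features, model, and policy."""

    seed: int = 0
    n_dogs: int = 5
    train_dogs: int = 2
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    features: FeatureOptions = field(default_factory=FeatureOptions)
    rf: RFConfig = field(default_factory=RFConfig)
    policy: StudyPolicy = field(default_factory=StudyPolicy)

    def to_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists, plain types only

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        out = {}
        out["simulation"] = _build_dc(SimulationConfig, d.pop("simulation", {}))
        out["features"] = _build_dc(FeatureOptions, d.pop("features", {}))
        out["rf"] = _build_dc(RFConfig, d.pop("rf", {}))
        pol = dict(d.pop("policy", {}))
        indiv = _build_dc(IndividualizationPolicy, pol.pop("individualization", {}))
        out["policy"] = _build_dc(StudyPolicy, pol, individualization=indiv)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        out.update(d)
        return cls(**out)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def config_hash(self) -> str:
        """Stable digest identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_TUPLE_FIELDS = {
    "seizure_duration_s", "tonic_duration_s", "tonic_amp_g", "clonic_freq_hz",
    "clonic_amp_g", "gap_schedule",
}


def _build_dc(cls, d: dict, **extra):
    if not isinstance(d, dict):
        raise ValueError(f"expected mapping for {cls.__name__}, got {type(d).__name__}")
    d = dict(d)
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for k, v in list(d.items()):
        if k in _TUPLE_FIELDS and isinstance(v, list):
            d[k] = tuple(v)
        elif k == "activity_schedule" and isinstance(v, list):
            d[k] = tuple(tuple(item) for item in v)
    return cls(**d, **extra)
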