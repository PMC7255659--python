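"""Synthetic collar-accelerometer study generator.

Emulates the data produced by a collar-mounted, 3-axis, 8-bit, 100 Hz
accelerometer worn by an epileptic dog over a two-phase field study:
rest and everyday activity bouts, generalized tonic-clonic seizure
signatures, slow collar-roll nuisance rotation, sensor noise and ADC
quantization, charging gaps (recorded as a wear mask), and paired
quality-of-life questionnaire sheets.

The seizure waveform is a synthetic stand-in: no quantitative kinematic
description of canine tonic-clonic movement exists for this device, so
the tonic (sustained offset plus broadband tremor) and clonic (decaying
1-4 Hz sinusoid) segments are phenomenological and fully config-exposed.

Axis convention for the dog frame: columns are (cranial, lateral,
ventral); at rest the sensed specific force is ``(0, 0, -1)`` g.  The
collar-roll nuisance rotation acts about the cranial (neck) axis.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone

import numpy as np

from .evaluation import QoLResponse, REVERSE_CODED_DEFAULT
from .intervals import Interval, check_disjoint_sorted, intersects, validate_interval

DEFAULT_START = datetime(2016, 1, 1, tzinfo=timezone.utc)

#: default everyday-activity schedule: (kind, mean bout seconds, fraction of each day)
DEFAULT_ACTIVITY_SCHEDULE: tuple[tuple[str, float, float], ...] = (
    ("walk", 600.0, 0.08),
    ("play", 180.0, 0.03),
    ("shake", 8.0, 0.004),
    ("scratch", 25.0, 0.008),
)

CONFUSABLE_KINDS = ("shake", "scratch", "play")


def derive_seed(root_seed: int, *names: object) -> int:
    """Stable sub-seed below 2**31 from a root seed and a name path.

    Uses SHA-256 so substreams are reproducible across processes and
    Python versions (the builtin ``hash`` is salted per process).
    """
    h = hashlib.sha256(repr((int(root_seed),) + tuple(names)).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dog-study.

    ``duration_days`` is the length of *each* study phase.  Amplitudes
    are in g, frequencies in Hz, and ``collar_roll_drift`` is the
    angular-random-walk scale of the collar's roll about the neck axis
    in rad/sqrt(hour).
    """

    seed: int = 0
    duration_days: float = 90.0
    sample_rate_hz: float = 100.0
    adc_bits: int = 8
    adc_range_g: float = 8.0
    seizure_rate_per_day: float = 0.1
    seizure_duration_s: tuple[float, float] = (30.0, 120.0)
    tonic_duration_s: tuple[float, float] = (5.0, 20.0)
    tonic_amp_g: tuple[float, float] = (0.5, 1.5)
    clonic_freq_hz: tuple[float, float] = (1.0, 4.0)
    clonic_amp_g: tuple[float, float] = (1.5, 3.0)
    activity_schedule: tuple[tuple[str, float, float], ...] = DEFAULT_ACTIVITY_SCHEDULE
    activity_amp_g: float = 0.5
    collar_roll_drift: float = 0.3
    collar_roll_initial_rad: float | None = None
    gap_schedule: tuple[float, float] = (3.0, 2.0)  # charge every k days for g hours
    noise_sd_g: float = 0.02
    qol_improvement_shift: float = 0.7
    allow_seizures_in_gaps: bool = False

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.adc_bits < 2:
            raise ValueError("adc_bits must be >= 2")
        if self.adc_range_g <= 0:
            raise ValueError("adc_range_g must be positive")
        if self.seizure_rate_per_day < 0:
            raise ValueError("seizure_rate_per_day must be non-negative")
        lo, hi = self.seizure_duration_s
        if not (0 < lo <= hi):
            raise ValueError("seizure_duration_s must satisfy 0 < min <= max")
        flo, fhi = self.clonic_freq_hz
        if not (0.5 <= flo <= fhi <= 6.0):
            raise ValueError("clonic_freq_hz must lie within [0.5, 6] Hz")
        frac = sum(f for _, _, f in self.activity_schedule)
        if frac > 1.0 + 1e-9:
            raise ValueError("activity daily_fraction values must sum to <= 1")
        # a rate so high that seizures are expected to overlap is unphysical
        if self.seizure_rate_per_day * hi > 0.25 * 86400.0:
            raise ValueError("seizure_rate_per_day too high: expected events would overlap")

    @property
    def adc_step_g(self) -> float:
        return 2.0 * self.adc_range_g / 2**self.adc_bits


@dataclass
class AccelTrace:
    """Uniformly sampled 3-axis acceleration with a non-collection mask.

    ``samples`` is an (N, 3) float array in g; ``wear_mask`` lists the
    half-open non-collection intervals (charging etc.), sorted and
    disjoint, within the trace extent.
    """

    start_time: datetime
    sample_rate_hz: float
    samples: np.ndarray
    wear_mask: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (N, 3)")
        check_disjoint_sorted(self.wear_mask)
        for iv in self.wear_mask:
            validate_interval(*iv)
            if iv[0] < self.start_time or iv[1] > self.end_time:
                raise ValueError("wear_mask interval outside trace extent")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=self.duration_s)

    @property
    def extent(self) -> Interval:
        return (self.start_time, self.end_time)

    def time_of_sample(self, i: int) -> datetime:
        return self.start_time + timedelta(seconds=i / self.sample_rate_hz)

    def sample_index(self, t: datetime) -> int:
        return int(round((t - self.start_time).total_seconds() * self.sample_rate_hz))


@dataclass(frozen=True)
class SeizureEvent:
    """A ground-truth seizure as a half-open absolute-time interval."""

    start: datetime
    end: datetime
    kind: str = "generalized"
    source: str = "simulator"

    def __post_init__(self) -> None:
        validate_interval(self.start, self.end)
        if self.kind not in ("generalized", "focal"):
            raise ValueError(f"unknown seizure kind {self.kind!r}")
        if self.source not in ("diary", "video", "simulator"):
            raise ValueError(f"unknown seizure source {self.source!r}")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class PhaseRecord:
    trace: AccelTrace
    events: list[SeizureEvent]


@dataclass
class DogStudyRecord:
    """One dog's two-phase study: traces, truth events, threshold, QoL sheets."""

    dog_id: str
    phase1: PhaseRecord
    phase2: PhaseRecord
    threshold: float = 0.5
    qol_initial: QoLResponse | None = None
    qol_final: QoLResponse | None = None

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if intersects(self.phase1.trace.extent, self.phase2.trace.extent):
            raise ValueError("study phases must not overlap in time")

    def phase(self, which: int) -> PhaseRecord:
        if which == 1:
            return self.phase1
        if which == 2:
            return self.phase2
        raise ValueError("phase must be 1 or 2")


# ---------------------------------------------------------------------------
# waveform building blocks
# ---------------------------------------------------------------------------

def quantize(samples: np.ndarray, adc_bits: int, adc_range_g: float) -> np.ndarray:
    """Mid-tread uniform quantization over [-range, +range].

    Idempotent: quantizing an already-quantized array is a no-op.
    """
    step = 2.0 * adc_range_g / 2**adc_bits
    clipped = np.clip(samples, -adc_range_g, adc_range_g)
    return (np.round(clipped / step) * step).astype(samples.dtype)


def seizure_waveform(duration_s: float, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Generalized tonic-clonic signature: tonic offset + tremor, then a
    decaying clonic sinusoid.  Returns an (n, 3) dog-frame block in g
    (dynamics only, no gravity)."""
    fs = config.sample_rate_hz
    n = int(round(duration_s * fs))
    out = np.zeros((n, 3), dtype=np.float32)
    if n == 0:
        return out
    tonic_s = float(np.clip(rng.uniform(*config.tonic_duration_s), 0.0, 0.4 * duration_s))
    n_tonic = int(round(tonic_s * fs))

    if n_tonic > 0:
        amp = rng.uniform(*config.tonic_amp_g)
        ramp = np.minimum(np.arange(n_tonic) / (0.5 * fs), 1.0).astype(np.float32)
        tremor = rng.normal(0.0, 0.35 * amp, size=(n_tonic, 3)).astype(np.float32)
        out[:n_tonic, 0] += amp * ramp
        out[:n_tonic] += tremor * ramp[:, None]

    n_clonic = n - n_tonic
    if n_clonic > 0:
        freq = rng.uniform(*config.clonic_freq_hz)
        amp0 = rng.uniform(*config.clonic_amp_g)
        t = np.arange(n_clonic, dtype=np.float32) / fs
        # decay to ~30% of initial amplitude by seizure end
        tau = (n_clonic / fs) / np.log(1.0 / 0.3)
        envelope = amp0 * np.exp(-t / tau)
        phase = 2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)
        osc = envelope * np.sin(phase)
        mix = rng.uniform(0, 2 * np.pi)  # cranial/lateral orientation of the jerks
        out[n_tonic:, 0] += np.cos(mix) * osc
        out[n_tonic:, 1] += np.sin(mix) * osc
        out[n_tonic:, 2] += 0.25 * envelope * np.sin(2 * phase)
    return out


def simulate_confusable_activity(
    kind: str,
    duration_s: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    amplitude_g: float | None = None,
) -> np.ndarray:
    """Rhythmic 3-6 Hz everyday-activity block (dog frame, dynamics only).

    Shaking, scratching and play share the clonic frequency range and are
    distinguishable from seizures mainly by amplitude envelope and axis
    mix; they exist to stress the false-detection rate.
    """
    if kind not in CONFUSABLE_KINDS:
        raise ValueError(f"unknown confusable activity kind {kind!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    fs = config.sample_rate_hz
    n = int(round(duration_s * fs))
    out = np.zeros((n, 3), dtype=np.float32)
    if n == 0:
        return out
    amp = config.activity_amp_g if amplitude_g is None else amplitude_g
    t = np.arange(n, dtype=np.float32) / fs
    if kind == "shake":
        freq = rng.uniform(4.0, 6.0)
        envelope = amp * np.hanning(n).astype(np.float32)
        axis_w = np.array([0.3, 1.0, 0.5], dtype=np.float32)
    elif kind == "scratch":
        freq = rng.uniform(3.0, 5.0)
        envelope = np.full(n, amp, dtype=np.float32)
        envelope[: n // 10] *= np.linspace(0, 1, n // 10 or 1, dtype=np.float32)
        axis_w = np.array([0.6, 0.8, 0.4], dtype=np.float32)
    else:  # play: rhythmic core plus broadband romping
        freq = rng.uniform(3.0, 4.5)
        envelope = amp * (0.6 + 0.4 * np.sin(2 * np.pi * 0.2 * t)).astype(np.float32)
        axis_w = np.array([1.0, 0.6, 0.7], dtype=np.float32)
        out += rng.normal(0.0, 0.3 * amp, size=(n, 3)).astype(np.float32)
    osc = envelope * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    out += osc[:, None] * axis_w[None, :]
    return out


def _walk_waveform(duration_s, config, rng) -> np.ndarray:
    fs = config.sample_rate_hz
    n = int(round(duration_s * fs))
    out = np.zeros((n, 3), dtype=np.float32)
    if n == 0:
        return out
    t = np.arange(n, dtype=np.float32) / fs
    freq = rng.uniform(1.4, 2.4)  # stride frequency
    amp = 0.8 * config.activity_amp_g
    osc = amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    out[:, 0] += osc
    out[:, 2] += 0.6 * amp * np.sin(2 * np.pi * 2 * freq * t)
    out += rng.normal(0.0, 0.15 * amp, size=(n, 3)).astype(np.float32)
    return out


def _activity_block(kind, duration_s, config, rng) -> np.ndarray:
    if kind == "walk":
        return _walk_waveform(duration_s, config, rng)
    return simulate_confusable_activity(kind, duration_s, config, rng)


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def gap_intervals(config: SimulationConfig, start_time: datetime, duration_s: float) -> list[Interval]:
    """Deterministic charging gaps: every k days, lasting g hours."""
    every_days, gap_hours = config.gap_schedule
    out: list[Interval] = []
    if every_days <= 0 or gap_hours <= 0:
        return out
    t = every_days * 86400.0
    while t < duration_s:
        lo = start_time + timedelta(seconds=t)
        hi = start_time + timedelta(seconds=min(t + gap_hours * 3600.0, duration_s))
        if lo < hi:
            out.append((lo, hi))
        t += every_days * 86400.0
    return out


def draw_seizure_schedule(
    config: SimulationConfig,
    rng: np.random.Generator,
    start_time: datetime,
    duration_s: float,
    gaps: list[Interval] | None = None,
) -> list[SeizureEvent]:
    """Homogeneous-Poisson seizure times with uniform placement.

    The event count is Poisson(rate x duration); events are redrawn if
    they would overlap one another or (unless configured otherwise) fall
    wholly inside a non-collection gap.
    """
    gaps = gaps or []
    duration_days = duration_s / 86400.0
    n_events = int(rng.poisson(config.seizure_rate_per_day * duration_days))
    events: list[Interval] = []
    for _ in range(n_events):
        for _attempt in range(1000):
            dur = rng.uniform(*config.seizure_duration_s)
            if dur >= duration_s:
                dur = duration_s * 0.5
            t0 = rng.uniform(0.0, duration_s - dur)
            lo = start_time + timedelta(seconds=float(t0))
            hi = lo + timedelta(seconds=float(dur))
            if any(intersects((lo, hi), ev) for ev in events):
                continue
            if not config.allow_seizures_in_gaps and any(
                g[0] <= lo and hi <= g[1] for g in gaps
            ):
                continue
            events.append((lo, hi))
            break
        else:  # pragma: no cover - pathological configs rejected upstream
            raise RuntimeError("could not place seizure without overlap")
    events.sort()
    return [SeizureEvent(lo, hi, "generalized", "simulator") for lo, hi in events]


def _activity_bouts(config, rng, duration_s, reserved: list[tuple[float, float]]):
    """Place activity bouts (offsets in seconds) avoiding reserved spans."""
    bouts: list[tuple[str, float, float]] = []
    occupied = list(reserved)
    for kind, mean_bout_s, daily_fraction in config.activity_schedule:
        target = daily_fraction * duration_s
        placed = 0.0
        attempts = 0
        while placed < target and attempts < 10000:
            attempts += 1
            dur = float(np.clip(rng.exponential(mean_bout_s), 2.0, mean_bout_s * 6))
            if dur >= duration_s:
                break
            t0 = rng.uniform(0.0, duration_s - dur)
            if any(t0 < hi and lo < t0 + dur for lo, hi in occupied):
                continue
            occupied.append((t0, t0 + dur))
            bouts.append((kind, t0, dur))
            placed += dur
    return bouts


# ---------------------------------------------------------------------------
# trace assembly
# ---------------------------------------------------------------------------

def _expand_piecewise_linear(coarse: np.ndarray, n: int, spp: int) -> np.ndarray:
    """Upsample a per-second series to per-sample by linear interpolation."""
    n_sec_full = n // spp + (1 if n % spp else 0)
    frac = (np.arange(spp, dtype=np.float32) / spp)[None, :]
    seg = coarse[:n_sec_full, None] + np.diff(coarse)[:n_sec_full, None] * frac
    return seg.ravel()[:n]


def _collar_roll_cos_sin(
    config, rng, n, fs
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (cos, sin) of the collar roll angle.

    At integer samples-per-second rates the transcendentals are taken on
    the 1 s coarse grid and expanded piecewise-linearly: the roll drifts
    by ~1e-3 rad/s, so the interpolation error is far below sensor noise.
    """
    theta0 = (
        rng.uniform(-np.pi, np.pi)
        if config.collar_roll_initial_rad is None
        else float(config.collar_roll_initial_rad)
    )
    n_sec = max(int(np.ceil(n / fs)), 1) + 2
    inc_sd = config.collar_roll_drift / np.sqrt(3600.0)
    coarse = theta0 + np.concatenate(
        [[0.0], np.cumsum(rng.normal(0.0, inc_sd, size=n_sec - 1))]
    )
    spp = int(round(fs))
    if abs(spp - fs) < 1e-9 and spp >= 1 and n >= spp:
        cc = np.cos(coarse).astype(np.float32)
        sc = np.sin(coarse).astype(np.float32)
        return _expand_piecewise_linear(cc, n, spp), _expand_piecewise_linear(sc, n, spp)
    idx = np.arange(n) / fs
    theta = np.interp(idx, np.arange(n_sec, dtype=float), coarse)
    return np.cos(theta).astype(np.float32), np.sin(theta).astype(np.float32)


def _apply_collar_roll(dyn: np.ndarray, c: np.ndarray, s: np.ndarray) -> None:
    """In-place rotation about the cranial axis given per-sample cos/sin."""
    y = dyn[:, 1].copy()
    z = dyn[:, 2]
    dyn[:, 1] = c * y - s * z
    dyn[:, 2] = s * y + c * z


def simulate_trace(
    config: SimulationConfig,
    rng: np.random.Generator,
    start_time: datetime = DEFAULT_START,
) -> tuple[AccelTrace, list[SeizureEvent]]:
    """One phase of collar accelerometry plus its ground-truth seizures."""
    fs = config.sample_rate_hz
    duration_s = config.duration_days * 86400.0
    n = int(round(duration_s * fs))
    if n == 0:
        raise ValueError("duration too short for sample rate")

    gaps = gap_intervals(config, start_time, duration_s)
    events = draw_seizure_schedule(config, rng, start_time, duration_s, gaps)

    dyn = np.zeros((n, 3), dtype=np.float32)

    reserved = [
        ((ev.start - start_time).total_seconds(), (ev.end - start_time).total_seconds())
        for ev in events
    ]
    for kind, t0, dur in _activity_bouts(config, rng, duration_s, reserved):
        i0 = int(round(t0 * fs))
        block = _activity_block(kind, dur, config, rng)
        i1 = min(i0 + block.shape[0], n)
        dyn[i0:i1] += block[: i1 - i0]

    for ev in events:
        i0 = ev_i0 = int(round((ev.start - start_time).total_seconds() * fs))
        block = seizure_waveform(ev.duration_s, config, rng)
        i1 = min(ev_i0 + block.shape[0], n)
        dyn[i0:i1] += block[: i1 - i0]

    dyn[:, 2] -= 1.0  # gravity: rest reads (0, 0, -1) g in the dog frame

    cth, sth = _collar_roll_cos_sin(config, rng, n, fs)
    _apply_collar_roll(dyn, cth, sth)
    del cth, sth

    # chunked so noise temporaries never materialize all at once
    chunk = 10_000_000
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        noise = rng.standard_normal(size=(i1 - i0, 3), dtype=np.float32)
        noise *= config.noise_sd_g
        dyn[i0:i1] += noise
        dyn[i0:i1] = quantize(dyn[i0:i1], config.adc_bits, config.adc_range_g)

    for lo, hi in gaps:  # non-collection periods store zeros
        i0 = int(round((lo - start_time).total_seconds() * fs))
        i1 = int(round((hi - start_time).total_seconds() * fs))
        dyn[i0:i1] = 0.0

    trace = AccelTrace(start_time, fs, dyn, wear_mask=gaps)
    return trace, events


def generate_qol_pair(
    seed_or_rng: int | np.random.Generator,
    improvement_shift: float,
    reverse_coded: frozenset[int] = REVERSE_CODED_DEFAULT,
) -> tuple[QoLResponse, QoLResponse]:
    """Paired 15-item QoL sheets (initial, final).

    Items use the 1-5 bipolar scale.  ``improvement_shift`` moves the
    final sheet toward better quality of life on the *standardized*
    scale (high = good); raw values for reverse-coded items are flipped
    accordingly.  Clipping keeps every item in 1..5.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    latent = rng.normal(3.0, 1.0, size=15)  # standardized scale, high = good
    std_initial = np.clip(np.round(latent), 1, 5).astype(int)
    std_final = np.clip(np.round(latent + improvement_shift), 1, 5).astype(int)

    def to_raw(std: np.ndarray) -> QoLResponse:
        raw = [int(6 - v) if i in reverse_coded else int(v) for i, v in enumerate(std)]
        return QoLResponse(tuple(raw), reverse_coded)

    return to_raw(std_initial), to_raw(std_final)


def simulate_dog_phase(
    config: SimulationConfig,
    dog_id: str,
    phase: int,
    start_time: datetime = DEFAULT_START,
) -> PhaseRecord:
    """Simulate a single study phase for one dog.

    Each (dog, phase) pair draws from its own RNG substream, so a phase
    can be regenerated on its own, bit-identically, without holding the
    rest of the cohort in memory.  Phase 2 starts where phase 1 ends.
    """
    if phase not in (1, 2):
        raise ValueError("phase must be 1 or 2")
    phase_start = start_time
    if phase == 2:
        phase_start = start_time + timedelta(seconds=config.duration_days * 86400.0)
    rng = np.random.default_rng(derive_seed(config.seed, "dog", dog_id, phase))
    trace, events = simulate_trace(config, rng, phase_start)
    return PhaseRecord(trace, events)


def simulate_dog(
    config: SimulationConfig,
    dog_id: str = "dog-00",
    start_time: datetime = DEFAULT_START,
) -> DogStudyRecord:
    """Simulate one dog's two-phase study record.

    Deterministic given ``(config.seed, dog_id)``: each dog (and each
    phase) draws from its own RNG substream so cohorts can be generated
    in any order.
    """
    p1 = simulate_dog_phase(config, dog_id, 1, start_time)
    p2 = simulate_dog_phase(config, dog_id, 2, start_time)
    trace1, events1 = p1.trace, p1.events
    trace2, events2 = p2.trace, p2.events
    qol_rng = np.random.default_rng(derive_seed(config.seed, "qol", dog_id))
    qol_initial, qol_final = generate_qol_pair(qol_rng, config.qol_improvement_shift)
    return DogStudyRecord(
        dog_id=dog_id,
        phase1=PhaseRecord(trace1, events1),
        phase2=PhaseRecord(trace2, events2),
        threshold=0.5,
        qol_initial=qol_initial,
        qol_final=qol_final,
    )


def simulate_cohort(
    config: SimulationConfig,
    n_dogs: int,
    start_time: datetime = DEFAULT_START,
    per_dog_overrides: dict[str, dict] | None = None,
) -> list[DogStudyRecord]:
    """Simulate ``n_dogs`` independent dogs under one config.

    ``per_dog_overrides`` maps dog_id to SimulationConfig field
    overrides, used to give dogs heterogeneous seizure phenotypes.
    """
    cohort = []
    for i in range(n_dogs):
        dog_id = f"dog-{i:02d}"
        cfg = config
        if per_dog_overrides and dog_id in per_dog_overrides:
            cfg = replace(config, **per_dog_overrides[dog_id])
        cohort.append(simulate_dog(cfg, dog_id, start_time))
    return cohort
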