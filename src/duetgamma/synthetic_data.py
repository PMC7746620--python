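"""Generative models for call streams and LFP traces.

The simulators produce data with the statistical structure the analysis
assumes, so every downstream stage is testable without recordings:

- call streams are homogeneous Poisson processes per (bird, call type),
  plus context-dependent "answers" inserted after heard partner calls;
- LFP traces are noise plus stimulus-locked narrowband bursts spanning
  each heard call, with amplitude controlled by a per-call gain.

One seed governs a whole simulated experiment; per-session RNGs are
derived deterministically with ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from duetgamma.datamodel_io import (
    REPERTOIRE,
    CallEvent,
    EventStream,
    LFPTrace,
    ValidationError,
    write_events,
    write_trace,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LatencySpec:
    """Distribution of answer latencies, supported on ``(low_s, high_s]``.

    ``family`` is ``"uniform"`` or ``"exponential-truncated"``; the latter
    is an exponential with the given ``scale_s`` truncated to the support.
    """

    family: str = "uniform"
    low_s: float = 0.05
    high_s: float = 0.45
    scale_s: float = 0.1

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "exponential-truncated"):
            raise ValidationError(f"unknown latency family {self.family!r}")
        if not (0 < self.low_s < self.high_s):
            raise ValidationError(
                f"latency support must satisfy 0 < low < high, got ({self.low_s}, {self.high_s})"
            )
        if self.scale_s <= 0:
            raise ValidationError("scale_s must be > 0")

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.family == "uniform":
            return rng.uniform(self.low_s, self.high_s, size=size)
        # inverse-CDF sampling of the truncated exponential
        u = rng.uniform(size=size)
        a = math.exp(-self.low_s / self.scale_s)
        b = math.exp(-self.high_s / self.scale_s)
        return -self.scale_s * np.log(a - u * (a - b))

    @property
    def mean_s(self) -> float:
        """Closed-form mean, used by recovery tests."""
        if self.family == "uniform":
            return 0.5 * (self.low_s + self.high_s)
        a, b = self.low_s, self.high_s
        s = self.scale_s
        ea, eb = math.exp(-a / s), math.exp(-b / s)
        return s + (a * ea - b * eb) / (ea - eb)


@dataclass
class VocalSimParams:
    """Parameters of one simulated vocal session.

    ``base_rates[bird][call_type]`` is the Poisson rate (calls/s) of
    spontaneous calling; ``reply_prob[(responder, ref_call_type)]`` is the
    probability that ``responder`` answers a heard call of that type, with
    latency drawn from ``latency``.  Answers are emitted as
    ``reply_call_type`` calls.  Answers neither suppress baseline events
    nor trigger further answers (no refractoriness, no chaining).
    """

    base_rates: Mapping[str, Mapping[str, float]]
    reply_prob: Mapping[tuple[str, str], float] = field(default_factory=dict)
    latency: LatencySpec = field(default_factory=LatencySpec)
    reply_call_type: str = "stack"
    call_duration_s: float = 0.15
    session_length_s: float = 600.0
    day_index: int = 0
    treatment: str = "NB"
    seed: int | None = None

    def __post_init__(self) -> None:
        for bird, rates in self.base_rates.items():
            for call_type, lam in rates.items():
                if call_type not in REPERTOIRE:
                    raise ValidationError(f"unknown call_type {call_type!r} for bird {bird}")
                if lam < 0:
                    raise ValidationError(f"rate for ({bird}, {call_type}) must be >= 0")
        for key, p in self.reply_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"reply_prob{key} must be in [0, 1], got {p}")
        if self.reply_call_type not in REPERTOIRE:
            raise ValidationError(f"unknown reply_call_type {self.reply_call_type!r}")
        if self.session_length_s <= 0 or self.call_duration_s <= 0:
            raise ValidationError("session_length_s and call_duration_s must be > 0")


def simulate_vocal_session(
    params: VocalSimParams, rng: np.random.Generator | None = None
) -> list[EventStream]:
    """Simulate one session of multi-bird calling with answers.

    Baseline events follow a homogeneous Poisson process per (bird, call
    type).  For each baseline call a bird hears, each other bird answers
    independently with its configured probability, at the call's onset
    plus a drawn latency.  Answers falling past the session end are
    dropped.  Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    T = params.session_length_s
    baseline: dict[str, list[CallEvent]] = {bird: [] for bird in params.base_rates}
    for bird, rates in params.base_rates.items():
        for call_type, lam in rates.items():
            n = rng.poisson(lam * T)
            onsets = np.sort(rng.uniform(0.0, T, size=n))
            baseline[bird].extend(
                CallEvent(bird, call_type, float(t), params.call_duration_s,
                          params.day_index, params.treatment)
                for t in onsets
            )

    answers: dict[str, list[CallEvent]] = {bird: [] for bird in params.base_rates}
    heard = sorted((e for events in baseline.values() for e in events), key=lambda e: e.onset_s)
    for event in heard:
        for responder in params.base_rates:
            if responder == event.emitter_id:
                continue
            p = params.reply_prob.get((responder, event.call_type), 0.0)
            if p > 0.0 and rng.random() < p:
                onset = event.onset_s + float(params.latency.sample(rng))
                if onset + params.call_duration_s <= T:
                    answers[responder].append(
                        CallEvent(responder, params.reply_call_type, onset,
                                  params.call_duration_s, params.day_index, params.treatment)
                    )

    streams = []
    for bird in params.base_rates:
        events = sorted(baseline[bird] + answers[bird], key=lambda e: e.onset_s)
        streams.append(
            EventStream(bird_id=bird, events=events, day_index=params.day_index,
                        treatment=params.treatment, session_length_s=T)
        )
    return streams


@dataclass
class LFPSimParams:
    """Parameters of the simulated neural trace.

    Each heard call evokes a burst: an amplitude-enveloped narrowband
    oscillation centred at ``burst_fc_hz`` spanning exactly the call's
    ``[onset, onset + duration)``.  ``burst_bw_hz == 0`` gives a pure
    tone; otherwise the carrier is a random-phase sum of tones covering
    ``fc ± bw/2``, normalized so a burst of amplitude ``A`` has RMS
    ``A/sqrt(2)`` (the pure-tone convention).  Burst amplitude is
    ``burst_amplitude * gain(call)``.
    """

    fs_hz: float = 1000.0
    noise_model: str = "white"  # "white" | "one-over-f"
    noise_sigma: float = 1.0
    burst_fc_hz: float = 40.0
    burst_bw_hz: float = 0.0
    burst_amplitude: float = 1.0
    gain: Callable[[CallEvent], float] | None = None
    ramp_s: float = 0.01  # raised-cosine on/off ramps against spectral splatter
    onset_jitter_s: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fs_hz < 400:
            raise ValidationError(f"fs_hz must be >= 400 for the 10-200 Hz bank, got {self.fs_hz}")
        if self.noise_model not in ("white", "one-over-f"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.burst_bw_hz < 0 or self.burst_amplitude < 0:
            raise ValidationError("burst bandwidth and amplitude must be >= 0")

    def gain_for(self, call: CallEvent) -> float:
        g = 1.0 if self.gain is None else float(self.gain(call))
        if g < 0:
            raise ValidationError(f"gain for {call} is negative")
        return g


def gain_table(
    table: Mapping[tuple[str, str, str], float], default: float = 1.0
) -> Callable[[CallEvent], float]:
    """Build a gain function from a ``(treatment, call_type, emitter) -> g`` map.

    Missing keys fall back to ``(treatment, call_type, "*")``, then to
    ``default``.
    """

    def gain(call: CallEvent) -> float:
        key = (call.treatment, call.call_type, call.emitter_id)
        if key in table:
            return table[key]
        return table.get((call.treatment, call.call_type, "*"), default)

    return gain


def _burst(
    n: int, fs: float, fc: float, bw: float, ramp_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-amplitude burst waveform of ``n`` samples (RMS ~ 1/sqrt(2))."""
    t = np.arange(n) / fs
    if bw == 0.0:
        carrier = np.cos(2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi))
    else:
        freqs = np.arange(fc - bw / 2, fc + bw / 2 + 1e-9, max(bw / 6.0, 1.0))
        phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
        carrier = np.cos(2 * np.pi * np.outer(freqs, t) + phases[:, None]).sum(axis=0)
    envelope = np.ones(n)
    n_ramp = min(int(round(ramp_s * fs)), n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        envelope[:n_ramp] = ramp
        envelope[-n_ramp:] = ramp[::-1]
    if bw > 0.0:
        # match the pure-tone convention: RMS of the unenveloped carrier = 1/sqrt(2)
        rms = np.sqrt(np.mean(carrier**2))
        if rms > 0:
            carrier = carrier / rms / math.sqrt(2.0)
    return carrier * envelope


def _noise(n: int, params: LFPSimParams, rng: np.random.Generator) -> np.ndarray:
    if params.noise_sigma == 0.0:
        return np.zeros(n)
    white = rng.normal(0.0, params.noise_sigma, size=n)
    if params.noise_model == "white":
        return white
    # 1/f amplitude shaping in the frequency domain, variance re-matched
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / params.fs_hz)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    shaping[0] = 0.0
    shaped = np.fft.irfft(spectrum * shaping, n=n)
    std = shaped.std()
    if std > 0:
        shaped *= params.noise_sigma / std
    return shaped


def simulate_lfp(
    events_heard: Sequence[CallEvent],
    session_length_s: float,
    params: LFPSimParams,
    bird_id: str = "focal",
    rng: np.random.Generator | None = None,
) -> LFPTrace:
    """Simulate a trace as noise plus one burst per heard call.

    Overlapping calls are allowed; their bursts sum (logged).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_total = int(round(session_length_s * params.fs_hz))
    samples = _noise(n_total, params, rng)

    last_end = -math.inf
    n_overlap = 0
    for call in sorted(events_heard, key=lambda e: e.onset_s):
        if call.offset_s > session_length_s:
            raise ValidationError(f"call at {call.onset_s:.3f}s extends past the session end")
        onset = call.onset_s
        if params.onset_jitter_s > 0:
            onset = max(0.0, onset + rng.normal(0.0, params.onset_jitter_s))
        if onset < last_end:
            n_overlap += 1
        last_end = max(last_end, onset + call.duration_s)
        i0 = int(round(onset * params.fs_hz))
        n = int(round(call.duration_s * params.fs_hz))
        n = min(n, n_total - i0)
        if n <= 0:
            continue
        amplitude = params.burst_amplitude * params.gain_for(call)
        if amplitude > 0:
            samples[i0 : i0 + n] += amplitude * _burst(
                n, params.fs_hz, params.burst_fc_hz, params.burst_bw_hz, params.ramp_s, rng
            )
    if n_overlap:
        logger.info("simulate_lfp: %d overlapping calls; bursts summed", n_overlap)
    return LFPTrace(bird_id=bird_id, samples=samples, fs_hz=params.fs_hz)


# ---------------------------------------------------------------------------
# Whole-experiment simulation


@dataclass
class ExperimentConfig:
    """Multi-day NB/B design feeding the full pipeline.

    ``reply_prob_by_treatment`` maps treatment -> the reply-probability
    table of :class:`VocalSimParams`; ``gain_by_treatment`` maps
    ``(treatment, call_type, emitter)`` (emitter ``"*"`` wildcard) to the
    evoked burst gain for the focal bird's trace.
    """

    base_rates: Mapping[str, Mapping[str, float]]
    focal_bird: str
    n_days_nb: int = 3
    n_days_b: int = 4
    session_length_s: float = 300.0
    reply_prob_by_treatment: Mapping[str, Mapping[tuple[str, str], float]] = field(
        default_factory=dict
    )
    gain_by_treatment: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    latency: LatencySpec = field(default_factory=LatencySpec)
    lfp: LFPSimParams = field(default_factory=LFPSimParams)
    seed: int = 0


@dataclass
class SimulatedDay:
    day_index: int
    treatment: str
    streams: list[EventStream]
    trace: LFPTrace


def simulate_experiment(config: ExperimentConfig) -> list[SimulatedDay]:
    """Simulate the full NB-then-B design in memory.

    Day ``0 .. n_days_nb-1`` are non-breeding; subsequent days breeding.
    The focal bird's trace contains bursts for every call it heard (all
    other birds' calls).  Deterministic for a fixed config seed.
    """
    days: list[SimulatedDay] = []
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_days_nb + config.n_days_b)
    for day in range(config.n_days_nb + config.n_days_b):
        treatment = "NB" if day < config.n_days_nb else "B"
        rng = np.random.default_rng(seeds[day])
        vocal = VocalSimParams(
            base_rates=config.base_rates,
            reply_prob=config.reply_prob_by_treatment.get(treatment, {}),
            latency=config.latency,
            session_length_s=config.session_length_s,
            day_index=day,
            treatment=treatment,
        )
        streams = simulate_vocal_session(vocal, rng=rng)
        heard = [
            e
            for s in streams
            if s.bird_id != config.focal_bird
            for e in s
        ]
        lfp = LFPSimParams(
            **{
                **{f: getattr(config.lfp, f) for f in (
                    "fs_hz", "noise_model", "noise_sigma", "burst_fc_hz", "burst_bw_hz",
                    "burst_amplitude", "ramp_s", "onset_jitter_s")},
                "gain": gain_table(config.gain_by_treatment),
            }
        )
        trace = simulate_lfp(heard, config.session_length_s, lfp,
                             bird_id=config.focal_bird, rng=rng)
        days.append(SimulatedDay(day, treatment, streams, trace))
    return days


def write_experiment(days: Sequence[SimulatedDay], config: ExperimentConfig,
                     out_dir: str | Path) -> None:
    """Write a simulated experiment to disk in the package's IO formats.

    Produces ``events.csv`` (all birds, all days), one ``trace_dayN.wav``
    per day, and ``manifest.json`` recording the true parameters for
    recovery tests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_events([s for d in days for s in d.streams], out / "events.csv")
    for d in days:
        write_trace(d.trace, out / f"trace_day{d.day_index}.wav", dtype="float32")
    manifest = {
        "focal_bird": config.focal_bird,
        "n_days_nb": config.n_days_nb,
        "n_days_b": config.n_days_b,
        "session_length_s": config.session_length_s,
        "seed": config.seed,
        "fs_hz": config.lfp.fs_hz,
        "burst_fc_hz": config.lfp.burst_fc_hz,
        "burst_bw_hz": config.lfp.burst_bw_hz,
        "burst_amplitude": config.lfp.burst_amplitude,
        "noise_sigma": config.lfp.noise_sigma,
        "gain_by_treatment": {"|".join(k): v for k, v in config.gain_by_treatment.items()},
        "reply_prob_by_treatment": {
            t: {"|".join(k): v for k, v in table.items()}
            for t, table in config.reply_prob_by_treatment.items()
        },
        "latency": {
            "family": config.latency.family,
            "low_s": config.latency.low_s,
            "high_s": config.latency.high_s,
            "scale_s": config.latency.scale_s,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
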