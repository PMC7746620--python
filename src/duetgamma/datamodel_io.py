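"""Domain types and file IO for call-event tables, LFP traces and configs.

Conventions used across the whole package:

- All times are session-relative seconds (floats); events and traces share
  one clock and are assumed pre-aligned.
- Intervals are half-open ``[start, end)``; answer windows are
  onset-exclusive ``(onset, onset + w]`` (see :mod:`vocal_interactions`).
- Event tables are comma-separated UTF-8 CSV with a header row and '.'
  decimals.  Traces are mono WAV.  Configs are YAML.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

logger = logging.getLogger(__name__)

#: Call repertoire: contact calls (stack, tet, distance), breeding calls
#: (kackle, whine), hat calls, song (males only) and non-vocal noise.
REPERTOIRE = ("stack", "tet", "distance", "kackle", "whine", "hat", "song", "noise")

#: Contact and breeding call groupings used by tallies and reports.
CONTACT_CALLS = ("stack", "tet", "distance")
BREEDING_CALLS = ("kackle", "whine")

TREATMENTS = ("NB", "B")

EVENT_COLUMNS = ("emitter_id", "call_type", "onset_s", "duration_s", "day_index", "treatment")
SCHEDULE_COLUMNS = ("stimulus_label", "emitter_id", "onset_s", "duration_s")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """A value violates a domain-type invariant."""


@dataclass(frozen=True)
class CallEvent:
    """One vocalization: who called, what, when and for how long."""

    emitter_id: str
    call_type: str
    onset_s: float
    duration_s: float
    day_index: int
    treatment: str

    def __post_init__(self) -> None:
        if self.call_type not in REPERTOIRE:
            raise ValidationError(
                f"unknown call_type {self.call_type!r}; expected one of {REPERTOIRE}"
            )
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        if not math.isfinite(self.onset_s) or self.onset_s < 0:
            raise ValidationError(f"onset_s must be finite and >= 0, got {self.onset_s}")
        if not math.isfinite(self.duration_s) or self.duration_s <= 0:
            raise ValidationError(f"duration_s must be finite and > 0, got {self.duration_s}")

    @property
    def offset_s(self) -> float:
        """End of the call on the session clock (half-open)."""
        return self.onset_s + self.duration_s


@dataclass
class EventStream:
    """All calls of one bird in one session (day), sorted by onset."""

    bird_id: str
    events: list[CallEvent]
    day_index: int
    treatment: str
    session_length_s: float | None = None

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError(f"events of bird {self.bird_id!r} are not sorted by onset")
        for e in self.events:
            if e.day_index != self.day_index or e.treatment != self.treatment:
                raise ValidationError(
                    f"event {e} disagrees with stream day/treatment "
                    f"({self.day_index}, {self.treatment})"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def onsets(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events], dtype=float)


@dataclass(frozen=True)
class InteractionConfig:
    """Windowing parameters for turn-taking and context analysis.

    ``answer_window_s``
        A call is an answer if its onset falls within this window after a
        reference call's onset (default 0.5 s).
    ``peri_window_s`` / ``bin_width_s``
        Extent and resolution of the optional peri-event histogram
        (default ±4 s, 50 ms bins).
    ``isolation_gap_s``
        A call is "isolated" if no other sound occurs this close before or
        after it (default 5 s).
    """

    answer_window_s: float = 0.5
    peri_window_s: float = 4.0
    bin_width_s: float = 0.05
    isolation_gap_s: float = 5.0

    def __post_init__(self) -> None:
        for name in ("answer_window_s", "peri_window_s", "bin_width_s", "isolation_gap_s"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValidationError(f"{name} must be strictly positive, got {value!r}")
        if self.answer_window_s > self.peri_window_s:
            raise ValidationError(
                f"answer_window_s ({self.answer_window_s}) must not exceed "
                f"peri_window_s ({self.peri_window_s})"
            )


@dataclass
class LFPTrace:
    """Uniformly sampled neural signal on the session clock."""

    bird_id: str
    samples: np.ndarray
    fs_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError(f"samples must be 1-D, got shape {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")
        if self.fs_hz <= 0:
            raise ValidationError(f"fs_hz must be > 0, got {self.fs_hz}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    def time_to_index(self, t_s: float) -> int:
        """Nearest-sample index of session time ``t_s``."""
        return int(round((t_s - self.t0_s) * self.fs_hz))


@dataclass(frozen=True)
class ReplyStrengthResult:
    """Counts and score for one (focal, partner, call-pair) interaction.

    ``rs`` is ``(n_response - n_baseline) / (n_response + n_baseline)``,
    or ``None`` when both counts are zero (undefined, never NaN).
    """

    n_response: int
    n_baseline: int
    n_reference_calls: int

    @property
    def rs(self) -> float | None:
        total = self.n_response + self.n_baseline
        if total == 0:
            return None
        return (self.n_response - self.n_baseline) / total


# ---------------------------------------------------------------------------
# Event-table IO


def read_events(path: str | Path) -> list[EventStream]:
    """Read a call-event CSV into one :class:`EventStream` per (bird, day).

    Unsorted rows are sorted silently (with a log notice); invalid values
    raise :class:`ValidationError`; missing columns raise
    :class:`FormatError`.
    """
    frame = pd.read_csv(
        path,
        dtype={"emitter_id": str, "call_type": str, "treatment": str},
        float_precision="round_trip",
    )
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return events_from_frame(frame, source=str(path))


def events_from_frame(frame: pd.DataFrame, source: str = "<frame>") -> list[EventStream]:
    """Build streams from an in-memory event table (same contract as CSV)."""
    streams: list[EventStream] = []
    if len(frame) == 0:
        return streams
    for (bird, day), group in frame.groupby(["emitter_id", "day_index"], sort=True):
        if not group["onset_s"].is_monotonic_increasing:
            logger.info("%s: events of bird %s day %s unsorted; sorting", source, bird, day)
            group = group.sort_values("onset_s", kind="stable")
        treatments = group["treatment"].unique()
        if len(treatments) > 1:
            raise ValidationError(
                f"{source}: bird {bird} day {day} mixes treatments {sorted(treatments)}"
            )
        events = [
            CallEvent(
                emitter_id=str(row.emitter_id),
                call_type=str(row.call_type),
                onset_s=float(row.onset_s),
                duration_s=float(row.duration_s),
                day_index=int(row.day_index),
                treatment=str(row.treatment),
            )
            for row in group.itertuples()
        ]
        streams.append(
            EventStream(
                bird_id=str(bird),
                events=events,
                day_index=int(day),
                treatment=str(treatments[0]),
            )
        )
    return streams


def events_to_frame(streams: Iterable[EventStream]) -> pd.DataFrame:
    rows = [
        {
            "emitter_id": e.emitter_id,
            "call_type": e.call_type,
            "onset_s": e.onset_s,
            "duration_s": e.duration_s,
            "day_index": e.day_index,
            "treatment": e.treatment,
        }
        for stream in streams
        for e in stream
    ]
    frame = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    return frame.sort_values(["emitter_id", "day_index", "onset_s"], kind="stable").reset_index(
        drop=True
    )


def write_events(streams: Iterable[EventStream], path: str | Path) -> None:
    """Write streams to CSV in canonical (bird, day, onset) order."""
    events_to_frame(streams).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trace IO (mono WAV; integer PCM scaled to [-1, 1])

_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31, np.dtype(np.uint8): 2**7}


def read_trace(path: str | Path, bird_id: str | None = None, t0_s: float = 0.0) -> LFPTrace:
    """Read a single-channel WAV file as an :class:`LFPTrace`.

    Integer PCM samples are scaled to [-1, 1]; float files pass through.
    Multi-channel files are rejected.
    """
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise FormatError(f"{path}: expected mono WAV, got {data.shape[1]} channels")
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        if data.dtype == np.dtype(np.uint8):  # unsigned 8-bit is offset binary
            samples = (data.astype(float) - 128.0) / scale
        else:
            samples = data.astype(float) / scale
    else:
        samples = data.astype(float)
    if bird_id is None:
        bird_id = Path(path).stem
    return LFPTrace(bird_id=bird_id, samples=samples, fs_hz=float(fs), t0_s=t0_s)


def write_trace(trace: LFPTrace, path: str | Path, dtype: str = "float32") -> None:
    """Write a trace as mono WAV (``float32``, ``float64`` or ``int16``)."""
    if dtype == "int16":
        clipped = np.clip(trace.samples, -1.0, 1.0 - 1.0 / 2**15)
        data = np.round(clipped * 2**15).astype(np.int16)
    elif dtype in ("float32", "float64"):
        data = trace.samples.astype(dtype)
    else:
        raise ValueError(f"unsupported WAV dtype {dtype!r}")
    wavfile.write(path, int(round(trace.fs_hz)), data)


# ---------------------------------------------------------------------------
# Schedule IO


def read_schedule(path: str | Path) -> pd.DataFrame:
    """Read a playback schedule CSV (stimulus_label, emitter_id, onset_s, duration_s)."""
    frame = pd.read_csv(
        path, dtype={"stimulus_label": str, "emitter_id": str}, float_precision="round_trip"
    )
    missing = [c for c in SCHEDULE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if (frame["duration_s"] <= 0).any():
        raise ValidationError(f"{path}: schedule durations must be > 0")
    if not frame["onset_s"].is_monotonic_increasing:
        logger.info("%s: schedule unsorted; sorting by onset", path)
        frame = frame.sort_values("onset_s", kind="stable").reset_index(drop=True)
    return frame


def write_schedule(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, columns=list(SCHEDULE_COLUMNS), index=False)


# ---------------------------------------------------------------------------
# Config IO

_CONFIG_KEYS = ("answer_window_s", "peri_window_s", "bin_width_s", "isolation_gap_s")


def read_config(path: str | Path) -> InteractionConfig:
    """Load an :class:`InteractionConfig` from YAML, applying defaults.

    Unknown keys are rejected with a message listing them.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: expected a mapping at top level, got {type(raw).__name__}")
    unknown = sorted(set(raw) - set(_CONFIG_KEYS))
    if unknown:
        raise FormatError(f"{path}: unknown config keys {unknown}; allowed: {list(_CONFIG_KEYS)}")
    try:
        return InteractionConfig(**raw)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_config(cfg: InteractionConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: getattr(cfg, k) for k in _CONFIG_KEYS}, fh, sort_keys=False)
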