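"""Night-playback experiment support.

Stimuli (the repertoire of call types plus a 100 ms white-noise internal
control) are peak-normalized to -5 dB, presented 30 times each in a
pseudorandomized order — implemented as a constrained shuffle with no two
consecutive presentations of the same stimulus — and each presentation is
scored with the same ARS machinery as daytime calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from duetgamma.datamodel_io import CallEvent, LFPTrace, ValidationError
from duetgamma.lfp_ars import FilterBank, ARSRecord, compute_ars, LOW_GAMMA_LABELS

logger = logging.getLogger(__name__)

EMITTER_CATEGORIES = (
    "mate", "familiar_single_male", "unfamiliar_male", "own", "unfamiliar_female", "control",
)

WHITE_NOISE_DURATION_S = 0.1


@dataclass
class Stimulus:
    """One playback stimulus: a labeled waveform from a known emitter."""

    label: str  # call type or "white_noise"
    emitter: str = "control"
    duration_s: float = WHITE_NOISE_DURATION_S
    waveform: np.ndarray | None = None
    fs_hz: float | None = None

    def __post_init__(self) -> None:
        if self.emitter not in EMITTER_CATEGORIES:
            raise ValidationError(
                f"unknown emitter category {self.emitter!r}; expected one of {EMITTER_CATEGORIES}"
            )
        if self.duration_s <= 0:
            raise ValidationError("stimulus duration must be > 0")

    @property
    def key(self) -> tuple[str, str]:
        return (self.label, self.emitter)


def normalize_peak(waveform: np.ndarray, target_db: float = -5.0) -> np.ndarray:
    """Scale a waveform so its peak |sample| is ``10^(target_db/20)``.

    Shape-preserving (a pure rescale); an all-zero waveform is an error.
    """
    waveform = np.asarray(waveform, dtype=float)
    peak = np.max(np.abs(waveform))
    if peak == 0:
        raise ValidationError("cannot peak-normalize an all-zero waveform")
    return waveform * (10.0 ** (target_db / 20.0) / peak)


@dataclass
class PlaybackSchedule:
    """Ordered presentations of a stimulus set."""

    presentations: pd.DataFrame  # stimulus_label, emitter_id, onset_s, duration_s
    repetitions: int
    seed: int | None = None

    def counts(self) -> pd.Series:
        return self.presentations.groupby(["stimulus_label", "emitter_id"]).size()


def _constrained_order(
    labels: Sequence[int], repetitions: int, rng: np.random.Generator
) -> list[int]:
    """Random order of ``labels * repetitions`` with no immediate repeats.

    Sequential sampling: at each step a stimulus is forced if its
    remaining count exceeds half the remaining slots (otherwise the
    constraint would become infeasible); else drawn uniformly among the
    allowed ones.  Succeeds whenever a valid order exists.
    """
    remaining = {s: repetitions for s in labels}
    order: list[int] = []
    last: int | None = None
    n_left = repetitions * len(labels)
    while n_left:
        # the last-placed stimulus can fill at most every other remaining slot
        if last is not None and remaining[last] > n_left // 2:
            raise ValidationError(
                "pseudorandomization infeasible: one stimulus dominates the remainder"
            )
        # a stimulus holding at least ceil(n_left/2) of the slots must go now
        forced = [
            s for s, c in remaining.items() if s != last and c >= (n_left + 1) // 2
        ]
        if forced:
            choice = forced[int(rng.integers(len(forced)))]
        else:
            allowed = [s for s, c in remaining.items() if c > 0 and s != last]
            if not allowed:
                raise ValidationError("pseudorandomization infeasible")
            choice = allowed[int(rng.integers(len(allowed)))]
        order.append(choice)
        remaining[choice] -= 1
        last = choice
        n_left -= 1
    return order


def build_schedule(
    stimuli: Sequence[Stimulus],
    repetitions: int = 30,
    gap_s: tuple[float, float] = (8.0, 12.0),
    seed: int | None = None,
    start_s: float = 10.0,
) -> PlaybackSchedule:
    """Build a pseudorandomized schedule: every stimulus exactly
    ``repetitions`` times, no two consecutive presentations of the same
    stimulus, inter-trial gaps uniform on ``gap_s``.

    Deterministic for a fixed seed.  An infeasible constraint (e.g. a
    single stimulus) is an error.
    """
    if len(stimuli) < 2:
        raise ValidationError("need at least 2 stimuli for a pseudorandomized schedule")
    keys = [s.key for s in stimuli]
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate (label, emitter) stimuli in the set")
    if repetitions < 1:
        raise ValidationError("repetitions must be >= 1")
    if not (0 < gap_s[0] <= gap_s[1]):
        raise ValidationError("gap bounds must satisfy 0 < low <= high")
    rng = np.random.default_rng(seed)
    order = _constrained_order(range(len(stimuli)), repetitions, rng)
    rows = []
    t = start_s
    for idx in order:
        stim = stimuli[idx]
        rows.append(
            {"stimulus_label": stim.label, "emitter_id": stim.emitter,
             "onset_s": t, "duration_s": stim.duration_s}
        )
        t += stim.duration_s + rng.uniform(*gap_s)
    return PlaybackSchedule(
        presentations=pd.DataFrame(rows), repetitions=repetitions, seed=seed
    )


def schedule_to_events(
    schedule: pd.DataFrame, day_index: int = 0, treatment: str = "NB"
) -> list[CallEvent]:
    """Treat each presentation as a heard call for the ARS machinery.

    The ``white_noise`` control maps to the repertoire's ``noise`` type;
    the original stimulus label is recoverable from the emitter pairing
    in the returned scoring table, which carries labels verbatim.
    """
    events = []
    for row in schedule.itertuples():
        call_type = "noise" if row.stimulus_label == "white_noise" else row.stimulus_label
        events.append(
            CallEvent(
                emitter_id=str(row.emitter_id),
                call_type=call_type,
                onset_s=float(row.onset_s),
                duration_s=float(row.duration_s),
                day_index=day_index,
                treatment=treatment,
            )
        )
    return events


def score_playback(
    trace: LFPTrace,
    schedule: PlaybackSchedule | pd.DataFrame,
    bank: FilterBank,
    bands_of_interest: Sequence[int] = LOW_GAMMA_LABELS,
    day_index: int = 0,
    treatment: str = "NB",
) -> pd.DataFrame:
    """Per-presentation ARS in the bands of interest, plus repetition means.

    Returns a table with one row per (presentation, band) carrying
    ``ars`` and the per-(stimulus, emitter, band) mean over repetitions
    in ``mean_ars``.  Presentations too close to the trace edges are
    skipped (reported via the compute_ars log summary).
    """
    frame = schedule.presentations if isinstance(schedule, PlaybackSchedule) else schedule
    events = schedule_to_events(frame, day_index=day_index, treatment=treatment)
    boi = [b for b in bank.bands if b.label_hz in set(bands_of_interest)]
    if not boi:
        raise ValidationError(f"bands of interest {bands_of_interest} not in the bank")
    sub_bank = FilterBank(bands=boi, fs_hz=bank.fs_hz, order=bank.order)
    records = compute_ars(trace, events, sub_bank)

    label_by_key = {
        ("noise" if row.stimulus_label == "white_noise" else row.stimulus_label,
         float(row.onset_s)): row.stimulus_label
        for row in frame.itertuples()
    }
    rows = [
        {
            "bird_id": r.bird_id,
            "day_index": r.day_index,
            "treatment": r.treatment,
            "stimulus_label": label_by_key[(r.call_type, r.onset_s)],
            "emitter_id": r.emitter_id,
            "onset_s": r.onset_s,
            "band_hz": r.band_hz,
            "rms_baseline": r.rms_baseline,
            "rms_stimulus": r.rms_stimulus,
            "ars": r.ars,
        }
        for r in records
    ]
    table = pd.DataFrame(rows)
    if len(table):
        table["mean_ars"] = table.groupby(["stimulus_label", "emitter_id", "band_hz"])[
            "ars"
        ].transform("mean")
    return table
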