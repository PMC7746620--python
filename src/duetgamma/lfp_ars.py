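"""LFP Auditory Response Strength (ARS) scoring.

Pipeline, per heard call and per frequency band:

1. band-filter the whole trace with a 1st-order Butterworth band-pass
   (10-200 Hz in contiguous 10 Hz bands), applied forward-backward
   (zero-phase) so RMS windows align with call boundaries;
2. cut a stimulus fragment ``[onset, onset + duration)`` and an
   equal-length baseline fragment ``[onset - duration, onset)``;
3. compute the RMS of each fragment and score
   ``ars = rms_stimulus - rms_baseline``;
4. normalize ARS to [-1, 1] within each bird (divide by the bird's
   max |ars| over all records), and rank bands by the mean of
   ``log(ars^2)`` to select the band of interest.

Band labels are the lower band edge, so the low-gamma "bands 30, 40 and
50 Hz" span 30-60 Hz.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from duetgamma.datamodel_io import CallEvent, LFPTrace, ValidationError

logger = logging.getLogger(__name__)

#: |ars| below this floor is excluded from the log(x^2) transform.
LOG_EPS = 1e-12

#: The low-gamma band-of-interest labels reported by band selection on
#: burst-bearing data (spanning 30-60 Hz under the lower-edge labeling).
LOW_GAMMA_LABELS = (30, 40, 50)


class Band(NamedTuple):
    label_hz: int
    low_hz: float
    high_hz: float


@dataclass
class FilterBank:
    """Ordered contiguous Butterworth band-passes sharing one sample rate."""

    bands: list[Band]
    fs_hz: float
    order: int = 1
    _sos: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def sos(self, band: Band) -> np.ndarray:
        if band.label_hz not in self._sos:
            self._sos[band.label_hz] = signal.butter(
                self.order, [band.low_hz, band.high_hz], btype="bandpass",
                fs=self.fs_hz, output="sos",
            )
        return self._sos[band.label_hz]

    def labels(self) -> list[int]:
        return [b.label_hz for b in self.bands]


def design_filter_bank(
    fs_hz: float,
    low_hz: float = 10.0,
    high_hz: float = 200.0,
    width_hz: float = 10.0,
    order: int = 1,
) -> FilterBank:
    """Design the 10-200 Hz bank of 10 Hz-wide order-1 band-passes.

    Defaults give 19 bands labeled 10, 20, ..., 190 (lower edges).
    Raises if ``high_hz`` reaches the Nyquist frequency.
    """
    if fs_hz <= 2 * high_hz:
        raise ValidationError(
            f"sample rate {fs_hz} Hz too low: top band edge {high_hz} Hz "
            f">= Nyquist {fs_hz / 2} Hz"
        )
    n_bands = int(round((high_hz - low_hz) / width_hz))
    if n_bands < 1 or not math.isclose(low_hz + n_bands * width_hz, high_hz):
        raise ValidationError(
            f"band range {low_hz}-{high_hz} Hz is not a whole number of {width_hz} Hz bands"
        )
    bands = [
        Band(label_hz=int(round(low_hz + i * width_hz)),
             low_hz=low_hz + i * width_hz,
             high_hz=low_hz + (i + 1) * width_hz)
        for i in range(n_bands)
    ]
    return FilterBank(bands=bands, fs_hz=fs_hz, order=order)


def bandpass(
    trace: LFPTrace, band: Band, bank: FilterBank, zero_phase: bool = True
) -> np.ndarray:
    """Band-filter a whole trace; output length equals input length.

    Zero-phase (forward-backward) by default so that windowing on call
    boundaries is not skewed by group delay; set ``zero_phase=False`` for
    causal forward-only filtering.
    """
    if trace.fs_hz != bank.fs_hz:
        raise ValidationError(
            f"trace fs {trace.fs_hz} Hz does not match bank fs {bank.fs_hz} Hz"
        )
    sos = bank.sos(band)
    if zero_phase:
        return signal.sosfiltfilt(sos, trace.samples)
    return signal.sosfilt(sos, trace.samples)


class FragmentError(ValueError):
    """The call is too close to a trace edge to cut both fragments."""


def extract_fragments(trace: LFPTrace, call: CallEvent) -> tuple[np.ndarray, np.ndarray]:
    """Cut (baseline, stimulus) fragments for one call.

    Stimulus is ``[onset, onset + duration)``; baseline is the
    immediately preceding equal-length window ``[onset - duration,
    onset)``.  Both are guaranteed equal length by construction.  Raises
    :class:`FragmentError` when either window leaves the trace.
    """
    i_on = trace.time_to_index(call.onset_s)
    n = int(round(call.duration_s * trace.fs_hz))
    if n < 1:
        raise FragmentError(f"call duration {call.duration_s}s shorter than one sample")
    if i_on - n < 0:
        raise FragmentError(
            f"call at {call.onset_s:.3f}s: baseline window starts before the trace"
        )
    if i_on + n > len(trace.samples):
        raise FragmentError(f"call at {call.onset_s:.3f}s: stimulus window ends past the trace")
    return trace.samples[i_on - n : i_on], trace.samples[i_on : i_on + n]


def rms(segment: np.ndarray) -> float:
    """Root mean square, ``sqrt(mean(x^2))``; empty input is an error."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("rms of an empty segment is undefined")
    return float(np.sqrt(np.mean(segment**2)))


@dataclass
class ARSRecord:
    """ARS of one call in one band, with the call's metadata."""

    bird_id: str
    emitter_id: str
    call_type: str
    onset_s: float
    duration_s: float
    day_index: int
    treatment: str
    context: str
    band_hz: int
    rms_baseline: float
    rms_stimulus: float
    ars_normalized: float | None = None

    @property
    def ars(self) -> float:
        return self.rms_stimulus - self.rms_baseline


def compute_ars(
    trace: LFPTrace,
    calls: Sequence[CallEvent],
    bank: FilterBank,
    contexts: Sequence[str] | None = None,
    zero_phase: bool = True,
    strict_baseline: bool = False,
) -> list[ARSRecord]:
    """Score every (call, band) pair on one trace.

    Each band filters the full trace once, then windows per call (no
    per-fragment filtering, avoiding edge transients in short windows).
    Calls whose fragments leave the trace are skipped and counted in a
    log summary.  With ``strict_baseline=True``, calls whose baseline
    window overlaps another call are also skipped.
    """
    if contexts is not None and len(contexts) != len(calls):
        raise ValidationError("contexts must align one-to-one with calls")
    intervals = sorted((c.onset_s, c.offset_s) for c in calls)

    def baseline_contaminated(call: CallEvent) -> bool:
        lo, hi = call.onset_s - call.duration_s, call.onset_s
        return any(
            a < hi and b > lo and not (a == call.onset_s and b == call.offset_s)
            for a, b in intervals
        )

    usable: list[tuple[int, CallEvent]] = []
    n_skipped_edge = n_skipped_contaminated = 0
    for i, call in enumerate(calls):
        try:
            extract_fragments(trace, call)
        except FragmentError:
            n_skipped_edge += 1
            continue
        if strict_baseline and baseline_contaminated(call):
            n_skipped_contaminated += 1
            continue
        usable.append((i, call))
    if n_skipped_edge or n_skipped_contaminated:
        logger.info(
            "compute_ars: skipped %d calls at trace edges, %d with contaminated baselines",
            n_skipped_edge, n_skipped_contaminated,
        )

    records: list[ARSRecord] = []
    for band in bank.bands:
        filtered = bandpass(trace, band, bank, zero_phase=zero_phase)
        filtered_trace = LFPTrace(trace.bird_id, filtered, trace.fs_hz, trace.t0_s)
        for i, call in usable:
            base_seg, stim_seg = extract_fragments(filtered_trace, call)
            records.append(
                ARSRecord(
                    bird_id=trace.bird_id,
                    emitter_id=call.emitter_id,
                    call_type=call.call_type,
                    onset_s=call.onset_s,
                    duration_s=call.duration_s,
                    day_index=call.day_index,
                    treatment=call.treatment,
                    context=contexts[i] if contexts is not None else "other",
                    band_hz=band.label_hz,
                    rms_baseline=rms(base_seg),
                    rms_stimulus=rms(stim_seg),
                )
            )
    return records


def normalize_within_bird(records: Sequence[ARSRecord]) -> list[ARSRecord]:
    """Scale ARS to [-1, 1] within each bird (all days and bands pooled).

    Divides by the bird's max |ars|; birds whose records are all zero
    pass through as zeros.  Returns the same record objects with
    ``ars_normalized`` filled in.
    """
    by_bird: dict[str, list[ARSRecord]] = {}
    for r in records:
        by_bird.setdefault(r.bird_id, []).append(r)
    for bird_records in by_bird.values():
        peak = max(abs(r.ars) for r in bird_records)
        for r in bird_records:
            r.ars_normalized = r.ars / peak if peak > 0 else 0.0
    return list(records)


def log_squared(x: np.ndarray, eps: float = LOG_EPS) -> tuple[np.ndarray, int]:
    """``log(x^2)`` with an epsilon floor.

    Values with ``|x| < eps`` are excluded (they would be -inf); returns
    the transformed kept values and the number excluded.
    """
    x = np.asarray(x, dtype=float)
    keep = np.abs(x) >= eps
    return np.log(x[keep] ** 2), int((~keep).sum())


@dataclass(frozen=True)
class BandSelection:
    """Result of band-of-interest selection."""

    selected: tuple[int, ...]            # experiment-level band set (modal top-k)
    per_bird: dict[str, tuple[int, ...]]  # top-k per bird
    margin: float                         # score gap between rank k and k+1 (min over birds)
    dominant: bool                        # margin above tolerance


def select_band_of_interest(
    records: Sequence[ARSRecord], k: int = 3, margin_tol: float = 0.5
) -> BandSelection:
    """Select the ``k`` bands with the strongest response.

    Per bird, bands are ranked by the mean of ``log(ars^2)`` over that
    bird's records; the experiment-level set is the modal top-``k``
    across birds.  When the per-bird score gap between the k-th and
    (k+1)-th band falls below ``margin_tol`` (log units) the selection is
    flagged as having no dominant band.
    """
    frame = ars_to_frame(records)
    per_bird: dict[str, tuple[int, ...]] = {}
    min_margin = math.inf
    for bird, group in frame.groupby("bird_id"):
        scores = {}
        for band, band_group in group.groupby("band_hz"):
            values, _ = log_squared(band_group["ars"].to_numpy())
            scores[int(band)] = float(values.mean()) if len(values) else -math.inf
        if len(scores) < k:
            raise ValidationError(
                f"bird {bird}: need at least k={k} bands to select, got {len(scores)}"
            )
        ranked = sorted(scores, key=lambda b: scores[b], reverse=True)
        per_bird[str(bird)] = tuple(sorted(ranked[:k]))
        if len(ranked) > k:
            min_margin = min(min_margin, scores[ranked[k - 1]] - scores[ranked[k]])

    sets = list(per_bird.values())
    selected = max(set(sets), key=sets.count)
    dominant = min_margin >= margin_tol
    if not dominant:
        logger.warning(
            "select_band_of_interest: no dominant band (margin %.3g < tol %.3g)",
            min_margin, margin_tol,
        )
    return BandSelection(selected=selected, per_bird=per_bird,
                         margin=float(min_margin), dominant=dominant)


def ars_to_frame(records: Iterable[ARSRecord]) -> pd.DataFrame:
    """Flatten ARS records into the tabular form used by inference and IO."""
    return pd.DataFrame(
        [
            {
                "bird_id": r.bird_id,
                "day_index": r.day_index,
                "treatment": r.treatment,
                "emitter_id": r.emitter_id,
                "call_type": r.call_type,
                "context": r.context,
                "band_hz": r.band_hz,
                "rms_baseline": r.rms_baseline,
                "rms_stimulus": r.rms_stimulus,
                "ars": r.ars,
                "ars_normalized": r.ars_normalized,
            }
            for r in records
        ]
    )
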