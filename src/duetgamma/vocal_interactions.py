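"""Turn-taking metrics on call-event streams.

Answer convention: a call of bird A answers a reference call of bird B if
its onset falls in the half-open-at-the-left window
``(ref.onset, ref.onset + answer_window_s]`` — onset-exclusive,
end-inclusive.  Answers are defined on onsets only; durations are ignored
for answer detection.  Self-replies are excluded by construction.

The reply strength of a (focal type, partner type) interaction is

    rs = (Nresponse - Nbaseline) / (Nresponse + Nbaseline)

where Nresponse counts all focal calls within the answer window after
each partner reference onset and Nbaseline counts focal calls in the
equal window before it.  When a reference call draws several answers all
are counted in Nresponse, but only the first defines its latency.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from duetgamma.datamodel_io import (
    BREEDING_CALLS,
    REPERTOIRE,
    TREATMENTS,
    CallEvent,
    EventStream,
    InteractionConfig,
    ReplyStrengthResult,
    ValidationError,
)

logger = logging.getLogger(__name__)

CONTEXT_LABELS = ("isolated", "answer_by_focal", "answered_by_partner", "other")


@dataclass(frozen=True)
class AnswerLink:
    """A reference call and one call that answered it."""

    reference: CallEvent
    answer: CallEvent

    def __post_init__(self) -> None:
        if self.answer.emitter_id == self.reference.emitter_id:
            raise ValidationError("an answer must come from a different bird")
        if self.latency_s <= 0:
            raise ValidationError("answer latency must be strictly positive")

    @property
    def latency_s(self) -> float:
        return self.answer.onset_s - self.reference.onset_s


def find_answers(
    reference: EventStream, responder: EventStream, cfg: InteractionConfig
) -> list[AnswerLink]:
    """Link every responder call within the answer window of each reference call.

    Both streams must be sorted (enforced by :class:`EventStream`) and
    belong to distinct birds.  Runs in O(n log n) via binary search; the
    test suite checks equivalence against an all-pairs brute force.
    """
    if reference.bird_id == responder.bird_id:
        raise ValidationError("reference and responder streams must be distinct birds")
    onsets = [e.onset_s for e in responder.events]
    links: list[AnswerLink] = []
    w = cfg.answer_window_s
    for ref in reference.events:
        lo = bisect.bisect_right(onsets, ref.onset_s)
        hi = bisect.bisect_right(onsets, ref.onset_s + w)
        links.extend(AnswerLink(ref, responder.events[i]) for i in range(lo, hi))
    return links


def reply_strength(
    focal: EventStream,
    partner: EventStream,
    call_pair: tuple[str, str],
    cfg: InteractionConfig,
) -> ReplyStrengthResult:
    """Reply strength of the focal bird's ``focal_type`` calls toward the
    partner's ``partner_type`` calls.

    ``call_pair`` is ``(focal_type, partner_type)``.  Counts accumulate
    over every partner reference call of ``partner_type``: focal calls of
    ``focal_type`` with onset in ``(ref, ref + w]`` go into ``n_response``
    and those in ``[ref - w, ref)`` into ``n_baseline``.
    """
    focal_type, partner_type = call_pair
    for ct in call_pair:
        if ct not in REPERTOIRE:
            raise ValidationError(f"unknown call_type {ct!r}")
    if focal.bird_id == partner.bird_id:
        raise ValidationError("focal and partner streams must be distinct birds")
    focal_onsets = [e.onset_s for e in focal.events if e.call_type == focal_type]
    w = cfg.answer_window_s
    n_resp = n_base = n_ref = 0
    for ref in partner.events:
        if ref.call_type != partner_type:
            continue
        n_ref += 1
        t = ref.onset_s
        n_resp += bisect.bisect_right(focal_onsets, t + w) - bisect.bisect_right(focal_onsets, t)
        n_base += bisect.bisect_left(focal_onsets, t) - bisect.bisect_left(focal_onsets, t - w)
    return ReplyStrengthResult(n_response=n_resp, n_baseline=n_base, n_reference_calls=n_ref)


def first_answers(links: Iterable[AnswerLink]) -> list[AnswerLink]:
    """Keep only the earliest answer per reference call."""
    best: dict[tuple[str, float], AnswerLink] = {}
    for link in links:
        key = (link.reference.emitter_id, link.reference.onset_s)
        if key not in best or link.latency_s < best[key].latency_s:
            best[key] = link
    return sorted(best.values(), key=lambda l: l.reference.onset_s)


def reply_latency(links: Sequence[AnswerLink]) -> float | None:
    """Mean latency over references, using only each reference's first answer.

    Returns ``None`` for an empty link list (logged).
    """
    firsts = first_answers(links)
    if not firsts:
        logger.info("reply_latency: empty link group; latency undefined")
        return None
    return float(np.mean([l.latency_s for l in firsts]))


def classify_call_context(
    call: CallEvent,
    streams: Sequence[EventStream],
    cfg: InteractionConfig,
    focal_id: str,
) -> str:
    """Context label of a heard call, relative to the focal (implanted) bird.

    - ``isolated``: no other event of any bird overlaps
      ``(onset - gap, onset + duration + gap)``, gap = ``isolation_gap_s``.
    - ``answer_by_focal``: the focal bird emitted a call within
      ``(onset, onset + answer_window_s]``.
    - ``answered_by_partner``: the call itself answers a focal call (its
      onset lies within the answer window after a focal onset).
    - ``other``: everything else, including the focal bird's own calls.

    When both answer rules hold, ``answer_by_focal`` wins (documented
    convention; the labels feed the ARS records as a random factor).
    """
    gap = cfg.isolation_gap_s
    lo, hi = call.onset_s - gap, call.offset_s + gap
    isolated = True
    for stream in streams:
        for other in stream.events:
            if other is call or (
                other.emitter_id == call.emitter_id
                and other.onset_s == call.onset_s
                and other.call_type == call.call_type
            ):
                continue
            if other.onset_s < hi and other.offset_s > lo:  # open-interval overlap
                isolated = False
                break
        if not isolated:
            break
    if isolated:
        return "isolated"

    if call.emitter_id == focal_id:
        return "other"
    focal_onsets: list[float] = []
    for stream in streams:
        if stream.bird_id == focal_id:
            focal_onsets.extend(e.onset_s for e in stream.events)
    focal_onsets.sort()
    w = cfg.answer_window_s
    lo_i = bisect.bisect_right(focal_onsets, call.onset_s)
    hi_i = bisect.bisect_right(focal_onsets, call.onset_s + w)
    if hi_i > lo_i:
        return "answer_by_focal"
    lo_i = bisect.bisect_left(focal_onsets, call.onset_s - w)
    hi_i = bisect.bisect_left(focal_onsets, call.onset_s)
    if hi_i > lo_i:
        return "answered_by_partner"
    return "other"


def peri_event_histogram(
    reference: EventStream, responder: EventStream, cfg: InteractionConfig
) -> pd.DataFrame:
    """Peri-event counts of responder onsets around reference onsets.

    Bins span ``[-peri_window_s, +peri_window_s)`` with ``bin_width_s``
    resolution; returned as a table (bin_left_s, count).
    """
    edges = np.arange(-cfg.peri_window_s, cfg.peri_window_s + cfg.bin_width_s / 2,
                      cfg.bin_width_s)
    counts = np.zeros(len(edges) - 1, dtype=int)
    resp_onsets = np.array([e.onset_s for e in responder.events])
    for ref in reference.events:
        rel = resp_onsets - ref.onset_s
        counts += np.histogram(rel, bins=edges)[0]
    return pd.DataFrame({"bin_left_s": edges[:-1], "count": counts})


def daily_call_counts(stream: EventStream, pool_breeding: bool = False) -> pd.DataFrame:
    """Per-(day, treatment, call_type) counts for one stream.

    With ``pool_breeding=True`` an extra ``breeding`` row tallies kackle
    and whine calls together; the per-type rows still partition events
    exactly.
    """
    counts = {ct: 0 for ct in REPERTOIRE}
    for e in stream.events:
        counts[e.call_type] += 1
    rows = [
        {"day_index": stream.day_index, "treatment": stream.treatment,
         "call_type": ct, "count": n}
        for ct, n in counts.items()
    ]
    if pool_breeding:
        rows.append(
            {"day_index": stream.day_index, "treatment": stream.treatment,
             "call_type": "breeding", "count": sum(counts[ct] for ct in BREEDING_CALLS)}
        )
    return pd.DataFrame(rows, columns=["day_index", "treatment", "call_type", "count"])


def interaction_table(
    streams: Sequence[EventStream],
    cfg: InteractionConfig,
    call_pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per (day, dyad, interaction) turn-taking summary.

    For every ordered pair of same-day streams and every
    ``(focal_type, partner_type)`` pair, reports the number of answer
    links, mean reply latency of the focal answering the partner, the
    reply strength and the raw counts.  By default the symmetric
    interactions over the full repertoire plus the two asymmetric
    contact-call interactions (tet-stack, stack-tet) are computed.
    """
    if call_pairs is None:
        call_pairs = [(ct, ct) for ct in REPERTOIRE if ct != "noise"]
        call_pairs += [("tet", "stack"), ("stack", "tet")]
    by_day: dict[int, list[EventStream]] = {}
    for s in streams:
        by_day.setdefault(s.day_index, []).append(s)
    rows = []
    for day, day_streams in sorted(by_day.items()):
        for focal in day_streams:
            for partner in day_streams:
                if focal.bird_id == partner.bird_id:
                    continue
                links = find_answers(partner, focal, cfg)
                for focal_type, partner_type in call_pairs:
                    pair_links = [
                        l for l in links
                        if l.answer.call_type == focal_type
                        and l.reference.call_type == partner_type
                    ]
                    rs = reply_strength(focal, partner, (focal_type, partner_type), cfg)
                    rows.append(
                        {
                            "day_index": day,
                            "treatment": focal.treatment,
                            "focal": focal.bird_id,
                            "partner": partner.bird_id,
                            "interaction": f"{focal_type}-{partner_type}",
                            "n_links": len(pair_links),
                            "mean_latency_s": reply_latency(pair_links),
                            "n_response": rs.n_response,
                            "n_baseline": rs.n_baseline,
                            "rs": rs.rs,
                        }
                    )
    return pd.DataFrame(rows)
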