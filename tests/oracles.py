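"""Independent brute-force oracles used by the test suite.

These deliberately reimplement the windowed counting rules as O(n^2)
all-pairs scans over plain tuples, sharing no code with the package.
"""

from __future__ import annotations

import math


def brute_find_answers(
    ref_onsets: list[float], resp_onsets: list[float], window_s: float
) -> list[tuple[float, float]]:
    """All (ref_onset, resp_onset) pairs with resp in (ref, ref + w]."""
    pairs = []
    for r in ref_onsets:
        for a in resp_onsets:
            if r < a <= r + window_s:
                pairs.append((r, a))
    return pairs


def brute_reply_strength(
    focal_onsets: list[float], partner_onsets: list[float], window_s: float
) -> tuple[int, int, float | None]:
    """(n_response, n_baseline, rs) via explicit double loops.

    Response window (t, t + w]; baseline window [t - w, t).
    """
    n_resp = n_base = 0
    for t in partner_onsets:
        for a in focal_onsets:
            if t < a <= t + window_s:
                n_resp += 1
            if t - window_s <= a < t:
                n_base += 1
    total = n_resp + n_base
    rs = None if total == 0 else (n_resp - n_base) / total
    return n_resp, n_base, rs


def brute_context(
    call: tuple[str, float, float],
    all_events: list[tuple[str, float, float]],
    focal_id: str,
    window_s: float,
    gap_s: float,
) -> str:
    """Context label via exhaustive interval checks.

    ``call`` and events are (emitter, onset, duration) tuples; the call
    itself must be present in ``all_events`` exactly once.
    """
    emitter, onset, duration = call
    lo, hi = onset - gap_s, onset + duration + gap_s
    others = [e for e in all_events if e != call]
    assert len(others) == len(all_events) - 1
    if not any(on < hi and on + dur > lo for _, on, dur in others):
        return "isolated"
    if emitter == focal_id:
        return "other"
    focal_onsets = [on for em, on, _ in all_events if em == focal_id]
    if any(onset < f <= onset + window_s for f in focal_onsets):
        return "answer_by_focal"
    if any(f < onset <= f + window_s for f in focal_onsets):
        return "answered_by_partner"
    return "other"


def brute_rms(values) -> float:
    total = 0.0
    for v in values:
        total += float(v) * float(v)
    return math.sqrt(total / len(values))


def butterworth1_bandpass_gain(f_hz: float, low_hz: float, high_hz: float) -> float:
    """Analytic magnitude response of an analog 1st-order Butterworth band-pass.

    |H(jw)| = 1 / sqrt(1 + ((w^2 - w0^2) / (B w))^2) with w0^2 = wl*wh,
    B = wh - wl.  Used only to predict band-energy orderings; the digital
    bilinear filter matches this closely far below Nyquist.
    """
    w = 2 * math.pi * f_hz
    wl, wh = 2 * math.pi * low_hz, 2 * math.pi * high_hz
    w0sq = wl * wh
    bw = wh - wl
    x = (w * w - w0sq) / (bw * w)
    return 1.0 / math.sqrt(1.0 + x * x)
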