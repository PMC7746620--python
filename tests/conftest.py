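from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from duetgamma.datamodel_io import CallEvent, EventStream, InteractionConfig


@pytest.fixture
def cfg() -> InteractionConfig:
    return InteractionConfig()


def random_stream(
    rng: np.random.Generator,
    bird_id: str,
    n_events: int,
    session_length_s: float = 60.0,
    call_types: tuple[str, ...] = ("stack", "tet", "distance", "kackle"),
    day_index: int = 0,
    treatment: str = "NB",
) -> EventStream:
    onsets = np.sort(rng.uniform(0, session_length_s, size=n_events))
    events = [
        CallEvent(
            emitter_id=bird_id,
            call_type=str(rng.choice(call_types)),
            onset_s=float(t),
            duration_s=float(rng.uniform(0.05, 0.4)),
            day_index=day_index,
            treatment=treatment,
        )
        for t in onsets
    ]
    return EventStream(bird_id=bird_id, events=events, day_index=day_index,
                       treatment=treatment, session_length_s=session_length_s)


@pytest.fixture
def make_stream():
    return random_stream
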