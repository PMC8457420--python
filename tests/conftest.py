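from pathlib import Path

import numpy as np
import pytest

from serialseq import Event, EventCode, Session

FIXTURE_PATH = Path(__file__).parent / "data" / "fixture_session.tsv"

# Hand-simulated state-machine table for the 12-trial fixture session
# (block, classification, latency, duration, transition, n_presses, long_s1);
# None classification marks the return-to-start record, nan = undefined.
FIXTURE_EXPECTED = [
    ("FORCED", "CORRECT", 1.0, 4.0, 1.0, 8, False),
    ("FORCED", "BREAK_S1", 1.0, 0.4, np.nan, 2, False),
    ("FORCED", "BREAK_S2", 1.0, 2.5, 1.0, 5, False),
    ("FORCED", "CORRECT", 1.0, 4.0, 1.0, 8, False),
    ("SELF_PACED", "CORRECT", 0.0, 4.0, 1.0, 8, False),
    ("SELF_PACED", "CORRECT", 1.0, 3.6, 0.8, 9, True),
    ("SELF_PACED", "INCORRECT_START", 1.0, 0.4, np.nan, 2, False),
    ("SELF_PACED", "PREMATURE_SWITCH", 1.0, 1.5, 1.0, 3, False),
    ("SELF_PACED", "BREAK_S1", 1.0, 1.0, np.nan, 3, False),
    ("SELF_PACED", "BREAK_S2", 1.0, 3.8, 1.0, 8, False),
    ("SELF_PACED", None, np.nan, np.nan, np.nan, 0, False),  # return to start
    ("SELF_PACED", "CORRECT", 1.0, 3.8, 0.8, 8, False),
    ("SELF_PACED", "CORRECT", 1.0, 4.5, 1.0, 9, False),
]


@pytest.fixture
def fixture_path() -> Path:
    return FIXTURE_PATH


def make_self_paced_session(
    s1_times, s2_times, beam=0.0, mag=None, rewarded=False, extra_events=()
) -> Session:
    """Build a one-trial self-paced session from explicit press times."""
    events = [Event(0.0, EventCode.BLOCK_SELF_START), Event(beam, EventCode.BEAM_OUT)]
    for t in s1_times:
        events.append(Event(t, EventCode.LP1))
    for t in s2_times:
        events.append(Event(t, EventCode.LP2))
    last = max(list(s1_times) + list(s2_times) + [beam])
    if rewarded:
        events.append(Event(last + 0.3, EventCode.REWARD))
    if mag is None:
        mag = last + 1.0
    events.append(Event(mag, EventCode.MAG_IN))
    events.extend(extra_events)
    events.append(Event(mag + 2.0, EventCode.SESSION_END))
    return Session(events=events).sorted()
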