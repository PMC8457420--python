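"""Trial segmentation, error taxonomy and timing metrics.

The task is a two-lever serial-order sequence: at least four presses on
lever 1 (subsequence S1) followed by at least four presses on lever 2
(subsequence S2) earn a reward.  Forced blocks expose one lever at a time
(the box enforces the order); self-paced blocks expose both levers.  The
event stream is partitioned at magazine entries into trials and each trial
is classified as correct or as one of four error categories: incorrect
start, break in S1, premature switch, break in S2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .io import Event, EventCode, Protocol, Session

__all__ = [
    "Block",
    "Classification",
    "LightLabel",
    "SequenceTrial",
    "StructuralError",
    "parse_trials",
    "percent_correct",
    "trial_metrics",
    "label_opto",
    "trials_to_frame",
]


class StructuralError(ValueError):
    """Event stream violates the task structure (e.g. press outside a block)."""


class Block(str, Enum):
    FORCED = "FORCED"
    SELF_PACED = "SELF_PACED"


class Classification(str, Enum):
    CORRECT = "CORRECT"
    INCORRECT_START = "INCORRECT_START"
    BREAK_S1 = "BREAK_S1"
    PREMATURE_SWITCH = "PREMATURE_SWITCH"
    BREAK_S2 = "BREAK_S2"


class LightLabel(str, Enum):
    ON = "ON"
    OFF = "OFF"
    NONE = "NONE"


@dataclass
class SequenceTrial:
    """A parsed candidate sequence with classification and timing metrics."""

    block: Block
    start_time: float
    end_time: float
    beam_out_time: float            # last beam crossing before the first press (nan if none)
    magazine_time: float
    s1_press_times: list[float] = field(default_factory=list)
    s2_press_times: list[float] = field(default_factory=list)
    all_press_times: list[float] = field(default_factory=list)
    classification: Classification | None = None
    return_to_start: bool = False
    long_s1: bool = False
    latency: float = np.nan
    duration: float = np.nan
    transition: float = np.nan
    ipis: list[float] = field(default_factory=list)
    n_presses: int = 0
    light: LightLabel = LightLabel.NONE
    trigger_press_index: int | None = None


def _classify(block: Block, first_lever: EventCode, n1: int, n2: int) -> Classification:
    if block is Block.SELF_PACED:
        if first_lever is EventCode.LP2:
            return Classification.INCORRECT_START
        if n1 < 4 and n2 == 0:
            return Classification.BREAK_S1
        if n1 < 4:
            return Classification.PREMATURE_SWITCH
        if n2 >= 4:
            return Classification.CORRECT
        return Classification.BREAK_S2  # >=4 S1 presses, S2 abandoned at 0-3
    # forced: lever availability forbids wrong starts and premature switches
    if n1 < 4:
        return Classification.BREAK_S1
    if n2 >= 4:
        return Classification.CORRECT
    return Classification.BREAK_S2


def trial_metrics(trial: SequenceTrial) -> SequenceTrial:
    """Populate latency, duration, transition, IPIs and press counts in place."""
    s1, s2 = trial.s1_press_times, trial.s2_press_times
    presses = trial.all_press_times
    trial.n_presses = len(presses)
    if presses:
        trial.latency = (
            round(presses[0] - trial.beam_out_time, 10)
            if np.isfinite(trial.beam_out_time)
            else np.nan
        )
        last = s2[-1] if s2 else presses[-1]
        trial.duration = round(last - presses[0], 10)
    if s1 and s2:
        trial.transition = round(s2[0] - s1[-1], 10)
    else:
        trial.transition = np.nan  # flagged undefined: no S2 (or no S1) press
    ipis = [round(b - a, 10) for a, b in zip(s1, s1[1:])]
    ipis += [round(b - a, 10) for a, b in zip(s2, s2[1:])]
    trial.ipis = ipis
    return trial


def parse_trials(session: Session) -> list[SequenceTrial]:
    """Partition an event stream at magazine entries into classified trials.

    A trial opens at the first beam crossing (or press) after the previous
    magazine entry and closes at the next magazine entry.  A beam crossing
    followed by a magazine entry with zero presses yields a return-to-start
    record.  LP1 presses after the first LP2 press do not count toward S1.
    """
    trials: list[SequenceTrial] = []
    block: Block | None = None
    open_time: float | None = None
    beams: list[float] = []
    presses: list[tuple[float, EventCode]] = []

    def close(end_time: float) -> None:
        nonlocal open_time, beams, presses
        if open_time is None:
            return
        if not presses:
            if beams:
                t = SequenceTrial(
                    block=block,
                    start_time=open_time,
                    end_time=end_time,
                    beam_out_time=beams[-1],
                    magazine_time=end_time,
                    return_to_start=True,
                )
                trials.append(trial_metrics(t))
            open_time, beams, presses = None, [], []
            return
        first_lever = presses[0][1]
        first_lp2 = next((t for t, c in presses if c is EventCode.LP2), None)
        s1 = [t for t, c in presses if c is EventCode.LP1 and (first_lp2 is None or t < first_lp2)]
        s2 = [t for t, c in presses if c is EventCode.LP2]
        cls = _classify(block, first_lever, len(s1), len(s2))
        beam_before = [b for b in beams if b <= presses[0][0] + 1e-9]
        t = SequenceTrial(
            block=block,
            start_time=open_time,
            end_time=end_time,
            beam_out_time=beam_before[-1] if beam_before else np.nan,
            magazine_time=end_time,
            s1_press_times=s1,
            s2_press_times=s2,
            all_press_times=[t for t, _ in presses],
            classification=cls,
            long_s1=(cls is Classification.CORRECT and block is Block.SELF_PACED and len(s1) > 4),
        )
        trials.append(trial_metrics(t))
        open_time, beams, presses = None, [], []

    for e in session.events:
        if e.code is EventCode.BLOCK_FORCED_START:
            block = Block.FORCED
        elif e.code is EventCode.BLOCK_SELF_START:
            block = Block.SELF_PACED
        elif e.code is EventCode.BEAM_OUT:
            if open_time is None:
                open_time = e.time
            beams.append(e.time)
        elif e.code in (EventCode.LP1, EventCode.LP2):
            if block is None:
                raise StructuralError(f"press at {e.time} outside any block")
            if open_time is None:
                open_time = e.time
            presses.append((e.time, e.code))
        elif e.code is EventCode.MAG_IN:
            close(e.time)
        elif e.code is EventCode.SESSION_END:
            close(e.time)
    return trials


def percent_correct(trials: list[SequenceTrial], block: Block) -> float:
    """100 x correct / (correct + errors); return-to-start records excluded."""
    scored = [t for t in trials if t.block is block and not t.return_to_start]
    if not scored:
        raise ValueError(f"no classified trials in block {block.value}")
    n_correct = sum(t.classification is Classification.CORRECT for t in scored)
    return 100.0 * n_correct / len(scored)


def label_opto(trials: list[SequenceTrial], session: Session) -> list[SequenceTrial]:
    """Label trials ON/OFF from the session's light markers.

    A trial is ON when a LIGHT_ON falls inside its span.  Under the
    transition protocol the triggering press is recorded as its index
    counted from the end of S1 (the last S1 press is index 0, so the press
    before the penultimate press is -2).
    """
    if session.protocol is Protocol.NONE:
        return trials
    light_times = list(session.times(EventCode.LIGHT_ON))
    unattributed = set(range(len(light_times)))
    for t in trials:
        t.light = LightLabel.OFF
        for i, lt in enumerate(light_times):
            if t.start_time - 1e-9 <= lt <= t.end_time + 1e-9:
                t.light = LightLabel.ON
                unattributed.discard(i)
                if session.protocol is Protocol.TRANSITION and t.s1_press_times:
                    s1 = np.asarray(t.s1_press_times)
                    at_or_before = np.nonzero(s1 <= lt + 1e-9)[0]
                    if at_or_before.size:
                        t.trigger_press_index = int(at_or_before[-1]) - (len(s1) - 1)
                break
    if unattributed:
        warnings.warn(
            f"{len(unattributed)} LIGHT_ON events not attributable to any trial",
            stacklevel=2,
        )
    return trials


def trials_to_frame(
    trials: list[SequenceTrial],
    animal_id: str = "",
    group: str = "",
    protocol: str = "",
) -> pd.DataFrame:
    """One row per trial, the interchange format consumed by effect statistics."""
    rows = []
    for t in trials:
        rows.append(
            {
                "animal_id": animal_id,
                "group": group,
                "protocol": protocol,
                "block": t.block.value if t.block else "",
                "classification": t.classification.value if t.classification else "",
                "return_to_start": t.return_to_start,
                "long_s1": t.long_s1,
                "latency": t.latency,
                "duration": t.duration,
                "transition": t.transition,
                "n_presses": t.n_presses,
                "n_s1": len(t.s1_press_times),
                "n_s2": len(t.s2_press_times),
                "mean_ipi": float(np.mean(t.ipis)) if t.ipis else np.nan,
                "light": t.light.value,
                "trigger_press_index": t.trigger_press_index,
                "start_time": t.start_time,
                "end_time": t.end_time,
            }
        )
    return pd.DataFrame(rows)
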