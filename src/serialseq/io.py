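"""Event-log and spike-table I/O.

Behavioral sessions are plain tab-separated event logs: one row per
timestamped event (columns ``time_s``, ``code``, ``payload``) recorded at
10-ms resolution.  Session-level metadata (animal, group, day, optogenetic
protocol) travels in ``#``-prefixed header lines so that a single file fully
describes a session.  Spike times are a second TSV (``unit_id``, ``region``,
``time_s``) with an optional companion waveform table keyed by unit.

All timestamps are quantized to 0.01 s on read and write, and simultaneous
events are ordered by a fixed code priority so that parsing is deterministic
regardless of the row order of ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spikes import SpikeTrain

__all__ = [
    "EventCode",
    "Group",
    "Protocol",
    "Event",
    "Session",
    "EventLogError",
    "OrderingError",
    "quantize_time",
    "read_event_log",
    "write_event_log",
    "read_spike_table",
    "write_spike_table",
]

TIME_RESOLUTION = 0.01  # acquisition resolution, seconds


class EventLogError(ValueError):
    """Malformed event-log content (carries the offending line number)."""


class OrderingError(EventLogError):
    """Timestamps decrease by more than the 0.01-s resolution."""


class EventCode(str, Enum):
    BLOCK_FORCED_START = "BLOCK_FORCED_START"
    BLOCK_SELF_START = "BLOCK_SELF_START"
    BEAM_OUT = "BEAM_OUT"
    LP1 = "LP1"
    LP2 = "LP2"
    MAG_IN = "MAG_IN"
    REWARD = "REWARD"
    TIMEOUT_START = "TIMEOUT_START"
    LIGHT_ON = "LIGHT_ON"
    LIGHT_OFF = "LIGHT_OFF"
    SESSION_END = "SESSION_END"


# Canonical tie order for simultaneous events: block markers first, then the
# beam crossing, presses, magazine entry, reward, timeout and light markers.
CODE_PRIORITY = {
    EventCode.BLOCK_FORCED_START: 0,
    EventCode.BLOCK_SELF_START: 1,
    EventCode.BEAM_OUT: 2,
    EventCode.LP1: 3,
    EventCode.LP2: 4,
    EventCode.MAG_IN: 5,
    EventCode.REWARD: 6,
    EventCode.TIMEOUT_START: 7,
    EventCode.LIGHT_ON: 8,
    EventCode.LIGHT_OFF: 9,
    EventCode.SESSION_END: 10,
}


class Group(str, Enum):
    ARCH_M2 = "ARCH_M2"
    ARCH_M1 = "ARCH_M1"
    ARCH_LS = "ARCH_LS"
    EYFP_CONTROL = "EYFP_CONTROL"


class Protocol(str, Enum):
    NONE = "NONE"
    BEFORE = "BEFORE"
    EXECUTION = "EXECUTION"
    TRANSITION = "TRANSITION"


def quantize_time(t: float) -> float:
    """Quantize a time in seconds to the 10-ms acquisition grid."""
    return round(round(float(t) / TIME_RESOLUTION) * TIME_RESOLUTION, 2)


@dataclass(frozen=True)
class Event:
    """One timestamped behavioral or stimulation record."""

    time: float
    code: EventCode
    payload: dict | None = None

    def sort_key(self) -> tuple[int, int]:
        return (int(round(self.time / TIME_RESOLUTION)), CODE_PRIORITY[self.code])


@dataclass
class Session:
    """An ordered event stream plus the metadata identifying it."""

    animal_id: str = "unknown"
    group: Group = Group.EYFP_CONTROL
    day: int = 1
    protocol: Protocol = Protocol.NONE
    events: list[Event] = field(default_factory=list)

    def sorted(self) -> "Session":
        ev = sorted(self.events, key=Event.sort_key)
        return replace(self, events=ev)

    def times(self, code: EventCode) -> np.ndarray:
        return np.array([e.time for e in self.events if e.code is code])

    def validate(self) -> None:
        last = -np.inf
        for e in self.events:
            if e.time < last - 1e-9:
                raise OrderingError("session events are not time-ordered")
            last = e.time
        # light markers must strictly alternate ON/OFF
        state = EventCode.LIGHT_OFF
        for e in self.events:
            if e.code in (EventCode.LIGHT_ON, EventCode.LIGHT_OFF):
                if e.code is state:
                    raise EventLogError("LIGHT_ON/LIGHT_OFF do not alternate")
                state = e.code


_META_KEYS = ("animal_id", "group", "day", "protocol")


def _payload_to_str(payload: dict | None) -> str:
    if not payload:
        return ""
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def write_event_log(session: Session, path: str | Path) -> Path:
    """Write a session to TSV; ``read_event_log`` round-trips it bit-exactly."""
    path = Path(path)
    s = session.sorted()
    lines = []
    for key in _META_KEYS:
        value = getattr(s, key)
        value = value.value if isinstance(value, Enum) else value
        lines.append(f"# {key}\t{value}")
    lines.append("time_s\tcode\tpayload")
    for e in s.events:
        lines.append(f"{e.time:.2f}\t{e.code.value}\t{_payload_to_str(e.payload)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_event_log(path: str | Path) -> Session:
    """Parse an event-log TSV into a :class:`Session`.

    Raises :class:`EventLogError` naming the line number for malformed rows
    and :class:`OrderingError` when raw timestamps run backwards by more than
    the 0.01-s resolution.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    events: list[Event] = []
    header_seen = False
    running_max = -np.inf
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    meta[parts[0]] = parts[1]
                continue
            if not header_seen:
                if line.split("\t")[:2] != ["time_s", "code"]:
                    raise EventLogError(f"line {lineno}: expected header row")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) < 2 or len(parts) > 3:
                raise EventLogError(f"line {lineno}: expected 2-3 columns")
            try:
                t = float(parts[0])
            except ValueError as exc:
                raise EventLogError(f"line {lineno}: unparseable time {parts[0]!r}") from exc
            try:
                code = EventCode(parts[1])
            except ValueError as exc:
                raise EventLogError(f"line {lineno}: unknown code {parts[1]!r}") from exc
            payload = None
            if len(parts) == 3 and parts[2]:
                try:
                    payload = json.loads(parts[2])
                except json.JSONDecodeError as exc:
                    raise EventLogError(f"line {lineno}: bad payload JSON") from exc
            if t < running_max - TIME_RESOLUTION - 1e-9:
                raise OrderingError(
                    f"line {lineno}: timestamp {t} precedes {running_max} by more "
                    f"than {TIME_RESOLUTION} s"
                )
            running_max = max(running_max, t)
            events.append(Event(quantize_time(t), code, payload))
    session = Session(
        animal_id=meta.get("animal_id", "unknown"),
        group=Group(meta.get("group", "EYFP_CONTROL")),
        day=int(meta.get("day", 1)),
        protocol=Protocol(meta.get("protocol", "NONE")),
        events=events,
    )
    return session.sorted()


def write_spike_table(
    units: Iterable[SpikeTrain],
    path: str | Path,
    waveform_path: str | Path | None = None,
) -> Path:
    path = Path(path)
    rows = []
    wf_rows = []
    for u in units:
        for t in u.spike_times:
            rows.append((u.unit_id, u.region, float(t)))
        if u.mean_waveform_behavioral is not None:
            light = u.mean_waveform_light
            for i, v in enumerate(u.mean_waveform_behavioral):
                lv = float(light[i]) if light is not None else np.nan
                wf_rows.append((u.unit_id, i, float(v), lv))
    df = pd.DataFrame(rows, columns=["unit_id", "region", "time_s"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    if waveform_path is not None:
        wf = pd.DataFrame(
            wf_rows,
            columns=["unit_id", "sample_index", "behavioral_uv", "light_evoked_uv"],
        )
        wf.to_csv(waveform_path, sep="\t", index=False, float_format="%.6f")
    return path


def read_spike_table(
    path: str | Path,
    waveform_path: str | Path | None = None,
) -> list[SpikeTrain]:
    """Read one :class:`SpikeTrain` per ``unit_id``, spike times sorted."""
    df = pd.read_csv(path, sep="\t", dtype={"unit_id": str})
    required = {"unit_id", "region", "time_s"}
    if not required.issubset(df.columns):
        raise EventLogError(f"spike table missing columns {required - set(df.columns)}")
    if (df["time_s"] < 0).any():
        raise ValueError("negative spike time in spike table")
    waveforms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if waveform_path is not None:
        wf = pd.read_csv(waveform_path, sep="\t", dtype={"unit_id": str})
        for uid, g in wf.groupby("unit_id"):
            g = g.sort_values("sample_index")
            light = g["light_evoked_uv"].to_numpy(float)
            waveforms[uid] = (
                g["behavioral_uv"].to_numpy(float),
                light if not np.all(np.isnan(light)) else None,
            )
    units = []
    for uid, g in df.groupby("unit_id", sort=True):
        region = str(g["region"].iloc[0])
        times = np.sort(g["time_s"].to_numpy(float))
        wf_b, wf_l = waveforms.get(uid, (None, None))
        units.append(
            SpikeTrain(
                unit_id=uid,
                region=region,
                spike_times=times,
                mean_waveform_behavioral=wf_b,
                mean_waveform_light=wf_l,
            )
        )
    return units
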