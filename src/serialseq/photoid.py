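"""Antidromic photo-identification of cortico-striatal projection units.

A unit counts as a projection neuron when striatal light pulses evoke
antidromic spikes at short latency (median first-spike latency below
10 ms) whose mean waveform correlates above 0.9 with the unit's
behavioral mean waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spikes import SpikeTrain

__all__ = [
    "PidResult",
    "LATENCY_BOUND_S",
    "WAVEFORM_R_BOUND",
    "antidromic_latency",
    "waveform_correlation",
    "identify_pid",
]

LATENCY_BOUND_S = 0.010
WAVEFORM_R_BOUND = 0.9


@dataclass
class PidResult:
    unit_id: str
    median_latency: float       # s; nan when no pulse evoked a spike
    latency_sd: float
    waveform_r: float
    follow_fraction: float      # fraction of pulses with a spike in the window
    accepted: bool
    reason: str = ""


def antidromic_latency(
    spikes: SpikeTrain | np.ndarray,
    pulse_onsets: np.ndarray,
    window: tuple[float, float] = (0.0, LATENCY_BOUND_S),
) -> tuple[float, np.ndarray]:
    """Median first-spike latency over responding pulses.

    For each pulse the latency of the first spike inside the response
    window is taken; pulses without a spike contribute no entry.  Returns
    (median latency, per-pulse latencies); the median is nan when no pulse
    responds.
    """
    st = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    pulses = np.asarray(pulse_onsets, float)
    latencies = []
    for p in pulses:
        i = np.searchsorted(st, p + window[0])
        if i < st.size and st[i] < p + window[1]:
            latencies.append(st[i] - p)
    latencies = np.array(latencies)
    med = float(np.median(latencies)) if latencies.size else float("nan")
    return med, latencies


def waveform_correlation(behavioral_wf: np.ndarray, light_wf: np.ndarray) -> float:
    """Pearson correlation between the behavioral and light-evoked mean waveforms."""
    a = np.asarray(behavioral_wf, float)
    b = np.asarray(light_wf, float)
    if a.size != b.size or a.size < 8:
        raise ValueError("waveforms must share a length of at least 8 samples")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance waveform: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def identify_pid(
    unit: SpikeTrain,
    pulse_onsets: np.ndarray,
    latency_bound: float = LATENCY_BOUND_S,
    r_bound: float = WAVEFORM_R_BOUND,
) -> PidResult:
    """Apply both photo-identification criteria to one unit.

    Accepted iff the median antidromic latency is strictly below 10 ms and
    the waveform correlation strictly above 0.9.
    """
    pulses = np.asarray(pulse_onsets, float)
    med, lats = antidromic_latency(unit, pulses, window=(0.0, latency_bound))
    follow = lats.size / pulses.size if pulses.size else 0.0
    if lats.size == 0:
        return PidResult(unit.unit_id, float("nan"), float("nan"), float("nan"), 0.0, False, "no response")
    try:
        r = waveform_correlation(unit.mean_waveform_behavioral, unit.mean_waveform_light)
    except (ValueError, TypeError):
        return PidResult(unit.unit_id, med, float(lats.std()), float("nan"), follow, False, "waveform undefined")
    accepted = bool(med < latency_bound and r > r_bound)
    reason = "" if accepted else "criteria not met"
    return PidResult(unit.unit_id, med, float(lats.std()), r, follow, accepted, reason)
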