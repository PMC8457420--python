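"""Spike-train processing: rates, alignment, z-scoring, time rescaling.

Spike times are turned into instantaneous firing rate with a unit-area
Gaussian kernel (sigma = 25 ms) evaluated on a 100-Hz grid, aligned to
behavioral anchors, z-scored against a pre-trial baseline, and piecewise-
linearly rescaled so that the eight press anchors (first, second,
penultimate, last press of each subsequence) land on a common template.
The rescaled, trial-averaged z profile is then summarized into four task
epochs (pre-initiation, S1, transition, S2) and a modulation category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "RateTrace",
    "AlignedRates",
    "RescaledTrial",
    "ModulationCategory",
    "DegenerateBaselineError",
    "rate_from_spikes",
    "align_rates",
    "zscore_rows",
    "rescale_trial",
    "build_template",
    "epoch_mean_z",
    "categorize_unit",
]

RATE_DT = 0.01          # 100-Hz rate grid
KERNEL_SIGMA = 0.025    # seconds
KERNEL_HALF_WIDTH = 4   # truncate the Gaussian at +/- 4 sigma
SD_FLOOR_HZ = 0.1       # baseline-sd floor for z-scoring near-silent units


class DegenerateBaselineError(ValueError):
    """Baseline has zero variance even before the sd floor: unit excluded."""


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit, with optional waveforms and PID flag."""

    unit_id: str
    region: str
    spike_times: np.ndarray
    mean_waveform_behavioral: np.ndarray | None = None
    mean_waveform_light: np.ndarray | None = None
    pid: bool | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            self.spike_times = np.sort(self.spike_times)
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError("negative spike time")


@dataclass
class RateTrace:
    """Kernel-smoothed instantaneous firing rate on a regular grid (Hz)."""

    t0: float
    dt: float
    values: np.ndarray
    kernel_sigma: float = KERNEL_SIGMA

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.dt

    def integral(self) -> float:
        """Riemann integral of the trace; equals spike count with full support."""
        return float(self.values.sum() * self.dt)


@dataclass
class AlignedRates:
    """Trials x bins matrix of rate (Hz) or z-score on a shared bin grid."""

    unit_id: str
    anchor: str
    window: tuple[float, float]     # (pre, post), both positive seconds
    bin_times: np.ndarray           # bin centers relative to the anchor
    matrix: np.ndarray              # trials x bins
    units: str = "hz"               # "hz" or "z"
    n_dropped: int = 0
    baseline_mean: float | None = None
    baseline_sd: float | None = None
    sd_floored: bool = False


@dataclass
class RescaledTrial:
    """A rate trace interpolated onto the canonical sequence template."""

    times: np.ndarray               # template time axis (s)
    values: np.ndarray
    anchor_positions: np.ndarray    # indices of the 8 template anchors


class ModulationCategory(str, Enum):
    INIT_S1_EXECUTION = "Init & S1 execution"
    INIT_S1_S2 = "Init S1 & S2"
    TRANSITION_INIT_S2 = "Transition (init S2)"
    S2_EXECUTION = "S2 execution"
    S1_S2_EXECUTION = "S1 & S2 execution"
    NEGATIVE = "Negative"
    NONE = "None"


def rate_from_spikes(
    spikes: SpikeTrain | np.ndarray,
    span: tuple[float, float],
    dt: float = RATE_DT,
    sigma: float = KERNEL_SIGMA,
) -> RateTrace:
    """Gaussian-kernel instantaneous firing rate on a 100-Hz grid.

    Each spike contributes a Gaussian truncated at +/-4 sigma and
    renormalized to unit mass on the discrete grid, so the integral of the
    trace equals the spike count exactly whenever the kernel has full
    support inside ``span``.
    """
    times = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    t0, t1 = span
    n = int(np.floor((t1 - t0) / dt)) + 1
    values = np.zeros(n)
    if times.size == 0:
        return RateTrace(t0=t0, dt=dt, values=values, kernel_sigma=sigma)
    half = int(np.ceil(KERNEL_HALF_WIDTH * sigma / dt))
    offsets = np.arange(-half, half + 1)
    centers = np.round((times - t0) / dt).astype(int)
    cols = centers[:, None] + offsets[None, :]                    # spikes x K
    t_rel = t0 + cols * dt - times[:, None]
    w = np.exp(-0.5 * (t_rel / sigma) ** 2)
    w[np.abs(t_rel) > KERNEL_HALF_WIDTH * sigma + 1e-12] = 0.0
    w /= (w.sum(axis=1, keepdims=True) * dt)                      # unit mass per spike
    inside = (cols >= 0) & (cols < n)
    np.add.at(values, cols[inside], w[inside])
    return RateTrace(t0=t0, dt=dt, values=values, kernel_sigma=sigma)


def align_rates(
    trace: RateTrace,
    anchors: Sequence[float],
    window: tuple[float, float],
    unit_id: str = "",
    anchor_name: str = "",
) -> AlignedRates:
    """Cut one window per anchor out of a rate trace.

    Anchors whose window lacks full support within the trace are dropped and
    counted in ``n_dropped``.  Raises ``ValueError`` if no anchor survives.
    """
    pre, post = window
    n_bins = int(round((pre + post) / trace.dt)) + 1
    rel = -pre + np.arange(n_bins) * trace.dt
    rows = []
    dropped = 0
    for a in anchors:
        start = int(round((a - pre - trace.t0) / trace.dt))
        if start < 0 or start + n_bins > trace.values.size:
            dropped += 1
            continue
        rows.append(trace.values[start : start + n_bins])
    if not rows:
        raise ValueError("no anchor has full window support within the trace")
    return AlignedRates(
        unit_id=unit_id,
        anchor=anchor_name,
        window=window,
        bin_times=rel,
        matrix=np.array(rows),
        units="hz",
        n_dropped=dropped,
    )


def zscore_rows(aligned: AlignedRates, baseline: tuple[float, float]) -> AlignedRates:
    """z-score every bin against the pooled per-trial baseline bins.

    The mean and sd are pooled across all trials' baseline bins (a single
    normalization per unit).  A floor of 0.1 Hz is applied to the sd; units
    whose baseline is exactly constant are rejected as degenerate.
    """
    sel = (aligned.bin_times >= baseline[0] - 1e-9) & (aligned.bin_times <= baseline[1] + 1e-9)
    if not sel.any():
        raise ValueError("baseline window outside the alignment window")
    base = aligned.matrix[:, sel].ravel()
    m = float(base.mean())
    sd_raw = float(base.std(ddof=1)) if base.size > 1 else 0.0
    if sd_raw == 0.0:
        raise DegenerateBaselineError(
            f"unit {aligned.unit_id!r}: zero baseline variance, excluded from z analyses"
        )
    sd = max(sd_raw, SD_FLOOR_HZ)
    z = (aligned.matrix - m) / sd
    return AlignedRates(
        unit_id=aligned.unit_id,
        anchor=aligned.anchor,
        window=aligned.window,
        bin_times=aligned.bin_times,
        matrix=z,
        units="z",
        n_dropped=aligned.n_dropped,
        baseline_mean=m,
        baseline_sd=sd,
        sd_floored=sd_raw < SD_FLOOR_HZ,
    )


def _collapse_duplicates(
    trial_anchors: np.ndarray, template_anchors: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop anchors duplicated (zero-length segment) on either side.

    Returns deduplicated (trial, template) anchors plus, for each of the
    original anchors, the index of the deduplicated anchor it maps to.
    """
    keep = [0]
    mapping = [0]
    for i in range(1, trial_anchors.size):
        if (trial_anchors[i] - trial_anchors[keep[-1]] <= 1e-12) or (
            template_anchors[i] - template_anchors[keep[-1]] <= 1e-12
        ):
            mapping.append(len(keep) - 1)
        else:
            keep.append(i)
            mapping.append(len(keep) - 1)
    return trial_anchors[keep], template_anchors[keep], np.array(mapping)


def rescale_trial(
    trace: RateTrace,
    trial_anchor_times: Sequence[float],
    template_anchor_times: Sequence[float],
    pad_pre: float = 1.0,
    pad_post: float = 0.5,
    dt: float = RATE_DT,
) -> RescaledTrial:
    """Piecewise-linear time rescaling of a rate trace onto a template.

    Each inter-anchor segment is stretched or compressed linearly so that
    the trial's anchors land exactly on the template's anchors; the rate is
    linearly interpolated at the warped sample times, so anchor values are
    preserved exactly.  Regions before the first / after the last anchor are
    carried over un-warped (unit slope).  Non-monotonic anchors raise;
    anchors duplicated on either side are collapsed rather than creating a
    zero-length segment.
    """
    trial = np.asarray(trial_anchor_times, float)
    template = np.asarray(template_anchor_times, float)
    if trial.size != template.size:
        raise ValueError("trial and template anchor lists differ in length")
    if np.any(np.diff(trial) < -1e-12) or np.any(np.diff(template) < -1e-12):
        raise ValueError("anchor times must be non-decreasing")
    trial_d, template_d, mapping = _collapse_duplicates(trial, template)

    # template grid: per-segment linspace so each anchor is an exact sample
    pieces = [template_d[0] - pad_pre + np.arange(int(round(pad_pre / dt))) * dt]
    anchor_pos_d = [int(round(pad_pre / dt))]
    for k in range(trial_d.size - 1):
        seg = template_d[k + 1] - template_d[k]
        n = max(1, int(round(seg / dt)))
        pieces.append(np.linspace(template_d[k], template_d[k + 1], n + 1)[:-1])
        anchor_pos_d.append(anchor_pos_d[-1] + n)
    pieces.append(template_d[-1] + np.arange(int(round(pad_post / dt)) + 1) * dt)
    t_template = np.concatenate(pieces)

    # warp template times back to trial times (exact at the anchors), with
    # unit-slope extension outside the anchored span
    mapped = np.interp(t_template, template_d, trial_d)
    before = t_template < template_d[0]
    after = t_template > template_d[-1]
    mapped[before] = trial_d[0] + (t_template[before] - template_d[0])
    mapped[after] = trial_d[-1] + (t_template[after] - template_d[-1])

    values = np.interp(mapped, trace.times, trace.values)
    positions = np.array([anchor_pos_d[m] for m in mapping])
    return RescaledTrial(times=t_template, values=values, anchor_positions=positions)


def build_template(
    ipis: Sequence[float] | np.ndarray,
    transitions: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Eight template anchor times from pooled mean IPI and transition.

    Within-subsequence template gaps use the pooled mean inter-press
    interval; the S1->S2 gap uses the pooled mean transition time.
    """
    ipi = float(np.mean(np.asarray(ipis, float)))
    tr = float(np.mean(np.asarray(transitions, float)))
    s1 = np.array([0.0, ipi, 2 * ipi, 3 * ipi])
    s2 = s1[-1] + tr + np.array([0.0, ipi, 2 * ipi, 3 * ipi])
    return np.concatenate([s1, s2])


def trial_anchors(s1_press_times: Sequence[float], s2_press_times: Sequence[float]) -> np.ndarray:
    """First, second, penultimate and last press of each subsequence."""
    s1 = np.asarray(s1_press_times, float)
    s2 = np.asarray(s2_press_times, float)
    if s1.size < 4 or s2.size < 4:
        raise ValueError("rescaling requires at least four presses per subsequence")
    return np.array([s1[0], s1[1], s1[-2], s1[-1], s2[0], s2[1], s2[-2], s2[-1]])


def epoch_mean_z(
    rescaled_mean: np.ndarray,
    times: np.ndarray,
    anchor_positions: np.ndarray,
    pre_initiation_span: float = 1.0,
) -> dict[str, float]:
    """Mean z per task epoch on the rescaled template.

    Epochs: pre-initiation (the second before the first S1 press), S1
    (first to last S1 press), transition (last S1 to first S2 press) and S2
    (first to last S2 press).
    """
    p1_s1, plast_s1 = anchor_positions[0], anchor_positions[3]
    p1_s2, plast_s2 = anchor_positions[4], anchor_positions[7]
    t = times
    init_sel = (t >= t[p1_s1] - pre_initiation_span - 1e-9) & (t < t[p1_s1])
    return {
        "init": float(rescaled_mean[init_sel].mean()),
        "s1": float(rescaled_mean[p1_s1 : plast_s1 + 1].mean()),
        "transition": float(rescaled_mean[plast_s1 : p1_s2 + 1].mean()),
        "s2": float(rescaled_mean[p1_s2 : plast_s2 + 1].mean()),
    }


def categorize_unit(
    epoch_z: dict[str, float] | Sequence[float],
    threshold: float = 2.0,
) -> ModulationCategory:
    """Assign a modulation category from the per-epoch mean z pattern.

    An epoch counts as modulated when ``|mean z| >= threshold``.  Positive
    exceedances determine the label; if only negative exceedances exist the
    unit is Negative, and with none it is None.  Precedence: pre-initiation
    plus transition reads as engagement at the start of both subsequences;
    otherwise pre-initiation implies the initiation/S1 label, then joint
    S1+S2 execution, then transition, then S2-only, with an S1-only pattern
    folded into the initiation/S1 label.
    """
    if isinstance(epoch_z, dict):
        z = np.array([epoch_z["init"], epoch_z["s1"], epoch_z["transition"], epoch_z["s2"]])
    else:
        z = np.asarray(epoch_z, float)
    pos = z >= threshold
    neg = z <= -threshold
    init, s1, tr, s2 = pos
    if not pos.any():
        return ModulationCategory.NEGATIVE if neg.any() else ModulationCategory.NONE
    if init and tr:
        return ModulationCategory.INIT_S1_S2
    if init:
        return ModulationCategory.INIT_S1_EXECUTION
    if s1 and s2:
        return ModulationCategory.S1_S2_EXECUTION
    if tr:
        return ModulationCategory.TRANSITION_INIT_S2
    if s2:
        return ModulationCategory.S2_EXECUTION
    return ModulationCategory.INIT_S1_EXECUTION  # S1-only pattern
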