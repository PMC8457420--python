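"""Synthetic sessions and spike trains with known ground truth.

The session generator walks the task state machine: alternating forced and
self-paced blocks that switch after five consecutive correct sequences,
10-s timeouts after errors, session end at a target reward count, and
optional state-dependent light delivery (2-s pulses on a random 50% of
trials, triggered at the beam crossing, the first press, or the press
before the penultimate S1 press depending on the protocol).  Error
probabilities, timing distributions and light effects are explicit model
parameters, so every downstream statistic can be checked against the
programmed ground truth.

Spike trains are drawn from an inhomogeneous Poisson process by thinning,
with intensity = baseline + event-locked kernels + a per-trial term
proportional to the sequence duration (for regression recovery).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .behavior import Block, Classification, parse_trials
from .io import Event, EventCode, Group, Protocol, Session, quantize_time
from .spikes import SpikeTrain

__all__ = [
    "ConfigurationError",
    "PerformerModel",
    "EventKernel",
    "ModulationSpec",
    "PidSpec",
    "simulate_session",
    "simulate_unit",
    "expected_spike_count",
    "simulate_photoid",
    "pulse_train_times",
    "simulate_opto_cohort",
]

LIGHT_DURATION = 2.0    # seconds of continuous light per stimulation trial
STIM_FRACTION = 0.5     # Bernoulli probability that a trial is a stimulation trial
TIMEOUT_S = 10.0
PRESS_FLOOR = 0.05      # hard floor for any generated interval, seconds


class ConfigurationError(ValueError):
    pass


@dataclass
class PerformerModel:
    """Generative model of a trained performer, one parameter per behavior.

    Error probabilities are per self-paced trial (forced trials can only
    break, so only the two break probabilities apply there).  Timing values
    are floored normals (floor 0.05 s).  ``opto_effects`` holds additive
    (``<param>_add``) or multiplicative (``<param>_mult``) deltas applied to
    the generative parameters on light-delivered trials — never post hoc —
    restricted per protocol to parameters the light can still causally
    reach (e.g. the transition protocol cannot change the latency).
    """

    p_incorrect_start: float = 0.06
    p_break_s1: float = 0.03
    p_premature_switch: float = 0.08
    p_break_s2: float = 0.17
    latency_mean: float = 1.5
    latency_sd: float = 0.8
    ipi_mean: float = 0.5
    ipi_sd: float = 0.15
    transition_mean: float = 1.0
    transition_sd: float = 0.3
    s1_extra_press_geometric_p: float = 0.32
    p_return: float = 0.01
    dwell_mean: float = 2.0
    dwell_sd: float = 0.5
    opto_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        probs = [
            self.p_incorrect_start,
            self.p_break_s1,
            self.p_premature_switch,
            self.p_break_s2,
        ]
        if any(not 0 <= p <= 1 for p in probs + [self.p_return]):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if sum(probs) > 1:
            raise ConfigurationError("error probabilities sum above 1")
        for name in ("latency_mean", "ipi_mean", "transition_mean", "dwell_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.s1_extra_press_geometric_p <= 1:
            raise ConfigurationError("s1_extra_press_geometric_p must be in (0, 1]")


# parameters the light can still causally influence, per protocol
_OPTO_SCOPE = {
    Protocol.BEFORE: None,  # everything
    Protocol.EXECUTION: {
        "p_break_s1",
        "p_premature_switch",
        "p_break_s2",
        "ipi_mean",
        "ipi_sd",
        "transition_mean",
        "transition_sd",
        "s1_extra_press_geometric_p",
    },
    Protocol.TRANSITION: {"transition_mean", "transition_sd"},
}


def _effective(model: PerformerModel, protocol: Protocol, lit: bool) -> PerformerModel:
    if not lit or not model.opto_effects or protocol is Protocol.NONE:
        return model
    scope = _OPTO_SCOPE[protocol]
    changes: dict[str, float] = {}
    for key, delta in model.opto_effects.items():
        if key.endswith("_add"):
            name, mult = key[:-4], False
        elif key.endswith("_mult"):
            name, mult = key[:-5], True
        else:
            raise ConfigurationError(f"opto effect {key!r} must end in _add or _mult")
        if not hasattr(model, name):
            if hasattr(model, name + "_mean"):  # latency_add targets latency_mean
                name = name + "_mean"
            else:
                raise ConfigurationError(f"opto effect targets unknown parameter {name!r}")
        if scope is not None and name not in scope:
            continue
        base = changes.get(name, getattr(model, name))
        value = base * delta if mult else base + delta
        if name.startswith("p_") or name == "s1_extra_press_geometric_p":
            value = min(1.0, max(0.0, value))
        changes[name] = value
    return replace(model, **changes) if changes else model


def _floored_normal(rng: np.random.Generator, mean: float, sd: float, floor: float = PRESS_FLOOR) -> float:
    return max(floor, float(rng.normal(mean, sd)))


def _draw_category(rng: np.random.Generator, model: PerformerModel, block: Block) -> Classification:
    u = rng.random()
    if block is Block.SELF_PACED:
        edges = np.cumsum(
            [model.p_incorrect_start, model.p_break_s1, model.p_premature_switch, model.p_break_s2]
        )
        cats = [
            Classification.INCORRECT_START,
            Classification.BREAK_S1,
            Classification.PREMATURE_SWITCH,
            Classification.BREAK_S2,
        ]
    else:
        edges = np.cumsum([model.p_break_s1, model.p_break_s2])
        cats = [Classification.BREAK_S1, Classification.BREAK_S2]
    idx = int(np.searchsorted(edges, u, side="right"))
    return cats[idx] if idx < len(cats) else Classification.CORRECT


def simulate_session(
    model: PerformerModel,
    n_rewards_target: int = 70,
    protocol: Protocol = Protocol.NONE,
    seed: int = 0,
    *,
    animal_id: str = "sim",
    group: Group = Group.EYFP_CONTROL,
    day: int = 1,
    block_structure: str = "alternating",
    max_trials: int = 20000,
) -> Session:
    """Simulate one session of the serial-order task.

    ``block_structure`` is ``"alternating"`` (forced and self-paced blocks
    switching after five consecutive correct sequences, the trained
    regimen) or ``"self_paced"`` (a single self-paced block, convenient for
    calibration studies that need many self-paced trials).
    """
    rng = np.random.default_rng(seed)
    events: list[Event] = []
    t = 5.0
    block = Block.FORCED if block_structure == "alternating" else Block.SELF_PACED
    events.append(
        Event(
            quantize_time(t - 1.0),
            EventCode.BLOCK_FORCED_START if block is Block.FORCED else EventCode.BLOCK_SELF_START,
        )
    )
    rewards = 0
    consecutive_correct = 0
    last_light_off = -math.inf
    n_lit = 0
    n_stim_assigned = 0

    def emit(time: float, code: EventCode, payload: dict | None = None) -> None:
        events.append(Event(quantize_time(time), code, payload))

    def emit_light(time: float) -> float:
        nonlocal last_light_off, n_lit
        time = max(time, last_light_off + 0.01)
        emit(time, EventCode.LIGHT_ON, {"protocol": protocol.value})
        emit(time + LIGHT_DURATION, EventCode.LIGHT_OFF)
        last_light_off = time + LIGHT_DURATION
        n_lit += 1
        return time

    for _ in range(max_trials):
        if rewards >= n_rewards_target:
            break
        stim = protocol is not Protocol.NONE and rng.random() < STIM_FRACTION
        n_stim_assigned += stim
        t_beam = t
        emit(t_beam, EventCode.BEAM_OUT)
        lit_now = False
        if stim and protocol is Protocol.BEFORE:
            emit_light(t_beam)
            lit_now = True
        eff = _effective(model, protocol, lit_now)

        # aborted initiation: beam crossing followed by a magazine re-entry
        if rng.random() < eff.p_return:
            t_mag = t_beam + _floored_normal(rng, 1.0, 0.3, 0.2)
            emit(t_mag, EventCode.MAG_IN)
            t = t_mag + _floored_normal(rng, model.dwell_mean, model.dwell_sd, 0.2)
            continue

        latency = _floored_normal(rng, eff.latency_mean, eff.latency_sd)
        if stim and protocol is Protocol.EXECUTION and not lit_now:
            eff = _effective(model, protocol, True)
        category = _draw_category(rng, eff, block)

        if block is Block.SELF_PACED:
            extra = int(rng.geometric(eff.s1_extra_press_geometric_p)) - 1
        else:
            extra = 0
        if category is Classification.CORRECT:
            n1, n2 = 4 + extra, 4
        elif category is Classification.BREAK_S1:
            n1, n2 = int(rng.integers(1, 4)), 0
        elif category is Classification.BREAK_S2:
            n1, n2 = 4 + extra, int(rng.integers(1, 4))
        elif category is Classification.PREMATURE_SWITCH:
            n1, n2 = int(rng.integers(1, 4)), int(rng.integers(1, 5))
        else:  # INCORRECT_START
            n1, n2 = 0, int(rng.integers(1, 4))

        t_press = t_beam + latency
        s1_times: list[float] = []
        trigger_idx = None
        if protocol is Protocol.TRANSITION and stim:
            trigger_idx = 2 if block is Block.FORCED else n1 - 3
            if trigger_idx < 0 or trigger_idx >= n1:
                trigger_idx = None  # trial never reaches the triggering press
        for i in range(n1):
            s1_times.append(t_press)
            emit(t_press, EventCode.LP1)
            if stim and protocol is Protocol.EXECUTION and i == 0 and n1 > 0:
                emit_light(t_press)
            if trigger_idx is not None and i == trigger_idx:
                emit_light(t_press)
                eff = _effective(model, protocol, True)
            if i < n1 - 1:
                t_press += _floored_normal(rng, eff.ipi_mean, eff.ipi_sd)
        s2_times: list[float] = []
        if n2 > 0:
            if n1 > 0:
                t_press = s1_times[-1] + _floored_normal(rng, eff.transition_mean, eff.transition_sd)
            for i in range(n2):
                s2_times.append(t_press)
                emit(t_press, EventCode.LP2)
                if stim and protocol is Protocol.EXECUTION and n1 == 0 and i == 0:
                    emit_light(t_press)
                if i < n2 - 1:
                    t_press += _floored_normal(rng, eff.ipi_mean, eff.ipi_sd)
        last_press = (s2_times or s1_times)[-1]
        if category is Classification.CORRECT:
            emit(last_press + 0.25, EventCode.REWARD)
            rewards += 1
            consecutive_correct += 1
        else:
            consecutive_correct = 0
        t_mag = last_press + _floored_normal(rng, 0.8, 0.2, 0.3)
        emit(t_mag, EventCode.MAG_IN)
        t = t_mag + _floored_normal(rng, model.dwell_mean, model.dwell_sd, 0.2)
        if category is not Classification.CORRECT:
            emit(t_mag, EventCode.TIMEOUT_START)
            t += TIMEOUT_S

        if block_structure == "alternating" and consecutive_correct >= 5:
            block = Block.SELF_PACED if block is Block.FORCED else Block.FORCED
            consecutive_correct = 0
            t += 3.0  # levers retract for the intertrial interval
            emit(
                t - 1.0,
                EventCode.BLOCK_SELF_START if block is Block.SELF_PACED else EventCode.BLOCK_FORCED_START,
            )

    if protocol is not Protocol.NONE and n_stim_assigned > 0 and n_lit == 0:
        raise ConfigurationError(
            "no stimulation trial ever reached its trigger; "
            "check the protocol against the programmed press counts"
        )
    emit(t + 1.0, EventCode.SESSION_END)
    return Session(
        animal_id=animal_id, group=group, day=day, protocol=protocol, events=events
    ).sorted()


# ---------------------------------------------------------------------------
# spike-train simulation


@dataclass
class EventKernel:
    """One additive rate kernel locked to a behavioral anchor.

    ``anchor`` is one of ``pre_initiation`` (first press; use negative
    onsets for anticipatory activity), ``s1_press`` (every S1 press),
    ``transition`` (last S1 press), ``s2_press`` (every S2 press) or
    ``reward`` (end of the sequence).  ``onset``/``offset`` are seconds
    relative to the anchor; ``shape`` is boxcar, ramp (0 to amplitude) or
    gaussian (centered between onset and offset, sigma = span/4).
    """

    anchor: str
    shape: str = "boxcar"
    amplitude: float = 0.0
    onset: float = 0.0
    offset: float = 0.5


@dataclass
class ModulationSpec:
    baseline_rate: float = 10.0
    event_kernels: list[EventKernel] = field(default_factory=list)
    duration_gain: float = 0.0  # Hz per second of sequence duration

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ConfigurationError("baseline_rate must be positive")
        for k in self.event_kernels:
            if k.offset <= k.onset:
                raise ConfigurationError("kernel offset must exceed onset")
            if k.shape not in ("boxcar", "ramp", "gaussian"):
                raise ConfigurationError(f"unknown kernel shape {k.shape!r}")


_INTENSITY_DT = 0.001


def _anchor_times(trial) -> dict[str, list[float]]:
    return {
        "pre_initiation": trial.all_press_times[:1],
        "s1_press": list(trial.s1_press_times),
        "transition": trial.s1_press_times[-1:] if trial.s1_press_times else [],
        "s2_press": list(trial.s2_press_times),
        "reward": trial.s2_press_times[-1:] if trial.s2_press_times else [],
    }


def _intensity_grid(session: Session, spec: ModulationSpec) -> tuple[np.ndarray, np.ndarray]:
    trials = parse_trials(session)
    t_end = max(e.time for e in session.events) + 1.0
    grid = np.arange(0.0, t_end, _INTENSITY_DT)
    lam = np.full(grid.size, float(spec.baseline_rate))

    def add(t0: float, t1: float, profile: np.ndarray | float) -> None:
        i0 = max(0, int(np.ceil(t0 / _INTENSITY_DT)))
        i1 = min(grid.size, int(np.floor(t1 / _INTENSITY_DT)) + 1)
        if i1 > i0:
            lam[i0:i1] += profile if np.isscalar(profile) else profile[: i1 - i0]

    eligible = [
        tr
        for tr in trials
        if tr.classification is Classification.CORRECT
        and len(tr.s1_press_times) >= 4
        and len(tr.s2_press_times) >= 4
    ]
    for tr in eligible:
        if spec.duration_gain:
            add(
                tr.all_press_times[0] - 1.0,
                tr.s2_press_times[-1],
                spec.duration_gain * tr.duration,
            )
        for k in spec.event_kernels:
            for a in _anchor_times(tr).get(k.anchor, []):
                t0, t1 = a + k.onset, a + k.offset
                i0 = max(0, int(np.ceil(t0 / _INTENSITY_DT)))
                i1 = min(grid.size, int(np.floor(t1 / _INTENSITY_DT)) + 1)
                if i1 <= i0:
                    continue
                tt = grid[i0:i1]
                if k.shape == "boxcar":
                    prof = np.full(tt.size, k.amplitude)
                elif k.shape == "ramp":
                    prof = k.amplitude * (tt - t0) / (t1 - t0)
                else:  # gaussian
                    center, sigma = (t0 + t1) / 2.0, (t1 - t0) / 4.0
                    prof = k.amplitude * np.exp(-0.5 * ((tt - center) / sigma) ** 2)
                lam[i0:i1] += prof
    np.clip(lam, 0.0, None, out=lam)
    return grid, lam


def expected_spike_count(session: Session, spec: ModulationSpec) -> float:
    """Integral of the programmed intensity (trapezoid on the 1-ms grid)."""
    grid, lam = _intensity_grid(session, spec)
    return float(np.trapezoid(lam, grid))


def simulate_unit(
    session: Session,
    spec: ModulationSpec,
    seed: int = 0,
    *,
    unit_id: str = "sim-unit",
    region: str = "M2",
) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train by thinning against the intensity."""
    rng = np.random.default_rng(seed)
    grid, lam = _intensity_grid(session, spec)
    lam_max = float(lam.max())
    span = grid[-1]
    n_cand = rng.poisson(lam_max * span)
    cand = np.sort(rng.uniform(0.0, span, size=n_cand))
    keep = rng.random(n_cand) * lam_max < np.interp(cand, grid, lam)
    return SpikeTrain(unit_id=unit_id, region=region, spike_times=cand[keep])


# ---------------------------------------------------------------------------
# antidromic photo-identification


@dataclass
class PidSpec:
    """Ground truth for a photo-identifiable cortico-striatal unit."""

    antidromic_latency: float = 0.005
    latency_jitter_sd: float = 0.0005
    follow_fidelity: float = 0.9
    waveform_correlation: float = 0.99

    def __post_init__(self) -> None:
        if self.antidromic_latency <= 0:
            raise ConfigurationError("antidromic latency must be positive")
        if not 0 <= self.follow_fidelity <= 1:
            raise ConfigurationError("follow fidelity must lie in [0, 1]")
        if not -1 <= self.waveform_correlation <= 1:
            raise ConfigurationError("waveform correlation must lie in [-1, 1]")


def pulse_train_times(
    n_trains: int = 5,
    start: float = 0.0,
    train_rate_hz: float = 10.0,
    pulses_per_train: int = 10,
    inter_train_interval: float = 3.0,
) -> np.ndarray:
    """Onset times of 10-Hz, 1-s trains of light pulses."""
    onsets = []
    t = start
    for _ in range(n_trains):
        onsets.extend(t + np.arange(pulses_per_train) / train_rate_hz)
        t += pulses_per_train / train_rate_hz + inter_train_interval
    return np.array(onsets)


def _spike_waveform(n: int = 40) -> np.ndarray:
    x = np.arange(n)
    return 80.0 * (-1.2 * np.exp(-0.5 * ((x - 12) / 2.2) ** 2) + 0.5 * np.exp(-0.5 * ((x - 20) / 4.5) ** 2))


def _correlated_waveform(base: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """A waveform whose sample Pearson correlation with ``base`` is exactly r."""
    c = base - base.mean()
    u = c / np.linalg.norm(c)
    if abs(r) >= 1.0 - 1e-12:
        return base.mean() + np.sign(r) * c
    noise = rng.normal(size=base.size)
    noise -= noise.mean()
    noise -= (noise @ u) * u
    v = noise / np.linalg.norm(noise)
    direction = r * u + math.sqrt(1.0 - r * r) * v
    return base.mean() + np.linalg.norm(c) * direction


def simulate_photoid(
    unit: SpikeTrain,
    pid: PidSpec,
    pulse_times: Sequence[float] | np.ndarray,
    seed: int = 0,
) -> SpikeTrain:
    """Add antidromically evoked spikes and a correlated waveform pair."""
    rng = np.random.default_rng(seed)
    pulses = np.asarray(pulse_times, float)
    evoked = []
    for p in pulses:
        if rng.random() < pid.follow_fidelity:
            lat = pid.antidromic_latency + rng.normal(0.0, pid.latency_jitter_sd)
            evoked.append(p + max(lat, 1e-4))
    times = np.sort(np.concatenate([unit.spike_times, np.array(evoked)]))
    base = _spike_waveform()
    light = _correlated_waveform(base, pid.waveform_correlation, rng)
    return SpikeTrain(
        unit_id=unit.unit_id,
        region=unit.region,
        spike_times=times,
        mean_waveform_behavioral=base,
        mean_waveform_light=light,
    )


# ---------------------------------------------------------------------------
# cohorts


def simulate_opto_cohort(
    n_animals: int,
    group: Group,
    protocol: Protocol,
    model: PerformerModel,
    n_rewards_target: int = 40,
    seed: int = 0,
) -> list[Session]:
    """One optogenetic session per animal, with per-animal independent seeds."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_animals) % (2**31)
    return [
        simulate_session(
            model,
            n_rewards_target=n_rewards_target,
            protocol=protocol,
            seed=int(child_seeds[i]),
            animal_id=f"{group.value.lower()}-{i:02d}",
            group=group,
        )
        for i in range(n_animals)
    ]
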