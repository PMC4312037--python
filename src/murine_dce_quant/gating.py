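"""Prospective cardiorespiratory dual-gating simulation.

A gated micro-CT projection may only be exposed when (a) the animal sits in
the quiescent end-exhalation plateau of its respiratory cycle for the whole
x-ray exposure, (b) the exposure starts at a fixed delay after an ECG
R-wave (0 ms ~ diastole, 55 ms ~ systole in the mouse), and (c) the
flat-panel detector has finished reading the previous frame (1 Hz frame
rate).  This module simulates the physiological signals and derives the
projection trigger schedule, gantry angles and total scan time under that
rule.  With the gating conditions vacuous the scan runs at the frame rate:
286 projections in 286 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhysioTrace",
    "GatingConfig",
    "GatingSchedule",
    "InsufficientTraceError",
    "simulate_physio",
    "projection_angles",
    "schedule_projections",
    "scan_duration",
]


class InsufficientTraceError(RuntimeError):
    """The physiological trace ended before all projections were triggered."""

    def __init__(self, n_obtained: int, n_requested: int):
        self.n_obtained = n_obtained
        self.n_requested = n_requested
        super().__init__(
            f"trace exhausted after {n_obtained} of {n_requested} triggers")


@dataclass(frozen=True)
class PhysioTrace:
    """Simulated ECG R-wave times and a sampled respiration waveform.

    ``resp_phase`` is a normalized bellows-like amplitude in [0, 1]:
    1 at peak inhalation, an exact 0 plateau at end exhalation.
    """

    r_wave_times_s: np.ndarray
    resp_phase: np.ndarray
    resp_sample_rate_hz: float
    cardiac_bpm_mean: float
    resp_bpm_mean: float
    duration_s: float

    def __post_init__(self):
        r = np.asarray(self.r_wave_times_s, dtype=float)
        if r.size and np.any(np.diff(r) <= 0):
            raise ValueError("R-wave times must be strictly increasing")
        p = np.asarray(self.resp_phase, dtype=float)
        if p.size and (p.min() < -1e-9 or p.max() > 1 + 1e-9):
            raise ValueError("resp_phase values must lie in [0, 1]")
        object.__setattr__(self, "r_wave_times_s", r)
        object.__setattr__(self, "resp_phase", p)


@dataclass(frozen=True)
class GatingConfig:
    """Acquisition parameters of the step-and-shoot gated protocol."""

    r_delay_ms: float = 0.0          # 0 = diastole, 55 = systole
    exposure_ms: float = 15.0
    n_projections: int = 286
    arc_deg: float = 200.0
    frame_rate_hz: float = 1.0
    exhalation_window_fraction: float = 0.3
    exhalation_threshold: float = 0.05  # resp_phase at/below this is "in window"

    def __post_init__(self):
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")
        if not (0 < self.arc_deg <= 360):
            raise ValueError("arc_deg must lie in (0, 360]")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.exposure_ms >= 1000.0 / self.frame_rate_hz:
            raise ValueError("exposure must fit within one detector frame")
        if self.r_delay_ms < 0:
            raise ValueError("r_delay_ms must be non-negative")
        if not (0 < self.exhalation_window_fraction <= 1):
            raise ValueError("exhalation_window_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class GatingSchedule:
    """Trigger times and gantry angles of one completed gated scan."""

    trigger_times_s: np.ndarray
    angles_deg: np.ndarray
    total_time_s: float
    n_rejected_resp: int = 0
    n_rejected_frame: int = 0

    def __post_init__(self):
        t = np.asarray(self.trigger_times_s, dtype=float)
        a = np.asarray(self.angles_deg, dtype=float)
        if t.shape != a.shape:
            raise ValueError("trigger times and angles must match in length")
        object.__setattr__(self, "trigger_times_s", t)
        object.__setattr__(self, "angles_deg", a)

    def __len__(self) -> int:
        return len(self.trigger_times_s)


def simulate_physio(cardiac_bpm: float, resp_bpm: float, jitter_cv: float,
                    duration_s: float, seed: int | None = None,
                    plateau_fraction: float = 0.3,
                    sample_rate_hz: float = 500.0) -> PhysioTrace:
    """Simulate jittered ECG R-waves and a respiration waveform.

    Cycle lengths are Normal(mean, jitter_cv * mean) truncated positive.
    Each respiratory cycle is a raised-cosine inhalation/exhalation bump
    followed by an end-exhalation plateau at exactly 0 occupying
    ``plateau_fraction`` of the cycle.  The first R-wave falls at t = 0.
    """
    if cardiac_bpm <= 0 or resp_bpm <= 0:
        raise ValueError("rates must be positive")
    if jitter_cv < 0:
        raise ValueError("jitter_cv must be non-negative")
    if not (0 < plateau_fraction <= 1):
        raise ValueError("plateau_fraction must lie in (0, 1]")
    rr = 60.0 / cardiac_bpm
    resp_cycle = 60.0 / resp_bpm
    if duration_s < max(rr, resp_cycle):
        raise ValueError("duration too short for a single cardiac and "
                         "respiratory cycle")
    rng = np.random.default_rng(seed)

    def cycles(mean: float) -> np.ndarray:
        n = int(duration_s / mean * 1.3) + 10
        draws = rng.normal(mean, jitter_cv * mean, size=n)
        out = np.maximum(draws, 0.05 * mean)  # truncate positive
        while out.sum() < duration_s:
            extra = np.maximum(rng.normal(mean, jitter_cv * mean, size=n),
                               0.05 * mean)
            out = np.concatenate([out, extra])
        return out

    r_times = np.concatenate([[0.0], np.cumsum(cycles(rr))])
    r_times = r_times[r_times <= duration_s]

    lengths = cycles(resp_cycle)
    starts = np.concatenate([[0.0], np.cumsum(lengths)])
    t = np.arange(0.0, duration_s, 1.0 / sample_rate_hz)
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0,
                  len(lengths) - 1)
    p = (t - starts[idx]) / lengths[idx]
    active = 1.0 - plateau_fraction
    if active > 0:
        phase = np.where(p < active,
                         0.5 * (1.0 - np.cos(2.0 * np.pi * p / active)), 0.0)
    else:
        phase = np.zeros_like(p)
    return PhysioTrace(r_wave_times_s=r_times, resp_phase=phase,
                       resp_sample_rate_hz=sample_rate_hz,
                       cardiac_bpm_mean=cardiac_bpm, resp_bpm_mean=resp_bpm,
                       duration_s=duration_s)


def projection_angles(n: int, arc_deg: float) -> np.ndarray:
    """Evenly spaced gantry angles from 0 to ``arc_deg`` inclusive."""
    if n < 2:
        raise ValueError("need at least 2 projections for an angular span")
    return np.linspace(0.0, arc_deg, n)


def schedule_projections(trace: PhysioTrace,
                         config: GatingConfig) -> GatingSchedule:
    """Derive the prospective trigger schedule from a physiological trace.

    Candidates arise at R-wave + r_delay, in time order; a candidate fires
    iff the whole exposure sits inside the end-exhalation window
    (resp_phase <= exhalation_threshold throughout) and at least one
    detector frame period has elapsed since the previous trigger.  Angles
    are assigned in step-and-shoot order; the total time adds one readout
    period after the last trigger.
    """
    fs = trace.resp_sample_rate_hz
    # window of samples covering [t, t + exposure] for any sub-sample phase
    n_expo = max(1, int(np.ceil(config.exposure_ms / 1000.0 * fs))) + 2
    phase = trace.resp_phase
    if len(phase) >= n_expo:
        window_max = np.lib.stride_tricks.sliding_window_view(
            phase, n_expo).max(axis=1)
    else:
        window_max = np.empty(0)
    frame_period = 1.0 / config.frame_rate_hz
    delay = config.r_delay_ms / 1000.0
    expo = config.exposure_ms / 1000.0

    triggers: list[float] = []
    last = -np.inf
    rej_resp = rej_frame = 0
    for r in trace.r_wave_times_s:
        t = r + delay
        i = int(t * fs)
        if i >= len(window_max) or t + expo > trace.duration_s:
            break
        if t - last < frame_period - 1e-9:
            rej_frame += 1
            continue
        if window_max[i] > config.exhalation_threshold:
            rej_resp += 1
            continue
        triggers.append(t)
        last = t
        if len(triggers) == config.n_projections:
            break
    if len(triggers) < config.n_projections:
        raise InsufficientTraceError(len(triggers), config.n_projections)
    angles = (projection_angles(config.n_projections, config.arc_deg)
              if config.n_projections >= 2 else np.zeros(1))
    return GatingSchedule(trigger_times_s=np.asarray(triggers),
                          angles_deg=angles,
                          total_time_s=triggers[-1] + frame_period,
                          n_rejected_resp=rej_resp,
                          n_rejected_frame=rej_frame)


def scan_duration(schedule: GatingSchedule) -> float:
    """Total scan time in seconds (last trigger + readout period)."""
    if len(schedule) == 0:
        raise ValueError("empty schedule has no duration")
    return float(schedule.total_time_s)
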