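"""Core domain types shared across the pipeline.

A recording session consists of four air-pressure channels — right knee
(RK), right back (RB), left knee (LK), left back (LB) — sampled while a
supine participant performs bridging tasks: bilateral (BB), unilateral
right (URB) and unilateral left (ULB). Knee channels are expected to rise
when the knees press into the support; back channels fall as the lower
back lifts off its sensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The four pressure channels, in canonical order.
CHANNELS: tuple[str, ...] = ("RK", "RB", "LK", "LB")
KNEE_CHANNELS: tuple[str, ...] = ("RK", "LK")
BACK_CHANNELS: tuple[str, ...] = ("RB", "LB")

#: The three bridging tasks, in canonical order.
TASKS: tuple[str, ...] = ("BB", "URB", "ULB")

#: Expected movement direction by channel type: knees press down
#: (pressure increase), the back lifts off (pressure decrease).
CHANNEL_DIRECTION: dict[str, str] = {
    "RK": "increase",
    "LK": "increase",
    "RB": "decrease",
    "LB": "decrease",
}

#: Left-right mirror of channels, used by the unilateral symmetry checks.
MIRROR_CHANNEL: dict[str, str] = {"RK": "LK", "LK": "RK", "RB": "LB", "LB": "RB"}


def validate_channel(channel: str) -> str:
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    return channel


def validate_task(task: str) -> str:
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    return task


@dataclass(frozen=True)
class PressureTrace:
    """One channel's uniformly sampled pressure series.

    Parameters
    ----------
    channel : str
        One of ``RK``, ``RB``, ``LK``, ``LB``.
    sampling_rate_hz : float
        Sampling rate of the digital stream (28 Hz for the reference
        hardware).
    t0_s : float
        Session time of the first sample, in seconds.
    samples : ndarray
        Pressure values in mmHg.
    """

    channel: str
    sampling_rate_hz: float
    t0_s: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        validate_channel(self.channel)
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Session time of every sample, in seconds."""
        return self.t0_s + np.arange(self.samples.size) / self.sampling_rate_hz

    @property
    def t_end(self) -> float:
        return self.t0_s + (self.samples.size - 1) / self.sampling_rate_hz

    def index_at(self, t_s: float) -> int:
        """Index of the first sample at or after session time ``t_s``."""
        return int(np.ceil((t_s - self.t0_s) * self.sampling_rate_hz - 1e-9))

    def with_samples(self, samples: np.ndarray) -> "PressureTrace":
        return PressureTrace(self.channel, self.sampling_rate_hz, self.t0_s, samples)


@dataclass(frozen=True)
class VelocityTrace:
    """Rate of change of pressure on the same grid as its source trace."""

    channel: str
    sampling_rate_hz: float
    t0_s: float
    values: np.ndarray  # mmHg/s

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("velocity values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.sampling_rate_hz


@dataclass(frozen=True)
class TrialWindow:
    """One repetition of one task.

    ``cue_onset_s`` is the session time of the movement cue;
    ``hold_duration_s`` spans from the cue to the end of the held plateau
    (the movement ramp happens inside it, as in the reference protocol
    where the participant rises into the bridge on cue and holds for
    10 s).
    """

    task: str
    trial_index: int
    cue_onset_s: float
    hold_duration_s: float

    def __post_init__(self) -> None:
        validate_task(self.task)
        if self.trial_index < 1:
            raise ValueError("trial_index starts at 1")
        if not self.hold_duration_s > 0:
            raise ValueError("hold_duration_s must be positive")

    @property
    def end_s(self) -> float:
        return self.cue_onset_s + self.hold_duration_s
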