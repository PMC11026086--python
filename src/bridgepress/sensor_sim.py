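"""Synthetic bridging-session generator with known ground truth.

The simulator emulates the dual-readout pressure system: a continuous
underlying pressure trajectory per channel (baseline, smooth ramps to a
per-trial plateau and back, optional slow drift), rendered through two
readout models —

* a digital stream sampled at 28 Hz with additive Gaussian sensor noise;
* an analog gauge read once per trial by an observer, with Gaussian
  reading noise and quantization to the gauge precision (2 mmHg).

Every simulated trial carries its true plateau pressure and transition
times, so extraction algorithms can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    BACK_CHANNELS,
    CHANNELS,
    KNEE_CHANNELS,
    TASKS,
    PressureTrace,
    TrialWindow,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "TruthRecord",
    "AnalogReading",
    "Session",
    "simulate_session",
    "simulate_cohort",
    "default_reference_config",
    "DEFAULT_PLATEAUS",
    "DEFAULT_BASELINES",
]

# Calibration defaults: representative stable digital pressures (mmHg)
# per task x channel from the reference validation experiment of the
# four-sensor system. Used to derive the default task deltas.
DEFAULT_PLATEAUS: dict[str, dict[str, float]] = {
    "BB": {"RK": 50.84, "RB": 10.60, "LK": 50.77, "LB": 9.30},
    "URB": {"RK": 57.99, "RB": 9.46, "LK": 42.18, "LB": 11.66},
    "ULB": {"RK": 40.99, "RB": 12.94, "LK": 56.54, "LB": 8.82},
}

# Resting pressures chosen so that pressed knees rise, the unloaded knee
# in a unilateral bridge drops by ~4 mmHg (as the reference plateaus
# imply), and back pressure always falls when bridging.
DEFAULT_BASELINES: dict[str, float] = {"RK": 44.99, "LK": 46.18, "RB": 20.0, "LB": 20.0}

# Between-participant spread of resting pressure, mmHg (applied to both
# baseline and plateau, so per-trial deltas are unaffected).
DEFAULT_PARTICIPANT_SD: dict[str, float] = {"RK": 5.5, "LK": 5.5, "RB": 6.5, "LB": 6.5}

_CH_INDEX = {ch: i for i, ch in enumerate(CHANNELS)}
# substream codes for seed derivation
_STREAM_NOISE = 0
_STREAM_DRIFT = 1
_STREAM_JITTER = 2
_STREAM_ANALOG = 3
_STREAM_OFFSET = 4


@dataclass
class SimConfig:
    """Parameters of a simulated bridging session.

    Attributes
    ----------
    baseline_mmHg : dict
        Resting pressure per channel.
    task_delta_mmHg : dict
        ``{task: {channel: delta}}`` plateau change relative to baseline;
        positive for pressed knees, negative for lifted backs and for the
        slightly unloaded knee of a unilateral bridge.
    ramp_duration_s : float
        Duration of the smoothstep transition into and out of the hold.
    hold_duration_s : float
        Cue-to-relax duration; the ramp up occurs inside it, so the flat
        plateau lasts ``hold_duration_s - ramp_duration_s``.
    n_reps : int
        Repetitions per task (6 in the reference protocol).
    inter_trial_rest_s, settle_s : float
        Rest between trials and initial settling time at baseline.
    digital_rate_hz : float
        Digital sampling rate (28 Hz reference hardware).
    analog_rate_hz : float
        Frame rate of the video capturing the analog dials (30 Hz);
        metadata only — the analog model produces one reading per trial.
    analog_precision_mmHg : float
        Gauge precision; analog readings are rounded to multiples of it.
    noise_sd_mmHg : float
        I.i.d. Gaussian sensor noise on each digital sample.
    drift_sd_mmHg_per_s : float
        Scale of an integrated Gaussian random-walk drift (0 disables).
    analog_read_sd_mmHg : float
        Observer reading noise applied before quantization.
    trial_jitter_sd_mmHg : float
        Within-participant trial-to-trial variability of the plateau
        (applied to the underlying trajectory, hence seen by both
        readouts).
    participant_sd_mmHg : dict
        Between-participant SD of a per-channel resting-pressure offset,
        used by :func:`simulate_cohort`.
    rng_seed : int
        Master seed; all randomness derives from it deterministically.
    """

    baseline_mmHg: dict[str, float]
    task_delta_mmHg: dict[str, dict[str, float]]
    ramp_duration_s: float = 1.5
    hold_duration_s: float = 10.0
    n_reps: int = 6
    inter_trial_rest_s: float = 5.0
    settle_s: float = 5.0
    digital_rate_hz: float = 28.0
    analog_rate_hz: float = 30.0
    analog_precision_mmHg: float = 2.0
    noise_sd_mmHg: float = 0.5
    drift_sd_mmHg_per_s: float = 0.0
    analog_read_sd_mmHg: float = 1.3
    trial_jitter_sd_mmHg: float = 0.75
    participant_sd_mmHg: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARTICIPANT_SD)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("digital_rate_hz", "analog_rate_hz", "analog_precision_mmHg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.ramp_duration_s > 0 or not self.hold_duration_s > 0:
            raise ValueError("ramp and hold durations must be positive")
        for sd in (
            self.noise_sd_mmHg,
            self.drift_sd_mmHg_per_s,
            self.analog_read_sd_mmHg,
            self.trial_jitter_sd_mmHg,
        ):
            if sd < 0:
                raise ValueError("noise scales must be non-negative")
        missing = set(CHANNELS) - set(self.baseline_mmHg)
        if missing:
            raise ValueError(f"baseline_mmHg missing channels {sorted(missing)}")
        for task in TASKS:
            if task not in self.task_delta_mmHg:
                raise ValueError(f"task_delta_mmHg missing task {task}")
            missing = set(CHANNELS) - set(self.task_delta_mmHg[task])
            if missing:
                raise ValueError(f"task_delta_mmHg[{task}] missing {sorted(missing)}")


@dataclass(frozen=True)
class TruthRecord:
    """True plateau and transition times for one (task, trial, channel)."""

    task: str
    trial_index: int
    channel: str
    plateau_mmHg: float
    t_cue_s: float
    t_ramp_end_s: float
    t_hold_end_s: float


@dataclass
class GroundTruth:
    """All truth records of a session, plus degenerate-input warnings."""

    records: list[TruthRecord]
    warnings: list[str] = field(default_factory=list)

    def plateau(self, task: str, trial_index: int, channel: str) -> float:
        for r in self.records:
            if (r.task, r.trial_index, r.channel) == (task, trial_index, channel):
                return r.plateau_mmHg
        raise KeyError((task, trial_index, channel))


@dataclass(frozen=True)
class AnalogReading:
    """One observer reading of an analog gauge during a trial's hold."""

    task: str
    trial_index: int
    channel: str
    value_mmHg: float


@dataclass
class Session:
    """A complete simulated session: both readouts plus ground truth."""

    session_id: str
    config: SimConfig
    traces: dict[str, PressureTrace]
    windows: list[TrialWindow]
    analog: list[AnalogReading]
    truth: GroundTruth


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """C1 sigmoid 0->1 on [0, 1]: 3x^2 - 2x^3."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _bump(t: np.ndarray, cue: float, ramp: float, hold: float) -> np.ndarray:
    """Unit trial envelope: ramp up over [cue, cue+ramp], flat to
    cue+hold, ramp down over [cue+hold, cue+hold+ramp]."""
    up = _smoothstep((t - cue) / ramp)
    down = _smoothstep((t - (cue + hold)) / ramp)
    return up - down


def _rng(config: SimConfig, participant: int, channel: str, code: int, trial: int = 0):
    seq = np.random.SeedSequence(
        (int(config.rng_seed), int(participant), _CH_INDEX[channel], code, trial)
    )
    return np.random.default_rng(seq)


def _build_windows(config: SimConfig) -> tuple[list[TrialWindow], float]:
    windows: list[TrialWindow] = []
    t = config.settle_s
    for task in TASKS:
        for rep in range(1, config.n_reps + 1):
            windows.append(TrialWindow(task, rep, t, config.hold_duration_s))
            t += config.hold_duration_s + config.ramp_duration_s + config.inter_trial_rest_s
    return windows, t + 2.0  # 2 s tail at baseline


def simulate_session(
    config: SimConfig,
    session_id: str = "S01",
    participant_index: int = 0,
    participant_offsets: dict[str, float] | None = None,
) -> Session:
    """Simulate one session under ``config``.

    The underlying trajectory for each channel is
    ``baseline + offset + sum of per-trial smoothstep bumps + drift``;
    the digital trace samples it at ``digital_rate_hz`` with additive
    sensor noise, and one analog reading per trial averages it over the
    middle 4 s of the plateau before observer noise and quantization.
    Identical seed (and participant index) yields bit-identical output.
    """
    windows, duration = _build_windows(config)
    fs = config.digital_rate_hz
    n = int(np.ceil(duration * fs)) + 1
    t = np.arange(n) / fs
    offsets = participant_offsets or {ch: 0.0 for ch in CHANNELS}

    truth = GroundTruth(records=[])
    min_hold = config.ramp_duration_s + 5.0  # 1 s delay + 4 s average
    if config.hold_duration_s < min_hold:
        truth.warnings.append(
            f"hold_duration_s={config.hold_duration_s} is shorter than the "
            f"extraction window requirement ({min_hold:.1f} s); stable values "
            "will not be extractable"
        )

    traces: dict[str, PressureTrace] = {}
    analog: list[AnalogReading] = []
    for ch in CHANNELS:
        base = config.baseline_mmHg[ch] + offsets.get(ch, 0.0)
        underlying = np.full(n, base)
        for w_idx, w in enumerate(windows):
            delta = config.task_delta_mmHg[w.task][ch]
            jitter = 0.0
            if config.trial_jitter_sd_mmHg > 0:
                jitter = _rng(config, participant_index, ch, _STREAM_JITTER, w_idx).normal(
                    0.0, config.trial_jitter_sd_mmHg
                )
            amp = delta + jitter
            underlying += amp * _bump(t, w.cue_onset_s, config.ramp_duration_s, config.hold_duration_s)
            truth.records.append(
                TruthRecord(
                    task=w.task,
                    trial_index=w.trial_index,
                    channel=ch,
                    plateau_mmHg=base + amp,
                    t_cue_s=w.cue_onset_s,
                    t_ramp_end_s=w.cue_onset_s + config.ramp_duration_s,
                    t_hold_end_s=w.end_s,
                )
            )

        if config.drift_sd_mmHg_per_s > 0:
            steps = _rng(config, participant_index, ch, _STREAM_DRIFT).normal(
                0.0, config.drift_sd_mmHg_per_s / np.sqrt(fs), size=n
            )
            underlying = underlying + np.cumsum(steps)

        # analog readout: trajectory averaged over the middle 4 s of the
        # plateau, observer noise, then gauge quantization
        for w_idx, w in enumerate(windows):
            plateau_start = w.cue_onset_s + config.ramp_duration_s
            center = 0.5 * (plateau_start + w.end_s)
            half = min(2.0, 0.5 * max(w.end_s - plateau_start, 0.0))
            sel = (t >= center - half) & (t <= center + half)
            value = float(underlying[sel].mean()) if sel.any() else base
            if config.analog_read_sd_mmHg > 0:
                value += _rng(config, participant_index, ch, _STREAM_ANALOG, w_idx).normal(
                    0.0, config.analog_read_sd_mmHg
                )
            q = config.analog_precision_mmHg
            analog.append(AnalogReading(w.task, w.trial_index, ch, float(q * np.round(value / q))))

        digital = underlying
        if config.noise_sd_mmHg > 0:
            digital = underlying + _rng(config, participant_index, ch, _STREAM_NOISE).normal(
                0.0, config.noise_sd_mmHg, size=n
            )
        traces[ch] = PressureTrace(ch, fs, 0.0, digital)

    return Session(session_id, config, traces, windows, analog, truth)


def _draw_offsets(config: SimConfig, participant_index: int) -> dict[str, float]:
    """Per-channel resting-pressure offsets; redrawn until every plateau
    stays above 0.5 mmHg (gauges cannot read negative pressure)."""
    offsets: dict[str, float] = {}
    for ch in CHANNELS:
        sd = config.participant_sd_mmHg.get(ch, 0.0)
        if sd <= 0:
            offsets[ch] = 0.0
            continue
        floor = min(
            [config.baseline_mmHg[ch]]
            + [config.baseline_mmHg[ch] + config.task_delta_mmHg[task][ch] for task in TASKS]
        )
        rng = _rng(config, participant_index, ch, _STREAM_OFFSET)
        for _ in range(1000):
            off = rng.normal(0.0, sd)
            if floor + off >= 0.5:
                offsets[ch] = float(off)
                break
        else:  # pragma: no cover - requires pathological config
            raise RuntimeError(f"could not draw a feasible offset for channel {ch}")
    return offsets


def simulate_cohort(config: SimConfig, n_participants: int, id_prefix: str = "P") -> list[Session]:
    """Simulate ``n_participants`` sessions differing by a per-channel
    resting-pressure offset (between-participant variability) and by
    their noise substreams. Deterministic in ``config.rng_seed``."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    sessions = []
    for i in range(n_participants):
        offsets = _draw_offsets(config, i)
        sessions.append(
            simulate_session(
                config,
                session_id=f"{id_prefix}{i + 1:02d}",
                participant_index=i,
                participant_offsets=offsets,
            )
        )
    return sessions


def default_reference_config(**overrides) -> SimConfig:
    """Simulator configuration calibrated to the reference system.

    Noiseless plateaus equal :data:`DEFAULT_PLATEAUS` exactly: deltas are
    the difference between those plateaus and :data:`DEFAULT_BASELINES`.
    Keyword overrides replace any :class:`SimConfig` field.
    """
    deltas = {
        task: {ch: DEFAULT_PLATEAUS[task][ch] - DEFAULT_BASELINES[ch] for ch in CHANNELS}
        for task in TASKS
    }
    kwargs = dict(baseline_mmHg=dict(DEFAULT_BASELINES), task_delta_mmHg=deltas)
    kwargs.update(overrides)
    return SimConfig(**kwargs)
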