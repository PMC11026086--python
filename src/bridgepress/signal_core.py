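"""Stable-pressure extraction from digital pressure traces.

The extraction pipeline per trial:

1. zero-phase low-pass filtering (Butterworth, forward-backward, 2 Hz
   cutoff by default);
2. pressure velocity by central differences;
3. the signed velocity extremum within the first 2 s after the movement
   cue (maximum for increasing channels, minimum for decreasing ones);
4. the first zero-crossing of velocity after that extremum, marking the
   end of the movement ramp;
5. the stable value: pressure averaged over 4 s starting 1 s after the
   zero-crossing;
6. per-task aggregation as the mean over valid trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import (
    CHANNEL_DIRECTION,
    PressureTrace,
    TrialWindow,
    VelocityTrace,
)

__all__ = [
    "FilterSpec",
    "StableValue",
    "TrialSummary",
    "filter_dualpass",
    "compute_velocity",
    "find_zero_crossing",
    "extract_stable_value",
    "extract_session",
    "summarize_trials",
]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass specification.

    ``order_per_pass`` is the order of each directional pass; the
    forward-backward application doubles the effective order and squares
    the magnitude response (amplitude 1/2 at the cutoff for any order).
    """

    cutoff_hz: float = 2.0
    order_per_pass: int = 2

    def __post_init__(self) -> None:
        if not self.cutoff_hz > 0:
            raise ValueError("cutoff_hz must be positive")
        if self.order_per_pass < 1:
            raise ValueError("order_per_pass must be >= 1")


@dataclass(frozen=True)
class StableValue:
    """The extracted per-trial plateau pressure with its timing marks.

    ``value_mmHg`` is the 4 s average taken 1 s after the velocity
    zero-crossing; ``baseline_mmHg`` (when computed) is the mean filtered
    pressure over the 2 s preceding the cue, used by compliance checks.
    Invalid extractions carry ``valid=False`` and an ``invalid_reason``
    of ``no_movement``, ``no_zero_crossing`` or ``window_truncated``.
    """

    channel: str
    task: str
    trial_index: int
    value_mmHg: float
    direction: str
    t_peak_velocity_s: float
    t_zero_cross_s: float
    avg_window_s: tuple[float, float]
    valid: bool
    invalid_reason: str | None = None
    baseline_mmHg: float | None = None

    @property
    def delta_mmHg(self) -> float | None:
        if self.baseline_mmHg is None or not self.valid:
            return None
        return self.value_mmHg - self.baseline_mmHg


@dataclass(frozen=True)
class TrialSummary:
    """Per (task, channel) mean of valid stable values across trials."""

    table: pd.DataFrame  # columns: task, channel, mean_mmHg, n_valid, missing

    def cell(self, task: str, channel: str) -> pd.Series:
        sel = self.table[(self.table.task == task) & (self.table.channel == channel)]
        if sel.empty:
            raise KeyError((task, channel))
        return sel.iloc[0]


def _min_length(spec: FilterSpec) -> int:
    # sosfiltfilt uses padlen = 3 * (2 * n_sections + 1) by default
    n_sections = (spec.order_per_pass + 1) // 2
    return 3 * (2 * n_sections + 1) + 1


def filter_dualpass(trace: PressureTrace, spec: FilterSpec | None = None) -> PressureTrace:
    """Apply the zero-phase (forward-backward) Butterworth low-pass.

    Edge transients are controlled by scipy's odd-reflection padding.
    DC gain is exactly 1, so constant traces pass through unchanged.

    Raises
    ------
    ValueError
        If the cutoff is at or above Nyquist, or the trace is shorter
        than the reflection padding requires.
    """
    spec = spec or FilterSpec()
    nyquist = trace.sampling_rate_hz / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz of the {trace.sampling_rate_hz} Hz trace"
        )
    if trace.samples.size < _min_length(spec):
        raise ValueError(
            f"trace of length {trace.samples.size} is too short for the filter; "
            f"need at least {_min_length(spec)} samples"
        )
    sos = sps.butter(
        spec.order_per_pass, spec.cutoff_hz, btype="low", fs=trace.sampling_rate_hz, output="sos"
    )
    return trace.with_samples(sps.sosfiltfilt(sos, trace.samples))


def compute_velocity(trace: PressureTrace) -> VelocityTrace:
    """Pressure velocity in mmHg/s: central differences on interior
    samples, one-sided differences at the two edges."""
    if trace.samples.size < 3:
        raise ValueError("need at least 3 samples to compute velocity")
    v = np.gradient(trace.samples, trace.dt)
    return VelocityTrace(trace.channel, trace.sampling_rate_hz, trace.t0_s, v)


def find_zero_crossing(values: np.ndarray, start: int, stop: int | None = None) -> int | None:
    """First index ``k > start`` in ``[start+1, stop)`` where ``values``
    changes sign relative to ``values[start]`` (exact zeros count).

    Returns ``None`` when no crossing exists in the range.
    """
    values = np.asarray(values)
    stop = values.size if stop is None else min(stop, values.size)
    s0 = np.sign(values[start])
    if s0 == 0:
        return start
    seg = np.sign(values[start + 1 : stop])
    hits = np.flatnonzero(seg != s0)
    if hits.size == 0:
        return None
    return start + 1 + int(hits[0])


def _invalid(channel, window, direction, reason, t_peak=np.nan, t_zc=np.nan):
    return StableValue(
        channel=channel,
        task=window.task,
        trial_index=window.trial_index,
        value_mmHg=np.nan,
        direction=direction,
        t_peak_velocity_s=t_peak,
        t_zero_cross_s=t_zc,
        avg_window_s=(np.nan, np.nan),
        valid=False,
        invalid_reason=reason,
    )


def extract_stable_value(
    filtered: PressureTrace,
    velocity: VelocityTrace,
    window: TrialWindow,
    direction: str,
    *,
    peak_search_s: float = 2.0,
    delay_s: float = 1.0,
    avg_duration_s: float = 4.0,
    min_peak_velocity: float = 1.0,
    zc_search_limit_s: float | None = None,
) -> StableValue:
    """Extract one trial's stable pressure.

    ``direction`` is ``increase`` (knee), ``decrease`` (back) or ``auto``
    (take the extremum of |velocity|, resolving the direction from its
    sign — useful for channels whose movement direction is not fixed a
    priori, such as the unloaded knee in a unilateral bridge).

    ``zc_search_limit_s`` optionally restricts the zero-crossing search
    to that many seconds after the velocity peak; by default the search
    runs to the end of the trial window.
    """
    if direction not in ("increase", "decrease", "auto"):
        raise ValueError(f"unknown direction {direction!r}")
    t = filtered.times
    if window.cue_onset_s < t[0] - 1e-9 or window.end_s > t[-1] + 1e-9:
        raise ValueError(
            f"trial window [{window.cue_onset_s}, {window.end_s}] s lies outside "
            f"the trace span [{t[0]}, {t[-1]}] s"
        )
    i_cue = filtered.index_at(window.cue_onset_s)
    i_peak_stop = min(filtered.index_at(window.cue_onset_s + peak_search_s) + 1, t.size)
    i_end = min(filtered.index_at(window.end_s) + 1, t.size)
    seg = velocity.values[i_cue:i_peak_stop]

    if direction == "increase":
        k_peak = i_cue + int(np.argmax(seg))
    elif direction == "decrease":
        k_peak = i_cue + int(np.argmin(seg))
    else:
        k_peak = i_cue + int(np.argmax(np.abs(seg)))
        direction = "increase" if velocity.values[k_peak] >= 0 else "decrease"

    v_peak = velocity.values[k_peak]
    if abs(v_peak) < min_peak_velocity:
        return _invalid(filtered.channel, window, direction, "no_movement", t_peak=t[k_peak])

    zc_stop = i_end
    if zc_search_limit_s is not None:
        zc_stop = min(zc_stop, filtered.index_at(t[k_peak] + zc_search_limit_s) + 1)
    k_zc = find_zero_crossing(velocity.values, k_peak, zc_stop)
    if k_zc is None:
        return _invalid(
            filtered.channel, window, direction, "no_zero_crossing", t_peak=t[k_peak]
        )

    t_zc = t[k_zc]
    avg_start = t_zc + delay_s
    avg_end = avg_start + avg_duration_s
    if avg_end > min(window.end_s, t[-1]) + 1e-9:
        return _invalid(
            filtered.channel, window, direction, "window_truncated", t_peak=t[k_peak], t_zc=t_zc
        )
    i0 = filtered.index_at(avg_start)
    i1 = filtered.index_at(avg_end)
    value = float(filtered.samples[i0:i1].mean())
    return StableValue(
        channel=filtered.channel,
        task=window.task,
        trial_index=window.trial_index,
        value_mmHg=value,
        direction=direction,
        t_peak_velocity_s=float(t[k_peak]),
        t_zero_cross_s=float(t_zc),
        avg_window_s=(float(avg_start), float(avg_end)),
        valid=True,
    )


def _pretrial_baseline(filtered: PressureTrace, window: TrialWindow, baseline_s: float) -> float | None:
    i1 = filtered.index_at(window.cue_onset_s)
    i0 = max(filtered.index_at(window.cue_onset_s - baseline_s), 0)
    if i1 - i0 < 2:
        return None
    return float(filtered.samples[i0:i1].mean())


def extract_session(
    traces: dict[str, PressureTrace],
    windows: list[TrialWindow],
    *,
    filter_spec: FilterSpec | None = None,
    direction_mode: str = "auto",
    baseline_window_s: float = 2.0,
    **extract_kwargs,
) -> list[StableValue]:
    """Run the full extraction on every (trial, channel) of a session.

    ``direction_mode='convention'`` fixes the search direction by channel
    type (knees increase, backs decrease); ``'auto'`` (default) lets each
    trial's dominant velocity decide, which also recovers the small
    pressure drop of the unloaded knee during unilateral bridges.

    Each stable value carries the pre-cue baseline (mean filtered
    pressure over ``baseline_window_s`` before the cue) for downstream
    compliance checks.
    """
    if direction_mode not in ("auto", "convention"):
        raise ValueError(f"unknown direction_mode {direction_mode!r}")
    out: list[StableValue] = []
    for ch, trace in traces.items():
        filtered = filter_dualpass(trace, filter_spec)
        velocity = compute_velocity(filtered)
        direction = CHANNEL_DIRECTION[ch] if direction_mode == "convention" else "auto"
        for w in windows:
            sv = extract_stable_value(filtered, velocity, w, direction, **extract_kwargs)
            base = _pretrial_baseline(filtered, w, baseline_window_s)
            out.append(replace(sv, baseline_mmHg=base))
    return out


def summarize_trials(values: list[StableValue]) -> TrialSummary:
    """Average valid stable values per (task, channel).

    Cells with zero valid trials are flagged ``missing`` with a NaN mean
    rather than silently dropped.
    """
    if not values:
        raise ValueError("no stable values to summarize")
    rows = []
    keys = sorted({(v.task, v.channel) for v in values})
    for task, channel in keys:
        cell = [v.value_mmHg for v in values if v.task == task and v.channel == channel and v.valid]
        rows.append(
            {
                "task": task,
                "channel": channel,
                "mean_mmHg": float(np.mean(cell)) if cell else np.nan,
                "n_valid": len(cell),
                "missing": len(cell) == 0,
            }
        )
    return TrialSummary(pd.DataFrame(rows))
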