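"""File formats: tidy-CSV traces, analog CSV, window/config/truth JSON.

All files are plain text: comma-separated UTF-8 CSV with a mandatory
header and "." decimals, and JSON with an explicit ``schema_version``.
Time is in seconds from session start; cue onsets are stored explicitly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CHANNELS, TASKS, PressureTrace, TrialWindow
from .sensor_sim import GroundTruth, Session, SimConfig, TruthRecord
from .signal_core import StableValue

SCHEMA_VERSION = 1

TRACE_COLUMNS = ["session_id", "task", "trial", "channel", "time_s", "pressure_mmHg"]
ANALOG_COLUMNS = ["session_id", "task", "trial", "channel", "analog_mmHg"]

__all__ = [
    "SessionBundle",
    "traces_to_frame",
    "write_session_bundle",
    "read_traces",
    "read_windows",
    "read_analog",
    "read_config",
    "read_truth",
    "write_stable_values",
    "read_stable_values",
]


@dataclass(frozen=True)
class SessionBundle:
    """Paths of the files that make up one stored session."""

    traces_csv: Path
    windows_json: Path
    analog_csv: Path
    config_json: Path
    truth_json: Path | None = None

    @classmethod
    def in_dir(cls, directory: Path | str, with_truth: bool = True) -> "SessionBundle":
        d = Path(directory)
        truth = d / "truth.json"
        return cls(
            traces_csv=d / "traces.csv",
            windows_json=d / "windows.json",
            analog_csv=d / "analog.csv",
            config_json=d / "config.json",
            truth_json=truth if (with_truth and truth.exists()) or with_truth else None,
        )

    def validate(self) -> None:
        for p in (self.traces_csv, self.windows_json, self.analog_csv, self.config_json):
            if not Path(p).exists():
                raise FileNotFoundError(f"bundle file missing: {p}")


def _window_label(windows: list[TrialWindow], t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Task / trial labels per sample: the enclosing trial window, or
    rest ('--', 0) between windows."""
    task = np.full(t.shape, "--", dtype=object)
    trial = np.zeros(t.shape, dtype=int)
    for w in windows:
        sel = (t >= w.cue_onset_s) & (t <= w.end_s)
        task[sel] = w.task
        trial[sel] = w.trial_index
    return task, trial


def traces_to_frame(session: Session) -> pd.DataFrame:
    """Tidy long table of all channels' digital samples."""
    frames = []
    for ch in CHANNELS:
        trace = session.traces[ch]
        t = trace.times
        task, trial = _window_label(session.windows, t)
        frames.append(
            pd.DataFrame(
                {
                    "session_id": session.session_id,
                    "task": task,
                    "trial": trial,
                    "channel": ch,
                    "time_s": t,
                    "pressure_mmHg": trace.samples,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _config_to_dict(config: SimConfig) -> dict:
    return {"schema_version": SCHEMA_VERSION, **dataclasses.asdict(config)}


def write_session_bundle(session: Session, directory: Path | str) -> SessionBundle:
    """Write one session's traces, windows, analog readings, config and
    ground truth to ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    traces_to_frame(session).to_csv(d / "traces.csv", index=False)
    pd.DataFrame(
        [
            {
                "session_id": session.session_id,
                "task": r.task,
                "trial": r.trial_index,
                "channel": r.channel,
                "analog_mmHg": r.value_mmHg,
            }
            for r in session.analog
        ]
    ).to_csv(d / "analog.csv", index=False)
    windows = {
        "schema_version": SCHEMA_VERSION,
        "session_id": session.session_id,
        "windows": [dataclasses.asdict(w) for w in session.windows],
    }
    (d / "windows.json").write_text(json.dumps(windows, indent=2))
    (d / "config.json").write_text(json.dumps(_config_to_dict(session.config), indent=2))
    truth = {
        "schema_version": SCHEMA_VERSION,
        "session_id": session.session_id,
        "warnings": session.truth.warnings,
        "records": [dataclasses.asdict(r) for r in session.truth.records],
    }
    (d / "truth.json").write_text(json.dumps(truth, indent=2))
    return SessionBundle.in_dir(d)


def read_traces(path: Path | str, rate_tolerance: float = 1e-3) -> tuple[dict[str, PressureTrace], str]:
    """Read a tidy trace CSV into per-channel traces.

    The sampling rate is inferred from the timestamps of each channel
    and checked for uniformity to ``rate_tolerance`` (relative).
    Returns ``(traces, session_id)``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[~df.channel.isin(CHANNELS)]
    if not bad.empty:
        row = bad.index[0]
        raise ValueError(
            f"{path}: unknown channel {bad.iloc[0].channel!r} at row {row + 2}"
        )
    bad = df[~df.task.isin(TASKS + ("--",))]
    if not bad.empty:
        row = bad.index[0]
        raise ValueError(f"{path}: unknown task {bad.iloc[0].task!r} at row {row + 2}")
    session_ids = df.session_id.unique()
    if len(session_ids) != 1:
        raise ValueError(f"{path}: expected one session_id, found {list(session_ids)}")
    traces: dict[str, PressureTrace] = {}
    for ch, sub in df.groupby("channel", sort=False):
        t = sub.time_s.to_numpy(float)
        dt = np.diff(t)
        if dt.size == 0:
            raise ValueError(f"{path}: channel {ch} has a single sample")
        med = float(np.median(dt))
        if med <= 0:
            raise ValueError(f"{path}: channel {ch} timestamps are not increasing")
        off = np.abs(dt - med) / med
        if np.any(off > rate_tolerance):
            k = int(np.argmax(off))
            raise ValueError(
                f"{path}: non-uniform sampling for channel {ch} near "
                f"t={t[k]:.4f} s (dt={dt[k]:.6f} s vs median {med:.6f} s)"
            )
        traces[str(ch)] = PressureTrace(
            str(ch), 1.0 / med, float(t[0]), sub.pressure_mmHg.to_numpy(float)
        )
    return traces, str(session_ids[0])


def read_windows(path: Path | str) -> list[TrialWindow]:
    data = json.loads(Path(path).read_text())
    return [
        TrialWindow(
            task=w["task"],
            trial_index=int(w["trial_index"]),
            cue_onset_s=float(w["cue_onset_s"]),
            hold_duration_s=float(w["hold_duration_s"]),
        )
        for w in data["windows"]
    ]


def read_analog(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(ANALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_config(path: Path | str) -> SimConfig:
    data = json.loads(Path(path).read_text())
    data.pop("schema_version", None)
    return SimConfig(**data)


def read_truth(path: Path | str) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(
        records=[TruthRecord(**r) for r in data["records"]],
        warnings=list(data.get("warnings", [])),
    )


def write_stable_values(
    values: list[StableValue], path: Path | str, session_id: str
) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "session_id": session_id,
                "task": v.task,
                "trial": v.trial_index,
                "channel": v.channel,
                "digital_mmHg": v.value_mmHg,
                "direction": v.direction,
                "baseline_mmHg": v.baseline_mmHg,
                "t_peak_velocity_s": v.t_peak_velocity_s,
                "t_zero_cross_s": v.t_zero_cross_s,
                "avg_start_s": v.avg_window_s[0],
                "avg_end_s": v.avg_window_s[1],
                "valid": v.valid,
                "invalid_reason": v.invalid_reason or "",
            }
            for v in values
        ]
    )
    df.to_csv(path, index=False)
    return df


def read_stable_values(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    df["valid"] = df["valid"].astype(bool)
    df["invalid_reason"] = df["invalid_reason"].fillna("")
    return df
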