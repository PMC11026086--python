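"""Task-compliance classification from per-channel pressure changes.

Each bridging task implies a fixed direction pattern across the four
channels: a bilateral bridge raises both knee pressures and lowers both
back pressures; a unilateral bridge raises only the working-side knee
while the opposite knee must not rise. A trial is compliant when every
channel's stable-pressure change relative to its pre-trial baseline
matches the pattern beyond a threshold.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .types import CHANNELS, validate_task
from .signal_core import StableValue

__all__ = [
    "ExpectedPattern",
    "ComplianceResult",
    "expected_pattern",
    "classify_trial",
    "trial_deltas",
    "classify_session",
    "compliance_summary",
    "DEFAULT_THRESHOLD_MMHG",
]

#: Minimum pressure change (mmHg) counted as a real increase/decrease.
#: Matches the scale of digital-analog agreement (mean differences below
#: 3 mmHg), so compliance is never asserted below measurement agreement.
DEFAULT_THRESHOLD_MMHG = 3.0

_PATTERNS: dict[str, dict[str, str]] = {
    "BB": {"RK": "increase", "LK": "increase", "RB": "decrease", "LB": "decrease"},
    "URB": {"RK": "increase", "LK": "no_increase", "RB": "decrease", "LB": "decrease"},
    "ULB": {"RK": "no_increase", "LK": "increase", "RB": "decrease", "LB": "decrease"},
}


@dataclass(frozen=True)
class ExpectedPattern:
    """Required pressure-change direction per channel for one task."""

    task: str
    directions: dict[str, str]


@dataclass(frozen=True)
class ComplianceResult:
    """Outcome of checking one trial against its task's pattern.

    ``compliant`` is ``None`` when the trial could not be assessed
    (a channel delta was missing), which is distinct from non-compliant.
    """

    task: str
    trial_index: int
    deltas: dict[str, float]
    channel_pass: dict[str, bool]
    compliant: bool | None
    assessable: bool


def expected_pattern(task: str) -> ExpectedPattern:
    """The fixed expected-direction table for ``task``."""
    validate_task(task)
    return ExpectedPattern(task, dict(_PATTERNS[task]))


def _passes(direction: str, delta: float, threshold: float) -> bool:
    if direction == "increase":
        return delta >= threshold
    if direction == "decrease":
        return delta <= -threshold
    if direction == "no_increase":
        return delta < threshold
    raise ValueError(f"unknown direction {direction!r}")


def classify_trial(
    deltas: dict[str, float],
    task: str,
    trial_index: int = 0,
    threshold_mmHg: float = DEFAULT_THRESHOLD_MMHG,
) -> ComplianceResult:
    """Classify one trial from its per-channel pressure changes.

    ``deltas`` maps channel to (stable value - pre-trial baseline) in
    mmHg. A missing channel makes the trial non-assessable.
    """
    pattern = expected_pattern(task)
    if threshold_mmHg <= 0:
        raise ValueError("threshold_mmHg must be positive")
    missing = [ch for ch in CHANNELS if ch not in deltas or pd.isna(deltas[ch])]
    if missing:
        present = {ch: float(deltas[ch]) for ch in deltas if ch in CHANNELS and not pd.isna(deltas[ch])}
        return ComplianceResult(task, trial_index, present, {}, compliant=None, assessable=False)
    flags = {
        ch: _passes(pattern.directions[ch], float(deltas[ch]), threshold_mmHg) for ch in CHANNELS
    }
    return ComplianceResult(
        task,
        trial_index,
        {ch: float(deltas[ch]) for ch in CHANNELS},
        flags,
        compliant=all(flags.values()),
        assessable=True,
    )


def trial_deltas(values: list[StableValue]) -> dict[tuple[str, int], dict[str, float]]:
    """Per-trial channel deltas (stable value - pre-cue baseline) from
    extracted stable values; invalid extractions leave their channel out."""
    out: dict[tuple[str, int], dict[str, float]] = defaultdict(dict)
    for v in values:
        d = v.delta_mmHg
        if d is not None:
            out[(v.task, v.trial_index)][v.channel] = d
    return dict(out)


def classify_session(
    values: list[StableValue], threshold_mmHg: float = DEFAULT_THRESHOLD_MMHG
) -> list[ComplianceResult]:
    """Classify every trial of a session from its stable values."""
    deltas = trial_deltas(values)
    trials = sorted({(v.task, v.trial_index) for v in values})
    return [
        classify_trial(deltas.get(key, {}), key[0], key[1], threshold_mmHg) for key in trials
    ]


def compliance_summary(results: list[ComplianceResult]) -> pd.DataFrame:
    """Per-task counts of compliant / non-compliant / non-assessable."""
    rows = []
    for task in sorted({r.task for r in results}):
        sub = [r for r in results if r.task == task]
        rows.append(
            {
                "task": task,
                "n_trials": len(sub),
                "n_compliant": sum(1 for r in sub if r.compliant is True),
                "n_non_compliant": sum(1 for r in sub if r.compliant is False),
                "n_non_assessable": sum(1 for r in sub if not r.assessable),
            }
        )
    return pd.DataFrame(rows)
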