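"""Concurrent-validity statistics for paired digital/analog pressures.

Implements the method-comparison toolkit used to validate the digital
pressure stream against the analog gauges: Shapiro-Wilk normality
screening, Spearman rank correlation with a Fisher-z confidence interval
(Bonett-Wright standard error), Bland-Altman agreement statistics, the
Fisher-z a priori power analysis for comparing two correlations, and a
report builder that assembles all of it per task x sensor cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import CHANNELS, TASKS, validate_channel, validate_task

__all__ = [
    "PairedStableSet",
    "NormalityResult",
    "SpearmanResult",
    "BlandAltmanResult",
    "PowerSpec",
    "ValidityReport",
    "normality_screen",
    "spearman_with_ci",
    "bland_altman",
    "required_sample_size",
    "build_validity_report",
    "ACCEPTABILITY_RHO",
    "REFERENCE_VALIDITY_RHO",
]

#: Minimum correlation for the system to count as acceptable for
#: research use (the pre-registered acceptability rule).
ACCEPTABILITY_RHO = 0.9

#: Digital-analog Spearman correlations reported in the original
#: validation experiment of the four-sensor system, per task x channel.
#: Kept as reference context: the smallest implies that >87% of analog
#: pressure variance is explained by the digital stream.
REFERENCE_VALIDITY_RHO: dict[tuple[str, str], float] = {
    ("BB", "RK"): 0.970,
    ("BB", "RB"): 0.962,
    ("BB", "LK"): 0.937,
    ("BB", "LB"): 0.969,
    ("URB", "RK"): 0.945,
    ("URB", "RB"): 0.974,
    ("URB", "LK"): 0.962,
    ("URB", "LB"): 0.978,
    ("ULB", "RK"): 0.968,
    ("ULB", "RB"): 0.983,
    ("ULB", "LK"): 0.983,
    ("ULB", "LB"): 0.974,
}


@dataclass(frozen=True)
class PairedStableSet:
    """Aligned (digital, analog) stable pressures for one sensor x task."""

    sensor: str
    task: str
    digital: np.ndarray
    analog: np.ndarray
    pairing_level: str = "trial"  # or "participant"

    def __post_init__(self) -> None:
        validate_channel(self.sensor)
        validate_task(self.task)
        if self.pairing_level not in ("trial", "participant"):
            raise ValueError("pairing_level must be 'trial' or 'participant'")
        d = np.asarray(self.digital, dtype=float)
        a = np.asarray(self.analog, dtype=float)
        if d.shape != a.shape or d.ndim != 1:
            raise ValueError("digital and analog must be aligned 1-D arrays")
        object.__setattr__(self, "digital", d)
        object.__setattr__(self, "analog", a)

    @property
    def n(self) -> int:
        return self.digital.size


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    normal: bool
    degenerate: bool = False


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int
    p_value: float


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement statistics on differences d = digital - analog."""

    bias_mmHg: float
    sd_diff_mmHg: float
    loa_low: float
    loa_high: float
    n: int
    n_outside_loa: int
    proportional_bias_slope: float
    proportional_bias_p: float


@dataclass(frozen=True)
class PowerSpec:
    """A priori power analysis for distinguishing two correlations."""

    rho_h1: float = 0.9
    rho_h0: float = 0.7
    power: float = 0.80
    alpha: float = 0.05
    tails: str = "one"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if not -1 < self.rho_h0 < 1 or not -1 < self.rho_h1 < 1:
            raise ValueError("correlations must lie in (-1, 1)")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")


def normality_screen(values, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk screen; ``normal`` iff p > alpha.

    Constant input is flagged degenerate and non-normal rather than
    raising, since real plateau data can degenerate under quantization.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for a normality screen")
    if np.ptp(x) == 0:
        return NormalityResult(math.nan, math.nan, normal=False, degenerate=True)
    stat, p = stats.shapiro(x)
    return NormalityResult(float(stat), float(p), normal=bool(p > alpha))


def _fisher_ci(rho: float, n: int, alpha: float) -> tuple[float, float]:
    """Fisher-z CI for a Spearman rho with the Bonett-Wright standard
    error sqrt((1 + rho^2/2) / (n - 3))."""
    if abs(rho) >= 1.0 - 1e-12:
        return (rho, rho)  # degenerate: perfect monotone association
    z = math.atanh(rho)
    se = math.sqrt((1.0 + rho**2 / 2.0) / (n - 3))
    zc = stats.norm.ppf(1.0 - alpha / 2.0)
    return (math.tanh(z - zc * se), math.tanh(z + zc * se))


def spearman_with_ci(
    pairs: PairedStableSet,
    alpha: float = 0.05,
    method: str = "fisher",
    n_boot: int = 2000,
    seed: int | None = None,
) -> SpearmanResult:
    """Spearman rho (average ranks for ties) with a 95% CI.

    ``method='fisher'`` (default) uses the Fisher-z interval with the
    Bonett-Wright standard error; ``method='bootstrap'`` a seeded
    percentile bootstrap over pairs.
    """
    if pairs.n < 4:
        raise ValueError(
            f"cell ({pairs.task}, {pairs.sensor}): need at least 4 pairs, got {pairs.n}"
        )
    if np.ptp(pairs.digital) == 0 or np.ptp(pairs.analog) == 0:
        raise ValueError(
            f"cell ({pairs.task}, {pairs.sensor}): zero rank variance, "
            "correlation undefined"
        )
    res = stats.spearmanr(pairs.digital, pairs.analog)
    rho, p = float(res.statistic), float(res.pvalue)
    if method == "fisher":
        lo, hi = _fisher_ci(rho, pairs.n, alpha)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, pairs.n, size=(n_boot, pairs.n))
        reps = np.array(
            [stats.spearmanr(pairs.digital[i], pairs.analog[i]).statistic for i in idx]
        )
        reps = reps[np.isfinite(reps)]
        lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        lo, hi = min(float(lo), rho), max(float(hi), rho)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return SpearmanResult(rho=rho, ci_low=lo, ci_high=hi, n=pairs.n, p_value=p)


def bland_altman(pairs: PairedStableSet) -> BlandAltmanResult:
    """Bland-Altman agreement: bias = mean(d), limits of agreement
    bias +/- 1.96 sd(d) (sample SD), d = digital - analog; proportional
    bias from a straight-line fit of d against the pair means."""
    if pairs.n < 4:
        raise ValueError(
            f"cell ({pairs.task}, {pairs.sensor}): need at least 4 pairs, got {pairs.n}"
        )
    d = pairs.digital - pairs.analog
    m = 0.5 * (pairs.digital + pairs.analog)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    outside = int(np.sum((d < lo) | (d > hi)))
    if np.ptp(m) == 0 or np.ptp(d) == 0:
        slope, slope_p = (0.0, math.nan) if np.ptp(d) == 0 else (math.nan, math.nan)
    else:
        fit = stats.linregress(m, d)
        slope, slope_p = float(fit.slope), float(fit.pvalue)
    return BlandAltmanResult(
        bias_mmHg=bias,
        sd_diff_mmHg=sd,
        loa_low=lo,
        loa_high=hi,
        n=pairs.n,
        n_outside_loa=outside,
        proportional_bias_slope=slope,
        proportional_bias_p=slope_p,
    )


def required_sample_size(spec: PowerSpec | None = None, **kwargs) -> int:
    """Fisher-z sample size for detecting rho_h1 against rho_h0.

    n = ceil( ((z_crit + z_power) / (atanh(rho_h1) - atanh(rho_h0)))^2 + 3 )

    with z_crit = z_{1-alpha} one-tailed or z_{1-alpha/2} two-tailed.
    With the defaults (0.9 vs 0.7, power 0.80, one-tailed alpha 0.05)
    this gives 20 participants.
    """
    spec = spec if spec is not None else PowerSpec(**kwargs)
    q = math.atanh(spec.rho_h1) - math.atanh(spec.rho_h0)
    if q == 0:
        raise ValueError("rho_h1 equals rho_h0: zero effect size")
    z_crit = stats.norm.ppf(1 - spec.alpha) if spec.tails == "one" else stats.norm.ppf(
        1 - spec.alpha / 2
    )
    z_pow = stats.norm.ppf(spec.power)
    return int(math.ceil(((z_crit + z_pow) / q) ** 2 + 3))


@dataclass
class CellValidity:
    """All validity statistics for one task x sensor cell."""

    task: str
    sensor: str
    n: int
    digital_mean: float = math.nan
    digital_sd: float = math.nan
    analog_mean: float = math.nan
    analog_sd: float = math.nan
    spearman: SpearmanResult | None = None
    agreement: BlandAltmanResult | None = None
    pairs: PairedStableSet | None = None
    missing: bool = False
    missing_reason: str | None = None


@dataclass
class ValidityReport:
    """Per-cell validity statistics plus acceptability flags.

    ``flags`` lists cells whose correlation falls below the
    acceptability threshold; ``n_tests`` counts the correlation tests
    run (p-values are reported raw, without multiplicity correction).
    """

    cells: dict[tuple[str, str], CellValidity]
    pairing_level: str
    acceptability_rho: float
    flags: list[tuple[str, str]] = field(default_factory=list)
    n_tests: int = 0

    def summary_frame(self) -> pd.DataFrame:
        """Means/SDs per task x sensor x modality (descriptive table)."""
        rows = []
        for (task, sensor), c in sorted(self.cells.items()):
            rows.append(
                {
                    "task": task,
                    "sensor": sensor,
                    "n": c.n,
                    "digital_mean": c.digital_mean,
                    "digital_sd": c.digital_sd,
                    "analog_mean": c.analog_mean,
                    "analog_sd": c.analog_sd,
                    "missing": c.missing,
                }
            )
        return pd.DataFrame(rows)

    def correlation_frame(self) -> pd.DataFrame:
        rows = []
        for (task, sensor), c in sorted(self.cells.items()):
            s = c.spearman
            rows.append(
                {
                    "task": task,
                    "sensor": sensor,
                    "n": c.n,
                    "rho": s.rho if s else math.nan,
                    "ci_low": s.ci_low if s else math.nan,
                    "ci_high": s.ci_high if s else math.nan,
                    "p_value": s.p_value if s else math.nan,
                    "acceptable": (s.rho >= self.acceptability_rho) if s else False,
                }
            )
        return pd.DataFrame(rows)

    def agreement_frame(self) -> pd.DataFrame:
        rows = []
        for (task, sensor), c in sorted(self.cells.items()):
            b = c.agreement
            rows.append(
                {
                    "task": task,
                    "sensor": sensor,
                    "n": c.n,
                    "bias_mmHg": b.bias_mmHg if b else math.nan,
                    "sd_diff_mmHg": b.sd_diff_mmHg if b else math.nan,
                    "loa_low": b.loa_low if b else math.nan,
                    "loa_high": b.loa_high if b else math.nan,
                    "prop_bias_slope": b.proportional_bias_slope if b else math.nan,
                    "prop_bias_p": b.proportional_bias_p if b else math.nan,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def _clean(x):
            if isinstance(x, float) and not math.isfinite(x):
                return None
            return x

        out = {
            "pairing_level": self.pairing_level,
            "acceptability_rho": self.acceptability_rho,
            "n_tests": self.n_tests,
            "flagged_cells": [list(f) for f in self.flags],
            "cells": {},
        }
        for (task, sensor), c in sorted(self.cells.items()):
            cell: dict = {
                "n": c.n,
                "missing": c.missing,
                "missing_reason": c.missing_reason,
                "digital_mean": _clean(c.digital_mean),
                "analog_mean": _clean(c.analog_mean),
            }
            if c.spearman:
                cell["spearman"] = {
                    "rho": c.spearman.rho,
                    "ci_low": c.spearman.ci_low,
                    "ci_high": c.spearman.ci_high,
                    "p_value": c.spearman.p_value,
                }
            if c.agreement:
                cell["bland_altman"] = {
                    "bias_mmHg": c.agreement.bias_mmHg,
                    "sd_diff_mmHg": _clean(c.agreement.sd_diff_mmHg),
                    "loa_low": _clean(c.agreement.loa_low),
                    "loa_high": _clean(c.agreement.loa_high),
                }
            out["cells"][f"{task}:{sensor}"] = cell
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


_KEYS = ["session_id", "task", "trial", "channel"]


def _check_alignment(merged: pd.DataFrame, task: str, channel: str) -> None:
    sub = merged[(merged.task == task) & (merged.channel == channel)]
    bad = sub[sub.digital_mmHg.isna() | sub.analog_mmHg.isna()]
    matched = len(sub) - len(bad)
    if len(bad) and matched:
        keys = bad[_KEYS].to_records(index=False).tolist()[:10]
        raise ValueError(
            f"cell ({task}, {channel}): {len(bad)} unmatched digital/analog "
            f"rows, e.g. {keys}"
        )


def build_validity_report(
    digital: pd.DataFrame,
    analog: pd.DataFrame,
    pairing_level: str = "trial",
    acceptability_rho: float = ACCEPTABILITY_RHO,
    alpha: float = 0.05,
    ci_method: str = "fisher",
) -> ValidityReport:
    """Assemble the full concurrent-validity report.

    Parameters
    ----------
    digital, analog : DataFrame
        Long tables with columns ``session_id, task, trial, channel`` and
        ``digital_mmHg`` / ``analog_mmHg`` respectively. Invalid digital
        rows (NaN) are dropped before pairing.
    pairing_level : str
        ``'trial'`` pairs each repetition; ``'participant'`` first
        averages over the repetitions of each session x task x channel.

    Cells entirely absent from one modality (or with fewer than 4 pairs)
    are marked missing; partially unmatched cells raise, listing the
    offending keys.
    """
    if pairing_level not in ("trial", "participant"):
        raise ValueError("pairing_level must be 'trial' or 'participant'")
    dig = digital.dropna(subset=["digital_mmHg"]).copy()
    ana = analog.dropna(subset=["analog_mmHg"]).copy()
    for df, col in ((dig, "digital_mmHg"), (ana, "analog_mmHg")):
        missing_cols = set(_KEYS + [col]) - set(df.columns)
        if missing_cols:
            raise ValueError(f"input table missing columns {sorted(missing_cols)}")

    if pairing_level == "participant":
        group = ["session_id", "task", "channel"]
        dig = dig.groupby(group, as_index=False)["digital_mmHg"].mean()
        ana = ana.groupby(group, as_index=False)["analog_mmHg"].mean()
        dig["trial"] = 0
        ana["trial"] = 0

    merged = dig.merge(ana, on=_KEYS, how="outer")
    cells: dict[tuple[str, str], CellValidity] = {}
    flags: list[tuple[str, str]] = []
    n_tests = 0
    for task in TASKS:
        for sensor in CHANNELS:
            sub = merged[(merged.task == task) & (merged.channel == sensor)]
            if sub.empty or sub.digital_mmHg.isna().all() or sub.analog_mmHg.isna().all():
                cells[(task, sensor)] = CellValidity(
                    task, sensor, n=0, missing=True, missing_reason="no_paired_data"
                )
                continue
            _check_alignment(merged, task, sensor)
            d = sub.digital_mmHg.to_numpy(float)
            a = sub.analog_mmHg.to_numpy(float)
            if d.size < 4:
                cells[(task, sensor)] = CellValidity(
                    task, sensor, n=int(d.size), missing=True, missing_reason="insufficient_n"
                )
                continue
            pairs = PairedStableSet(sensor, task, d, a, pairing_level)
            sp = spearman_with_ci(pairs, alpha=alpha, method=ci_method, seed=0)
            ba = bland_altman(pairs)
            n_tests += 1
            cells[(task, sensor)] = CellValidity(
                task,
                sensor,
                n=pairs.n,
                digital_mean=float(d.mean()),
                digital_sd=float(d.std(ddof=1)),
                analog_mean=float(a.mean()),
                analog_sd=float(a.std(ddof=1)),
                spearman=sp,
                agreement=ba,
                pairs=pairs,
            )
            if sp.rho < acceptability_rho:
                flags.append((task, sensor))
    return ValidityReport(
        cells=cells,
        pairing_level=pairing_level,
        acceptability_rho=acceptability_rho,
        flags=flags,
        n_tests=n_tests,
    )
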