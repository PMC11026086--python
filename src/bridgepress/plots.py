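"""Bland-Altman panels for the validity report."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .validity import ValidityReport


def bland_altman_axes(report: ValidityReport, task: str, sensor: str, ax=None):
    """One Bland-Altman scatter: pair means on x, digital - analog on y,
    with bias and limits-of-agreement lines."""
    cell = report.cells[(task, sensor)]
    if cell.missing or cell.pairs is None or cell.agreement is None:
        raise ValueError(f"cell ({task}, {sensor}) has no paired data to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    d = cell.pairs.digital - cell.pairs.analog
    m = 0.5 * (cell.pairs.digital + cell.pairs.analog)
    ba = cell.agreement
    ax.scatter(m, d, s=12, alpha=0.6, edgecolor="none")
    ax.axhline(ba.bias_mmHg, color="k", lw=1.2, label=f"bias {ba.bias_mmHg:.2f}")
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="k", lw=0.8, ls="--")
    ax.set_xlabel("mean of methods (mmHg)")
    ax.set_ylabel("digital − analog (mmHg)")
    ax.set_title(f"{task} · {sensor}")
    return ax


def save_bland_altman_panels(report: ValidityReport, out_dir: Path | str) -> list[Path]:
    """Write one PNG per non-missing task x sensor cell; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for (task, sensor), cell in sorted(report.cells.items()):
        if cell.missing:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        bland_altman_axes(report, task, sensor, ax=ax)
        fig.tight_layout()
        p = out / f"bland_altman_{task}_{sensor}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
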