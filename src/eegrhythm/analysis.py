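"""Descriptive contrasts over the feature table.

Three comparisons: left- vs right-hemisphere band ratio over homologous
electrode pairs, task-vs-task band ratio per channel, and trained- vs
untrained-group band ratio across subjects; plus per-region summaries.
All contrasts are descriptive (group means and paired differences with a
direction flag) — no inferential statistics are attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import pandas as pd

from .record_io import Montage, default_montage

__all__ = [
    "ContrastReport",
    "group_contrast",
    "hemispheric_contrast",
    "plot_band_ratio_bars",
    "region_summary",
    "task_contrast",
]


@dataclass(frozen=True)
class ContrastReport:
    """Outcome of one descriptive contrast.

    ``group_means`` maps group label to its mean energy ratio;
    ``pair_differences`` holds the paired per-unit differences (e.g.
    Fp1-Fp2 for a hemispheric contrast, per-channel for a task contrast);
    ``direction`` names the group with the larger mean.
    """

    band: str
    grouping: str
    group_means: Dict[str, float]
    pair_differences: Dict[str, float] = field(default_factory=dict)
    n_per_group: Dict[str, int] = field(default_factory=dict)

    @property
    def direction(self) -> str:
        return max(self.group_means, key=self.group_means.get)

    @property
    def mean_difference(self) -> float:
        """First-listed group mean minus the second (two-group contrasts)."""
        keys = list(self.group_means)
        if len(keys) == 1:  # a group contrasted with itself
            return 0.0
        if len(keys) != 2:
            raise ValueError("mean_difference is defined for two groups")
        return self.group_means[keys[0]] - self.group_means[keys[1]]

    def summary(self) -> str:
        lines = [f"{self.grouping} contrast, {self.band} band:"]
        for g, m in self.group_means.items():
            n = self.n_per_group.get(g)
            lines.append(f"  {g}: mean ratio {m:.4f}" +
                         (f" (n={n})" if n is not None else ""))
        for pair, d in self.pair_differences.items():
            lines.append(f"  {pair}: {d:+.4f}")
        lines.append(f"  larger: {self.direction}")
        return "\n".join(lines)


def _band_slice(
    table: pd.DataFrame, band: str, task: Optional[str] = None
) -> pd.DataFrame:
    sub = table[table["band"] == band]
    if task is not None:
        sub = sub[sub["task"] == task]
    if sub.empty:
        raise ValueError(
            f"feature table has no rows for band {band!r}"
            + (f", task {task!r}" if task else "")
        )
    return sub


def _channel_means(sub: pd.DataFrame) -> pd.Series:
    """Mean ratio per channel over whatever testers/tasks are in the slice."""
    return sub.groupby("channel")["energy_ratio"].mean()


def hemispheric_contrast(
    table: pd.DataFrame,
    band: str = "beta",
    task: Optional[str] = None,
    montage: Montage | None = None,
) -> ContrastReport:
    """Left vs right hemisphere mean band ratio over homologous pairs.

    Reports the left-minus-right difference for each electrode pair
    (Fp1-Fp2, T3-T4, C3-C4, O1-O2) and the two hemisphere means.
    """
    montage = montage or default_montage()
    sub = _band_slice(table, band, task)
    means = _channel_means(sub)
    missing = [c for c in montage.channels if c not in means.index]
    if missing:
        raise ValueError(f"feature table lacks channels: {missing}")
    pairs = {
        f"{lft}-{rgt}": float(means[lft] - means[rgt])
        for lft, rgt in montage.homologous_pairs
    }
    left = montage.side("left")
    right = montage.side("right")
    return ContrastReport(
        band=band,
        grouping="hemisphere",
        group_means={
            "left": float(means[list(left)].mean()),
            "right": float(means[list(right)].mean()),
        },
        pair_differences=pairs,
        n_per_group={"left": len(left), "right": len(right)},
    )


def task_contrast(
    table: pd.DataFrame,
    band: str,
    task_a: str,
    task_b: str,
) -> ContrastReport:
    """Per-channel band-ratio difference between two tasks (a minus b)."""
    means_a = _channel_means(_band_slice(table, band, task_a))
    means_b = _channel_means(_band_slice(table, band, task_b))
    common = [c for c in means_a.index if c in means_b.index]
    if not common:
        raise ValueError("the two tasks share no channels")
    diffs = {c: float(means_a[c] - means_b[c]) for c in common}
    return ContrastReport(
        band=band,
        grouping="task",
        group_means={
            task_a: float(means_a[common].mean()),
            task_b: float(means_b[common].mean()),
        },
        pair_differences=diffs,
        n_per_group={task_a: len(common), task_b: len(common)},
    )


def n_channels_larger(report: ContrastReport) -> int:
    """How many paired differences favour the first group."""
    return sum(1 for d in report.pair_differences.values() if d > 0)


def group_contrast(
    table: pd.DataFrame,
    groups: Mapping[int, str],
    band: str = "beta",
) -> ContrastReport:
    """Trained- vs untrained-group mean band ratio across subjects.

    ``groups`` maps tester id to a group label; the table must carry a
    ``tester`` column.  Per-subject means are listed as pair differences
    under the subject's id for inspection.
    """
    if "tester" not in table.columns:
        raise ValueError("group_contrast needs a per-subject feature table")
    sub = _band_slice(table, band)
    per_subject = sub.groupby("tester")["energy_ratio"].mean()
    labels = {}
    for tid, value in per_subject.items():
        if tid not in groups:
            raise ValueError(f"tester {tid} has no group assignment")
        labels.setdefault(groups[tid], []).append((tid, float(value)))
    if len(labels) < 2:
        raise ValueError("need at least one subject in each of two groups")
    return ContrastReport(
        band=band,
        grouping="training",
        group_means={
            g: sum(v for _, v in vals) / len(vals)
            for g, vals in labels.items()
        },
        pair_differences={
            f"tester {tid}": v for vals in labels.values() for tid, v in vals
        },
        n_per_group={g: len(vals) for g, vals in labels.items()},
    )


def region_summary(
    table: pd.DataFrame,
    band: str = "beta",
    task: Optional[str] = None,
    montage: Montage | None = None,
) -> pd.DataFrame:
    """Mean band ratio per scalp region, one row per region.

    The left-parietal pair (T3, C3) is reported as an extra row because the
    hemispheric and regional effects compound there.
    """
    montage = montage or default_montage()
    means = _channel_means(_band_slice(table, band, task))
    rows = []
    for region in ("frontal", "parietal", "occipital"):
        chans = [c for c in montage.in_region(region) if c in means.index]
        if chans:
            rows.append({
                "region": region,
                "mean_energy_ratio": float(means[chans].mean()),
                "channels": ",".join(chans),
            })
    lp = [c for c in ("T3", "C3") if c in means.index]
    if lp:
        rows.append({
            "region": "left-parietal",
            "mean_energy_ratio": float(means[lp].mean()),
            "channels": ",".join(lp),
        })
    return pd.DataFrame(rows)


def plot_band_ratio_bars(
    table: pd.DataFrame,
    band: str = "beta",
    tasks: Optional[Sequence[str]] = None,
    path: str | Path | None = None,
):
    """Bar chart of one band's energy ratio per channel, grouped by task."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = _band_slice(table, band)
    tasks = list(tasks) if tasks else sorted(sub["task"].unique())
    channels = [c for c in default_montage().channels
                if c in sub["channel"].unique()]
    fig, ax = plt.subplots(figsize=(8, 4))
    width = 0.8 / len(tasks)
    for j, task in enumerate(tasks):
        means = _channel_means(sub[sub["task"] == task])
        ax.bar(
            [i + j * width for i in range(len(channels))],
            [means.get(c, float("nan")) for c in channels],
            width=width,
            label=task,
        )
    ax.set_xticks([i + width * (len(tasks) - 1) / 2 for i in range(len(channels))])
    ax.set_xticklabels(channels)
    ax.set_ylabel(f"{band} energy ratio")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
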