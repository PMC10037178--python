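"""Optional figure regeneration (PNG artifacts; not part of any analysis result)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_hourly_histogram(hourly: pd.DataFrame, path: str | Path) -> Path:
    """Cohort count of measurements per local hour of day."""
    counts = hourly.groupby("hour")["count"].sum().reindex(range(24), fill_value=0)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(counts.index, counts.to_numpy(), color="#3b7ea1")
    ax.set_xlabel("hour of day (local)")
    ax.set_ylabel("measurements")
    ax.set_xticks(range(0, 24, 2))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_weight_trajectories(weight_points: pd.DataFrame, path: str | Path) -> Path:
    """Sliding-window weight averages per participant; flagged spans colored."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for pid, grp in weight_points.groupby("participant_id"):
        ts = pd.to_datetime(grp["timestamp"], utc=True)
        ax.plot(ts, grp["avg_value"], color="0.6", lw=0.8)
        for flag, color in (("LOSS", "tab:blue"), ("GAIN", "tab:red")):
            sel = grp["flag"] == flag
            if sel.any():
                ax.plot(ts[sel], grp.loc[sel, "avg_value"], ".", color=color, ms=4)
    ax.set_ylabel("window-averaged weight (kg)")
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_burden_histograms(per_scheme: dict[str, pd.DataFrame], path: str | Path) -> Path:
    """Histograms of alerts per day per participant, one panel per scheme/tier."""
    panels = [
        (name, tier, grp)
        for name, df in per_scheme.items()
        for tier, grp in df.groupby("tier")
    ]
    n = max(len(panels), 1)
    fig, axes = plt.subplots(n, 1, figsize=(6, 2.2 * n), squeeze=False)
    for ax, (name, tier, grp) in zip(axes.ravel(), panels):
        ax.hist(grp["alerts_per_day"], bins=30, color="#c2703d")
        ax.set_title(f"{name} tier {tier}+", fontsize=9)
        ax.set_xlabel("alerts per day")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
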