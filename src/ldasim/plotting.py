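"""Basic trajectory plot for a simulated feature."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .simulate import SimulatedDataset

__all__ = ["plot_trajectories"]

_COLORS = {"Control": "tab:blue", "Treatment": "tab:red"}


def plot_trajectories(
    dataset: SimulatedDataset,
    path: str | Path | None = None,
    use_observed: bool = True,
    ax: "plt.Axes | None" = None,
):
    """Per-subject trajectories with group-mean overlays.

    Plots ``Y_obs`` (or ``Y`` when ``use_observed`` is False) against time,
    one faint line per subject colored by arm, plus the per-timepoint group
    means as heavy lines. Saves to ``path`` (PNG/SVG by extension) when
    given, otherwise returns the axes.
    """
    col = "Y_obs" if use_observed else "Y"
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    rec = dataset.records
    for _, g in rec.groupby("ID"):
        ax.plot(
            g["time"], g[col], color=_COLORS[g["group"].iloc[0]], alpha=0.25, lw=0.8
        )
    for grp, g in rec.groupby("group"):
        means = g.groupby("time")[col].mean()
        ax.plot(means.index, means.values, color=_COLORS[grp], lw=2.5, label=grp)
    ax.set_xlabel("time")
    ax.set_ylabel("abundance (transformed scale)")
    ax.legend(title="group")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
        return None
    return ax
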