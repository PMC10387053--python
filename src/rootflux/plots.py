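"""Plotting hooks for depth profiles and carbon tables."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .carbon import CarbonProfile
from .profiles import DepthMeansProfile, DepthProfile

__all__ = ["plot_depth_profiles", "plot_carbon_profiles"]


def plot_depth_profiles(
    measured: Sequence[DepthMeansProfile],
    predicted: Mapping[str, DepthProfile] | None = None,
    path: str | Path | None = None,
):
    """Depth on the vertical axis (down), production on the horizontal.

    Measured means are drawn as points with SE bars; if LOESS-predicted
    profiles are given, they are drawn as the smooth curves.
    """
    fig, ax = plt.subplots(figsize=(5, 6))
    for prof in measured:
        ax.errorbar(
            prof.means, prof.midpoints_cm, xerr=prof.ses, fmt="o", capsize=3, label=prof.label
        )
        if predicted and prof.label in predicted:
            t = predicted[prof.label].table
            ax.plot(t["frp_mean"], t["depth_top_cm"] + 1.25, "-", alpha=0.7)
    ax.invert_yaxis()
    ax.set_xlabel("fine root production (m m$^{-2}$ mo$^{-1}$)")
    ax.set_ylabel("depth (cm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_carbon_profiles(profiles: Mapping[str, CarbonProfile], path: str | Path | None = None):
    """Per-section carbon flux with SE bars, one line per ecosystem."""
    fig, ax = plt.subplots(figsize=(5, 6))
    for eco, p in profiles.items():
        t = p.table
        ax.errorbar(
            t["carbon"], t["section_top_cm"] + 5.0, xerr=t["se"], fmt="o-", capsize=3,
            label=f"{eco} (total {p.total:.2f} ± {p.total_se:.2f})",
        )
    ax.invert_yaxis()
    ax.set_xlabel("fine root production (Mg C ha$^{-1}$ yr$^{-1}$)")
    ax.set_ylabel("depth (cm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
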