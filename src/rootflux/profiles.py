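"""Depth profiles: extrapolation of five measured depth means to 0–100 cm.

The measured design photographs five 2.5-cm windows (tops 0, 6, 16, 36,
71 cm).  To estimate production over a full 1-m profile the five depth
means are smoothed with LOESS against window midpoint, predicted at every
2.5-cm window midpoint down to 1 m (40 windows), clamped at zero, and
binned into ten 10-cm sections.  A depth-weighted profile mean over
0–75 cm uses the midpoint-partition weights, under which each measured
window represents the span of profile closer to it than to its
neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import MEASURED_DEPTH_TOPS_CM, MEASURED_MIDPOINTS_CM, DepthWindow, ObservationSet
from .loess import Loess, fit_loess

__all__ = [
    "PREDICTION_DEPTH_TOPS_CM",
    "DepthMeansProfile",
    "DepthProfile",
    "BinnedProfile",
    "depth_means_from_observations",
    "predict_grid",
    "bin_profile",
    "depth_weighted_mean",
    "midpoint_partition_weights",
]

#: Tops of the forty 2.5-cm prediction windows tiling 0–100 cm.
PREDICTION_DEPTH_TOPS_CM: tuple[float, ...] = tuple(
    float(t) for t in np.arange(0.0, 100.0, 2.5)
)


@dataclass(frozen=True)
class DepthMeansProfile:
    """Five (midpoint, mean, SE) triples for one ecosystem (or cell).

    ``label`` identifies the stratum, e.g. ``"palm_peat"`` or
    ``"palm_peat/long_dry"``.  Units m m⁻² mo⁻¹.
    """

    label: str
    midpoints_cm: tuple[float, ...]
    means: tuple[float, ...]
    ses: tuple[float, ...]

    def __post_init__(self) -> None:
        if tuple(self.midpoints_cm) != MEASURED_MIDPOINTS_CM:
            raise ValueError(
                f"expected the five measured midpoints {MEASURED_MIDPOINTS_CM}, "
                f"got {self.midpoints_cm}"
            )
        if len(self.means) != 5 or len(self.ses) != 5:
            raise ValueError("means and ses must each hold five values")
        if any(m < 0 for m in self.means) or any(s < 0 for s in self.ses):
            raise ValueError("means and SEs must be non-negative")

    @classmethod
    def from_table(cls, df: pd.DataFrame, label: str) -> "DepthMeansProfile":
        """Build from a frame with columns depth_top_cm, mean, se."""
        df = df.sort_values("depth_top_cm")
        mids = tuple(DepthWindow(t).midpoint_cm for t in df["depth_top_cm"])
        return cls(
            label=label,
            midpoints_cm=mids,
            means=tuple(float(v) for v in df["mean"]),
            ses=tuple(float(v) for v in df["se"]),
        )

    def smoothers(self, span: float = 1.0, degree: int = 1) -> tuple[Loess, Loess]:
        """LOESS smoothers for the mean profile and (same path) the SE profile."""
        x = np.asarray(self.midpoints_cm)
        return (
            fit_loess(x, np.asarray(self.means), span=span, degree=degree),
            fit_loess(x, np.asarray(self.ses), span=span, degree=degree),
        )


@dataclass(frozen=True)
class DepthProfile:
    """Predicted production for the forty 2.5-cm windows of a 1-m profile."""

    label: str
    table: pd.DataFrame  # columns: depth_top_cm, frp_mean, frp_se

    def __post_init__(self) -> None:
        if tuple(self.table["depth_top_cm"]) != PREDICTION_DEPTH_TOPS_CM:
            raise ValueError("profile must hold exactly the 40 prediction windows")
        if (self.table["frp_mean"] < 0).any() or (self.table["frp_se"] < 0).any():
            raise ValueError("predictions and SEs must be non-negative")


@dataclass(frozen=True)
class BinnedProfile:
    """Ten 10-cm sections, each the average of its four window predictions."""

    label: str
    table: pd.DataFrame  # columns: section_top_cm, frp_mean, frp_se

    def __post_init__(self) -> None:
        if list(self.table["section_top_cm"]) != [10.0 * i for i in range(10)]:
            raise ValueError("binned profile must hold ten 10-cm sections tiling 0-100 cm")


def depth_means_from_observations(
    obs: ObservationSet,
    by_season: bool = False,
) -> list[DepthMeansProfile]:
    """Raw per-(ecosystem[, season], depth) means and SEs of the observations.

    The SE is the standard error of the per-depth sample mean (all tubes ×
    intervals pooled), matching how the published measured-mean table is
    assembled (mean of 16 locations and three one-month measurements).
    """
    df = obs.to_frame()
    keys = ["ecosystem", "season"] if by_season else ["ecosystem"]
    out = []
    for group, sub in df.groupby(keys, observed=True, sort=True):
        group = group if isinstance(group, tuple) else (group,)
        g = (
            sub.groupby("depth_top_cm")["frp_length"]
            .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
            .reset_index()
        )
        out.append(DepthMeansProfile.from_table(g, label="/".join(str(k) for k in group)))
    return out


def predict_grid(mean_smoother: Loess, se_smoother: Loess | None = None, label: str = "") -> DepthProfile:
    """Evaluate fitted smoothers at the forty window midpoints to 1 m.

    Negative predictions are clamped to zero (production cannot be
    negative); beyond the deepest measured midpoint the boundary local fit
    extends and is clamped the same way.
    """
    mids = np.asarray(PREDICTION_DEPTH_TOPS_CM) + 1.25
    mean = np.clip(mean_smoother.predict(mids), 0.0, None)
    se = (
        np.clip(se_smoother.predict(mids), 0.0, None)
        if se_smoother is not None
        else np.zeros_like(mean)
    )
    return DepthProfile(
        label=label,
        table=pd.DataFrame(
            {"depth_top_cm": PREDICTION_DEPTH_TOPS_CM, "frp_mean": mean, "frp_se": se}
        ),
    )


def bin_profile(profile: DepthProfile) -> BinnedProfile:
    """Average the four window predictions of each 10-cm section.

    The section average, later multiplied by the 10-cm section depth in the
    carbon chain, is equivalent to summing the four 2.5-cm windows.  The
    section SE is assembled by the same averaging of the window SE curve.
    """
    df = profile.table.copy()
    df["section_top_cm"] = (df["depth_top_cm"] // 10.0) * 10.0
    g = (
        df.groupby("section_top_cm", sort=True)
        .agg(frp_mean=("frp_mean", "mean"), frp_se=("frp_se", "mean"))
        .reset_index()
    )
    return BinnedProfile(label=profile.label, table=g)


def midpoint_partition_weights(
    midpoints_cm: Sequence[float] = MEASURED_MIDPOINTS_CM, max_depth_cm: float = 75.0
) -> np.ndarray:
    """Normalised widths of the profile slices each measured window represents.

    Slice boundaries sit at the surface, halfway between adjacent window
    midpoints, and at ``max_depth_cm``: for the measured design over 75 cm
    the widths are (4.25, 8, 15, 27.5, 20.25) cm.  Weights sum to one.
    """
    mids = np.asarray(midpoints_cm, dtype=float)
    if max_depth_cm < mids[-1]:
        raise ValueError("max_depth_cm must reach at least the deepest midpoint")
    bounds = np.concatenate([[0.0], (mids[:-1] + mids[1:]) / 2.0, [max_depth_cm]])
    widths = np.diff(bounds)
    return widths / widths.sum()


def depth_weighted_mean(profile: DepthMeansProfile, max_depth_cm: float = 75.0) -> float:
    """Depth-weighted mean production over 0–``max_depth_cm`` (m m⁻² mo⁻¹)."""
    w = midpoint_partition_weights(profile.midpoints_cm, max_depth_cm)
    return float(np.dot(w, np.asarray(profile.means)))
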