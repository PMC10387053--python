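"""Domain types, validation and CSV/JSON I/O for minirhizotron root-growth tables.

The tabular unit of the package is one *observation*: the length of new fine
root that appeared in one 2.5-cm-tall minirhizotron window during one
one-month census interval, normalised by window area (m m⁻² mo⁻¹), together
with its design labels (ecosystem type, tube, season, depth window).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ECOSYSTEMS",
    "SEASONS",
    "MEASURED_DEPTH_TOPS_CM",
    "WINDOW_SPAN_CM",
    "DepthWindow",
    "RootGrowthObservation",
    "ObservationSet",
    "ConversionConstants",
    "DesignReport",
    "read_observations",
    "write_observations",
    "validate_design",
]

#: Canonical ecosystem-type levels, in fixed display order.
ECOSYSTEMS: tuple[str, ...] = ("terra_firme", "hardwood_peat", "palm_peat")

#: Census seasons bounding the three one-month growth intervals
#: (short wet: May–Jun; long wet: Dec–Jan; long dry: Feb–Mar).
SEASONS: tuple[str, ...] = ("short_wet", "long_wet", "long_dry")

#: Tops (cm below the surface) of the five photographed depth windows.
MEASURED_DEPTH_TOPS_CM: tuple[float, ...] = (0.0, 6.0, 16.0, 36.0, 71.0)

#: Height of every observation window, cm.
WINDOW_SPAN_CM: float = 2.5

_CSV_COLUMNS = ["ecosystem", "tube_id", "season", "depth_top_cm", "frp_length"]


@dataclass(frozen=True, order=True)
class DepthWindow:
    """A 2.5-cm-tall observation window, addressed by its top depth in cm.

    The midpoint (``top_cm + 1.25``) is derived on demand and never stored,
    so the window top is the single source of truth for depth coordinates.
    """

    top_cm: float
    span_cm: float = WINDOW_SPAN_CM

    def __post_init__(self) -> None:
        if self.top_cm < 0:
            raise ValueError(f"window top must be >= 0 cm, got {self.top_cm}")
        if self.span_cm != WINDOW_SPAN_CM:
            raise ValueError(f"window span is fixed at {WINDOW_SPAN_CM} cm")

    @property
    def midpoint_cm(self) -> float:
        return self.top_cm + self.span_cm / 2.0

    @property
    def bottom_cm(self) -> float:
        return self.top_cm + self.span_cm


#: Midpoints of the five measured windows (1.25, 7.25, 17.25, 37.25, 72.25 cm).
MEASURED_MIDPOINTS_CM: tuple[float, ...] = tuple(
    DepthWindow(t).midpoint_cm for t in MEASURED_DEPTH_TOPS_CM
)


@dataclass(frozen=True)
class RootGrowthObservation:
    """One measured window growth value with its design labels.

    ``frp_length`` is new-root length per window area per month
    (m m⁻² mo⁻¹); exact zeros are common (≈ three-quarters of real
    measurements record no new roots).
    """

    ecosystem: str
    tube_id: int
    season: str
    window: DepthWindow
    frp_length: float

    def __post_init__(self) -> None:
        if self.ecosystem not in ECOSYSTEMS:
            raise ValueError(
                f"unknown ecosystem {self.ecosystem!r}; expected one of {ECOSYSTEMS}"
            )
        if self.season not in SEASONS:
            raise ValueError(
                f"unknown season {self.season!r}; expected one of {SEASONS}"
            )
        if self.frp_length < 0:
            raise ValueError(f"frp_length must be >= 0, got {self.frp_length}")

    @property
    def key(self) -> tuple[str, int, str, float]:
        return (self.ecosystem, self.tube_id, self.season, self.window.top_cm)


class ObservationSet:
    """An immutable collection of :class:`RootGrowthObservation` rows.

    Duplicate (ecosystem, tube, season, window) keys are rejected.  The
    ``provenance`` tag records where the rows came from (``"measured"``,
    ``"synthetic"`` or ``"fixture"``).
    """

    def __init__(
        self,
        observations: Iterable[RootGrowthObservation],
        provenance: str = "measured",
    ) -> None:
        obs = list(observations)
        seen: set[tuple] = set()
        for o in obs:
            if o.key in seen:
                raise ValueError(f"duplicate observation key {o.key}")
            seen.add(o.key)
        self._obs = tuple(obs)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self._obs)

    def __iter__(self):
        return iter(self._obs)

    def __getitem__(self, i: int) -> RootGrowthObservation:
        return self._obs[i]

    @property
    def observations(self) -> tuple[RootGrowthObservation, ...]:
        return self._obs

    def to_frame(self) -> pd.DataFrame:
        """Return the set as a tidy DataFrame with canonical categorical codes.

        Factor columns are ordered categoricals (ecosystem, season) so that
        design matrices built from the frame use a fixed level order.
        """
        df = pd.DataFrame(
            {
                "ecosystem": pd.Categorical(
                    [o.ecosystem for o in self._obs], categories=ECOSYSTEMS, ordered=True
                ),
                "tube_id": [o.tube_id for o in self._obs],
                "season": pd.Categorical(
                    [o.season for o in self._obs], categories=SEASONS, ordered=True
                ),
                "depth_top_cm": [o.window.top_cm for o in self._obs],
                "frp_length": [o.frp_length for o in self._obs],
            }
        )
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "measured") -> "ObservationSet":
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        obs = []
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                obs.append(
                    RootGrowthObservation(
                        ecosystem=str(row.ecosystem),
                        tube_id=int(row.tube_id),
                        season=str(row.season),
                        window=DepthWindow(float(row.depth_top_cm)),
                        frp_length=float(row.frp_length),
                    )
                )
            except ValueError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
        return cls(obs, provenance=provenance)

    def subset(self, **levels) -> "ObservationSet":
        """Restrict to observations matching all given factor levels.

        >>> obs.subset(ecosystem="terra_firme", season="long_dry")
        """
        keep = []
        for o in self._obs:
            vals = {
                "ecosystem": o.ecosystem,
                "tube_id": o.tube_id,
                "season": o.season,
                "depth_top_cm": o.window.top_cm,
            }
            if all(vals[k] == v for k, v in levels.items()):
                keep.append(o)
        return ObservationSet(keep, provenance=self.provenance)


class SchemaError(ValueError):
    """A CSV is missing required columns."""


class ValidationError(ValueError):
    """A row violates a domain invariant (names the offending row)."""


@dataclass(frozen=True)
class ConversionConstants:
    """Constants of the length-to-carbon conversion chain.

    depth_of_field_m
        Distance into the soil from the tube wall within which roots are
        visible to the camera; sets the sampled soil volume.  Default 2 mm.
    srl_by_band
        Specific root length (m of root per g dry mass) per depth band,
        keyed by (top_cm, bottom_cm).  The bands must tile 0–100 cm.
    carbon_fraction
        Dry-mass carbon content of fine roots (0.474).
    months_per_year
        Annualisation factor for monthly growth rates.
    section_depth_m
        Thickness of one reporting section of the soil profile (10 cm).
    """

    depth_of_field_m: float = 0.002
    srl_by_band: Mapping[tuple[float, float], float] = field(
        default_factory=lambda: {(0.0, 10.0): 37.1, (10.0, 20.0): 45.1, (20.0, 100.0): 51.6}
    )
    carbon_fraction: float = 0.474
    months_per_year: float = 12.0
    section_depth_m: float = 0.1

    def __post_init__(self) -> None:
        for name in ("depth_of_field_m", "carbon_fraction", "months_per_year", "section_depth_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        bands = sorted(self.srl_by_band)
        if not bands:
            raise ValueError("srl_by_band must not be empty")
        if bands[0][0] != 0.0 or bands[-1][1] != 100.0:
            raise ValueError("SRL bands must span 0-100 cm")
        for (a, b), (c, _) in zip(bands, bands[1:]):
            if b != c:
                raise ValueError(f"SRL bands must tile without gaps/overlap: {(a, b)} then {(c, _)}")
        for band, srl in self.srl_by_band.items():
            if srl <= 0:
                raise ValueError(f"SRL for band {band} must be > 0")

    def srl_for_depth(self, top_cm: float) -> float:
        """SRL (m g⁻¹) for the band containing a section whose top is ``top_cm``."""
        for (a, b), srl in sorted(self.srl_by_band.items()):
            if a <= top_cm < b:
                return srl
        raise ValueError(f"depth {top_cm} cm outside the 0-100 cm SRL bands")


@dataclass(frozen=True)
class DesignReport:
    """Completeness report for a factorial observation set."""

    n_observations: int
    n_expected: int
    cell_counts: pd.DataFrame  # counts per (ecosystem, season, depth_top_cm)
    missing_keys: tuple[tuple[str, int, str, float], ...]
    zero_fraction: float

    @property
    def complete(self) -> bool:
        return not self.missing_keys

    def summary(self) -> str:
        status = "complete" if self.complete else f"{len(self.missing_keys)} key(s) missing"
        return (
            f"{self.n_observations}/{self.n_expected} observations ({status}); "
            f"zero fraction {self.zero_fraction:.3f}"
        )


def validate_design(
    obs: ObservationSet,
    n_tubes: int = 16,
    ecosystems: Iterable[str] = ECOSYSTEMS,
    seasons: Iterable[str] = SEASONS,
    depth_tops_cm: Iterable[float] = MEASURED_DEPTH_TOPS_CM,
) -> DesignReport:
    """Report design completeness and the overall fraction of exact zeros.

    The full crossed design holds one row per
    (ecosystem, tube 1..n_tubes, season, measured depth window):
    3 × 16 × 3 × 5 = 720 rows at the study's dimensions.
    """
    ecosystems = tuple(ecosystems)
    seasons = tuple(seasons)
    depth_tops = tuple(depth_tops_cm)
    expected = {
        (e, t, s, d)
        for e in ecosystems
        for t in range(1, n_tubes + 1)
        for s in seasons
        for d in depth_tops
    }
    present = {o.key for o in obs}
    missing = tuple(sorted(expected - present))

    df = obs.to_frame()
    if len(df):
        counts = (
            df.groupby(["ecosystem", "season", "depth_top_cm"], observed=True)
            .size()
            .rename("count")
            .reset_index()
        )
        zero_fraction = float((df["frp_length"] == 0).mean())
    else:
        counts = pd.DataFrame(columns=["ecosystem", "season", "depth_top_cm", "count"])
        zero_fraction = float("nan")

    return DesignReport(
        n_observations=len(obs),
        n_expected=len(expected),
        cell_counts=counts,
        missing_keys=missing,
        zero_fraction=zero_fraction,
    )


def read_observations(
    path: str | Path,
    provenance: str = "measured",
    **read_csv_kwargs,
) -> ObservationSet:
    """Read an observation CSV (columns ecosystem, tube_id, season,
    depth_top_cm, frp_length) into a validated :class:`ObservationSet`.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (naming the row) for invalid values.
    """
    path = Path(path)
    read_csv_kwargs.setdefault("float_precision", "round_trip")
    df = pd.read_csv(path, **read_csv_kwargs)
    return ObservationSet.from_frame(df, provenance=provenance)


def write_observations(obs: ObservationSet, path: str | Path) -> None:
    """Write an observation set to CSV (UTF-8, comma-separated, '.' decimal).

    Uses ``repr``-faithful float formatting so a read-back round-trip
    reproduces every value bit-exactly.
    """
    path = Path(path)
    df = obs.to_frame()
    df["frp_length"] = [repr(float(v)) for v in df["frp_length"]]
    df.to_csv(path, index=False)


def design_report_to_json(report: DesignReport, path: str | Path) -> None:
    payload = {
        "n_observations": report.n_observations,
        "n_expected": report.n_expected,
        "complete": report.complete,
        "missing_keys": [list(k) for k in report.missing_keys],
        "zero_fraction": report.zero_fraction,
        "cell_counts": report.cell_counts.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
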