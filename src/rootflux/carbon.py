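"""Length-rate to carbon-flux conversion (minirhizotron chain).

A window's growth rate L (m of new root per m² of window per month) is
converted to an annual carbon flux per ground area through the standard
minirhizotron chain:

    root length density   L / depth_of_field          (m m⁻³ mo⁻¹)
    biomass density       ÷ SRL                       (g m⁻³ mo⁻¹)
    areal biomass         × section depth (0.1 m)     (g m⁻² mo⁻¹)
    annual                × 12                        (g m⁻² yr⁻¹)
    carbon, field units   × 0.01 × carbon fraction    (Mg C ha⁻¹ yr⁻¹)

With the default constants the chain collapses to ``L × 2.844 / SRL``,
where SRL is the specific root length of the section's depth band.  The
window area cancels because L is already normalised per m² of window.
Total uncertainty is the square root of the sum of squared section SEs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ConversionConstants
from .profiles import BinnedProfile

__all__ = [
    "CarbonProfile",
    "length_to_density",
    "density_to_biomass",
    "section_carbon",
    "propagate_total_se",
    "assemble_carbon_table",
]


def length_to_density(frp_length: float, constants: ConversionConstants) -> float:
    """Root length density (m m⁻³ mo⁻¹) observed behind a window.

    Divides the per-window-area rate by the camera's depth of field; the
    window area itself cancels.
    """
    if constants.depth_of_field_m <= 0:
        raise ValueError("depth_of_field_m must be positive")
    if frp_length < 0:
        raise ValueError("frp_length must be >= 0")
    return frp_length / constants.depth_of_field_m


def density_to_biomass(density: float, srl: float) -> float:
    """Biomass density (g m⁻³ mo⁻¹) from length density and SRL (m g⁻¹)."""
    if srl <= 0:
        raise ValueError("SRL must be > 0")
    return density / srl


def section_carbon(
    section_mean_frp: float, section_top_cm: float, constants: ConversionConstants
) -> float:
    """Annual carbon flux (Mg C ha⁻¹ yr⁻¹) of one 10-cm section.

    ``section_mean_frp`` is the section's mean window rate (m m⁻² mo⁻¹);
    the SRL is resolved from the band containing the section top.
    """
    srl = constants.srl_for_depth(section_top_cm)
    density = length_to_density(section_mean_frp, constants)  # m m^-3 mo^-1
    biomass = density_to_biomass(density, srl)  # g m^-3 mo^-1
    areal = biomass * constants.section_depth_m  # g m^-2 mo^-1
    annual = areal * constants.months_per_year  # g m^-2 yr^-1
    return annual * 0.01 * constants.carbon_fraction  # Mg C ha^-1 yr^-1


def propagate_total_se(section_ses: Sequence[float]) -> float:
    """Total SE as the square root of the sum of squared section SEs."""
    ses = np.asarray(section_ses, dtype=float)
    if (ses < 0).any():
        raise ValueError("SEs must be >= 0")
    return float(np.sqrt(np.sum(ses**2)))


@dataclass(frozen=True)
class CarbonProfile:
    """Ten 10-cm sections of carbon flux for one ecosystem, plus totals."""

    ecosystem: str
    table: pd.DataFrame  # columns: section_top_cm, carbon, se (Mg C ha^-1 yr^-1)
    total: float
    total_se: float

    def __post_init__(self) -> None:
        if (self.table["carbon"] < 0).any():
            raise ValueError("carbon fluxes must be >= 0")
        if not np.isclose(self.total, self.table["carbon"].sum()):
            raise ValueError("total must equal the sum of section fluxes")


def assemble_carbon_table(
    binned: Mapping[str, BinnedProfile],
    constants: ConversionConstants | None = None,
) -> dict[str, CarbonProfile]:
    """Convert per-ecosystem binned monthly profiles to carbon profiles.

    Expects season-averaged monthly rates (seasonal inputs are averaged
    before the ×12 annualisation inside the chain); SEs pass through the
    same linear factor as the means.
    """
    constants = constants or ConversionConstants()
    out: dict[str, CarbonProfile] = {}
    for eco, prof in binned.items():
        rows = []
        for r in prof.table.itertuples(index=False):
            carbon = section_carbon(r.frp_mean, r.section_top_cm, constants)
            factor = carbon / r.frp_mean if r.frp_mean > 0 else (
                section_carbon(1.0, r.section_top_cm, constants)
            )
            rows.append(
                {
                    "section_top_cm": r.section_top_cm,
                    "carbon": carbon,
                    "se": r.frp_se * factor,
                }
            )
        table = pd.DataFrame(rows)
        out[eco] = CarbonProfile(
            ecosystem=eco,
            table=table,
            total=float(table["carbon"].sum()),
            total_se=propagate_total_se(table["se"]),
        )
    return out


def carbon_table_to_frame(profiles: Mapping[str, CarbonProfile]) -> pd.DataFrame:
    """Tidy frame of all sections plus one TOT row per ecosystem."""
    rows = []
    for eco, p in profiles.items():
        for r in p.table.itertuples(index=False):
            rows.append(
                {"ecosystem": eco, "section": f"{r.section_top_cm:.0f}-{r.section_top_cm + 10:.0f}",
                 "carbon": r.carbon, "se": r.se}
            )
        rows.append({"ecosystem": eco, "section": "TOT", "carbon": p.total, "se": p.total_se})
    return pd.DataFrame(rows)
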