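"""Published summary tables used as packaged fixtures.

Two tables from the Congo Basin minirhizotron study are shipped verbatim:

* the measured per-(ecosystem, depth) means and standard errors of fine
  root production (m m⁻² mo⁻¹), each cell the mean of 16 tube locations
  and three one-month intervals; and
* the extrapolated carbon table: ten 10-cm soil sections of fine-root
  carbon flux (Mg C ha⁻¹ yr⁻¹) per ecosystem, with SEs and totals.

They let the downstream arithmetic (grand depth means, depth ratios,
depth-weighted profile means, 30-cm sums, SE propagation) be reproduced
without access to the unreleased raw observations.
"""

from __future__ import annotations

import pandas as pd

from .data import ECOSYSTEMS, MEASURED_DEPTH_TOPS_CM

__all__ = ["measured_depth_means", "carbon_table", "fixture_from_table1"]

# (ecosystem, depth_top_cm) -> (mean, SE), m m^-2 mo^-1
_TABLE1 = {
    ("terra_firme", 0.0): (18.82, 4.84),
    ("terra_firme", 6.0): (9.66, 2.92),
    ("terra_firme", 16.0): (0.21, 0.21),
    ("terra_firme", 36.0): (4.26, 1.96),
    ("terra_firme", 71.0): (1.57, 1.30),
    ("hardwood_peat", 0.0): (20.14, 3.92),
    ("hardwood_peat", 6.0): (6.01, 1.92),
    ("hardwood_peat", 16.0): (6.60, 1.69),
    ("hardwood_peat", 36.0): (3.92, 1.85),
    ("hardwood_peat", 71.0): (0.32, 0.27),
    ("palm_peat", 0.0): (24.53, 8.35),
    ("palm_peat", 6.0): (20.59, 4.71),
    ("palm_peat", 16.0): (8.75, 3.19),
    ("palm_peat", 36.0): (2.92, 1.32),
    ("palm_peat", 71.0): (0.29, 0.29),
}

# (ecosystem, section_top_cm) -> (carbon flux, SE), Mg C ha^-1 yr^-1
_TABLE3 = {
    "terra_firme": [
        (0.95, 0.05), (0.17, 0.04), (0.02, 0.04), (0.11, 0.04), (0.17, 0.05),
        (0.14, 0.04), (0.07, 0.04), (0.01, 0.04), (0.01, 0.04), (0.01, 0.04),
    ],
    "hardwood_peat": [
        (1.01, 0.18), (0.36, 0.16), (0.14, 0.14), (0.17, 0.17), (0.13, 0.19),
        (0.08, 0.17), (0.03, 0.16), (0.00, 0.18), (0.00, 0.18), (0.00, 0.18),
    ],
    "palm_peat": [
        (1.48, 0.08), (0.68, 0.06), (0.27, 0.06), (0.10, 0.07), (0.02, 0.09),
        (0.02, 0.09), (0.02, 0.09), (0.02, 0.09), (0.02, 0.09), (0.02, 0.09),
    ],
}

# Printed totals (mean, SE); the section sums reproduce the means exactly,
# the SE column is the printed sqrt-sum-of-squares value.
_TABLE3_TOTALS = {
    "terra_firme": (1.67, 0.13),
    "hardwood_peat": (1.93, 0.54),
    "palm_peat": (2.63, 0.27),
}


def measured_depth_means() -> pd.DataFrame:
    """The measured per-(ecosystem, depth) FRP means and SEs.

    Returns a tidy frame with columns ``ecosystem``, ``depth_top_cm``,
    ``mean`` and ``se`` (units m m⁻² mo⁻¹), 15 rows.
    """
    rows = [
        {"ecosystem": e, "depth_top_cm": d, "mean": m, "se": s}
        for (e, d), (m, s) in _TABLE1.items()
    ]
    df = pd.DataFrame(rows)
    df["ecosystem"] = pd.Categorical(df["ecosystem"], categories=ECOSYSTEMS, ordered=True)
    return df.sort_values(["ecosystem", "depth_top_cm"], ignore_index=True)


#: Alias kept for discoverability: the fixture is the study's Table-1-shaped
#: mean/SE table.
def fixture_from_table1() -> pd.DataFrame:
    return measured_depth_means()


def carbon_table() -> pd.DataFrame:
    """The published carbon-flux profile: ten 10-cm sections per ecosystem.

    Columns: ``ecosystem``, ``section_top_cm``, ``carbon``, ``se``
    (Mg C ha⁻¹ yr⁻¹), 30 rows.  Totals are available via
    :func:`carbon_table_totals`.
    """
    rows = []
    for eco, cells in _TABLE3.items():
        for i, (c, s) in enumerate(cells):
            rows.append(
                {"ecosystem": eco, "section_top_cm": 10.0 * i, "carbon": c, "se": s}
            )
    df = pd.DataFrame(rows)
    df["ecosystem"] = pd.Categorical(df["ecosystem"], categories=ECOSYSTEMS, ordered=True)
    return df.sort_values(["ecosystem", "section_top_cm"], ignore_index=True)


def carbon_table_totals() -> pd.DataFrame:
    """Printed per-ecosystem totals (mean, SE) of the carbon-flux profile."""
    rows = [
        {"ecosystem": e, "total": t, "se": s} for e, (t, s) in _TABLE3_TOTALS.items()
    ]
    df = pd.DataFrame(rows)
    df["ecosystem"] = pd.Categorical(df["ecosystem"], categories=ECOSYSTEMS, ordered=True)
    return df.sort_values("ecosystem", ignore_index=True)


def _check_fixture_shapes() -> None:
    assert set(d for _, d in _TABLE1) == set(MEASURED_DEPTH_TOPS_CM)
    assert all(len(v) == 10 for v in _TABLE3.values())


_check_fixture_shapes()
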