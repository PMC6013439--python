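"""Total carbon stocks from mean densities and areas; climate-zone rules.

A mean carbon density in kgC m^-3 applied over a depth (m) and an area
(hectares) gives a total stock in petagrams:

    total [Pg C] = density [kgC m^-3] * depth [m] * area [ha] * 1e4 / 1e12

(1 ha = 1e4 m^2, 1 Pg = 1e12 kg; note 1 gC cm^-3 = 1000 kgC m^-3).  The
scenario table compares mapping strategies across area scenarios the way
national assessments tabulate them, attaching each strategy's qualitative
accuracy/precision verdict.

Climate zones follow the U.S. GHG-inventory conventions: mediterranean is
California south of 40 deg latitude; subtropical is the Gulf coast plus the
Atlantic coast (Florida) south of 30 deg; temperate warm is the Atlantic
coast between 30 and 40 deg; temperate cool is the Pacific or Atlantic
coast north of 40 deg.  Boundary latitudes belong to the cooler class
("south of" is strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import pandas as pd

__all__ = [
    "GC_CM3_TO_KG_M3",
    "StockEstimate",
    "total_stock",
    "scenario_table",
    "climate_zone",
]

#: Conversion: 1 gC cm^-3 = 1000 kgC m^-3.
GC_CM3_TO_KG_M3 = 1000.0


@dataclass
class StockEstimate:
    """One strategy x area-scenario stock estimate."""
    strategy_name: str
    area_ha: float
    mean_density_kg_m3: float
    depth_m: float
    total_pg: float
    verdict: str = ""


def total_stock(mean_density_kg_m3: float, area_ha: float, depth_m: float = 1.0) -> float:
    """Total carbon stock in Pg C."""
    if mean_density_kg_m3 < 0 or area_ha < 0 or depth_m < 0:
        raise ValueError("density, area and depth must be >= 0")
    return mean_density_kg_m3 * depth_m * area_ha * 1e4 / 1e12


def scenario_table(strategies: Mapping[str, Mapping[str, Optional[float]]],
                   areas: Mapping[str, float],
                   verdicts: Optional[Mapping[str, str]] = None,
                   depth_m: float = 1.0) -> pd.DataFrame:
    """Strategy x area-scenario comparison of mean densities and totals.

    Parameters
    ----------
    strategies : mapping
        ``{strategy: {scenario: mean density in kgC m^-3 or None}}``; a
        None (or missing) cell means the strategy has no coverage for that
        scenario and the cell is left blank.
    areas : mapping
        ``{scenario: area in hectares}``.
    verdicts : mapping, optional
        ``{strategy: qualitative verdict string}``.

    Densities are reported to 1 decimal and totals (Pg) to 2, alongside
    the unrounded values.
    """
    rows = []
    for strat, per_scenario in strategies.items():
        for scen, area in areas.items():
            density = per_scenario.get(scen)
            if density is None:
                continue
            total = total_stock(density, area, depth_m)
            rows.append({
                "strategy": strat,
                "scenario": scen,
                "area_ha": area,
                "mean_density_kg_m3": density,
                "mean_density_rounded": round(density, 1),
                "total_pg": total,
                "total_pg_rounded": round(total, 2),
                "verdict": (verdicts or {}).get(strat, ""),
            })
    return pd.DataFrame(rows)


def climate_zone(state: str, latitude: float, coast: str) -> str:
    """Assign the GHG-inventory climate zone from state, latitude and coast."""
    coast = coast.lower()
    if coast not in {"atlantic", "gulf", "pacific"}:
        raise ValueError(f"unknown coast: {coast!r}")
    is_california = state.strip().lower() == "california"
    if is_california and coast == "pacific" and latitude < 40.0:
        return "mediterranean"
    if coast == "gulf":
        return "subtropical"
    if coast == "pacific":
        return "temperate_cool"
    # Atlantic coast
    if latitude < 30.0:
        return "subtropical"
    if latitude < 40.0:
        return "temperate_warm"
    return "temperate_cool"
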