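"""SSURGO-like soil-map aggregation, classification accuracy, and BD bias correction.

A soil map is organized as map units (spatial polygons) composed of
components (soil descriptions with a percent share), each described by
depth horizons carrying bulk density and organic-matter content.  This
module aggregates that hierarchy to per-10-cm-slab map-unit values,
converts them to carbon density with the van Bemmelen factor
(0.58 gOC gOM^-1, the conversion recommended for soil-survey data),
classifies soils as organic- or mineral-dominated at the empirical 13.2%
OM threshold, scores the classification against reference classes, and
bias-corrects mapped bulk densities through standardized mixing-model
residuals:

    r_i   = BD_i - BDhat_map(OM_i)          (residual about the map's own curve)
    r_i*  = r_i / sigma_map                 (standardized residual)
    CBD_i = BDhat_cal(OM_i) + r_i* sigma_cal

so corrected map values mimic the mean and spread of the empirical
calibration data while preserving the map's relative anomaly pattern.
Corrected values that fall below zero are assigned the minimum
pre-correction map BD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mixing_model import MixingFit, fit_mixing_model, predict_bd

__all__ = [
    "VAN_BEMMELEN",
    "ORGANIC_OM_THRESHOLD",
    "Horizon",
    "Component",
    "MapUnit",
    "MapUnitTable",
    "AccuracyMatrix",
    "aggregate_horizons",
    "aggregate_components",
    "map_unit_slab_table",
    "map_carbon_density",
    "classify_soil",
    "accuracy_assessment",
    "bias_correct_bd",
]

#: Conventional OC per OM conversion for soil-survey data (gOC gOM^-1).
VAN_BEMMELEN = 0.58
#: Empirical organic/mineral organic-matter threshold (fraction).
ORGANIC_OM_THRESHOLD = 0.132

SLAB_TOPS = tuple(range(0, 100, 10))


@dataclass
class Horizon:
    """A mapped depth interval (NaN = missing value)."""
    depth_top: float
    depth_bottom: float
    bulk_density: float = np.nan
    om_fraction: float = np.nan

    def __post_init__(self):
        if not self.depth_bottom > self.depth_top:
            raise ValueError("require depth_bottom > depth_top")


@dataclass
class Component:
    component_id: str
    hydric: bool
    component_percent: float
    horizons: List[Horizon] = field(default_factory=list)


@dataclass
class MapUnit:
    map_unit_id: str
    components: List[Component] = field(default_factory=list)
    soil_class: Optional[str] = None


@dataclass
class MapUnitTable:
    """Three-table soil-map schema: map units, components, horizons.

    ``map_units``: map_unit_id, soil_class_true, soil_class_mapped;
    ``components``: map_unit_id, component_id, hydric, component_percent;
    ``horizons``: component_id, depth_top_cm, depth_bottom_cm,
    bulk_density_g_cm3, om_fraction.
    """
    map_units: pd.DataFrame
    components: pd.DataFrame
    horizons: pd.DataFrame

    def write_csvs(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.map_units.to_csv(d / "map_units.csv", index=False)
        self.components.to_csv(d / "components.csv", index=False)
        self.horizons.to_csv(d / "horizons.csv", index=False)

    @classmethod
    def read_csvs(cls, directory) -> "MapUnitTable":
        d = Path(directory)
        return cls(
            map_units=pd.read_csv(d / "map_units.csv"),
            components=pd.read_csv(d / "components.csv"),
            horizons=pd.read_csv(d / "horizons.csv"),
        )


def aggregate_horizons(horizons: pd.DataFrame, max_depth: int = 100) -> pd.DataFrame:
    """Depth-weighted per-slab BD and OM for one component.

    Horizons are discretized to 1-cm cells.  Where BD is present but OM is
    missing, OM is treated as 0; where BD is missing the cell is no-data.
    Returns one row per slab with any data: ``increment_top, bulk_density,
    om_fraction, coverage_cm``.
    """
    bd = np.full(max_depth, np.nan)
    om = np.full(max_depth, np.nan)
    for row in horizons.sort_values("depth_top_cm").itertuples():
        top, bottom = float(row.depth_top_cm), float(row.depth_bottom_cm)
        if bottom <= top:
            raise ValueError("require depth_bottom > depth_top")
        lo, hi = int(np.floor(top)), min(int(np.ceil(bottom)), max_depth)
        if lo >= max_depth:
            continue
        if np.isnan(row.bulk_density_g_cm3):
            continue  # no-data horizon
        bd[lo:hi] = row.bulk_density_g_cm3
        om[lo:hi] = 0.0 if np.isnan(row.om_fraction) else row.om_fraction
    rows = []
    for top in SLAB_TOPS:
        if top >= max_depth:
            break
        sl = slice(top, top + 10)
        ok = ~np.isnan(bd[sl])
        if not ok.any():
            continue
        rows.append({"increment_top": top,
                     "bulk_density": float(np.mean(bd[sl][ok])),
                     "om_fraction": float(np.mean(om[sl][ok])),
                     "coverage_cm": int(ok.sum())})
    return pd.DataFrame(rows, columns=["increment_top", "bulk_density", "om_fraction",
                                       "coverage_cm"])


def aggregate_components(component_slabs: Dict[str, pd.DataFrame],
                         percents: Dict[str, float]) -> pd.DataFrame:
    """Component-percent-weighted map-unit values per slab.

    ``component_slabs`` maps component ids to the per-slab frames from
    :func:`aggregate_horizons`; ``percents`` gives each component's share.
    Weights are renormalized over the components that have data in a given
    slab; zero-percent components are ignored.
    """
    records: Dict[int, List[Tuple[float, float, float]]] = {}
    for cid, slabs in component_slabs.items():
        w = float(percents.get(cid, 0.0))
        if w <= 0 or slabs is None or len(slabs) == 0:
            continue
        for row in slabs.itertuples():
            records.setdefault(int(row.increment_top), []).append(
                (w, row.bulk_density, row.om_fraction))
    rows = []
    for top in sorted(records):
        entries = records[top]
        wsum = sum(w for w, _, _ in entries)
        bd = sum(w * b for w, b, _ in entries) / wsum
        om = sum(w * o for w, _, o in entries) / wsum
        rows.append({"increment_top": top, "bulk_density": bd, "om_fraction": om})
    return pd.DataFrame(rows, columns=["increment_top", "bulk_density", "om_fraction"])


def map_unit_slab_table(table: MapUnitTable) -> pd.DataFrame:
    """Aggregate a full map table to per-map-unit, per-slab values.

    Only hydric components contribute.  Adds carbon density (van
    Bemmelen), an OM-derived soil class, and the unit's mapped/true class
    labels.  Units with no data anywhere are absent from the output.
    """
    comp_by_unit = table.components.groupby("map_unit_id")
    hor_by_comp = {cid: grp for cid, grp in table.horizons.groupby("component_id")}
    meta = table.map_units.set_index("map_unit_id")
    frames = []
    for mu_id, comps in comp_by_unit:
        slabs: Dict[str, pd.DataFrame] = {}
        percents: Dict[str, float] = {}
        for comp in comps.itertuples():
            if not comp.hydric:
                continue
            hz = hor_by_comp.get(comp.component_id)
            if hz is None:
                continue
            slabs[comp.component_id] = aggregate_horizons(hz)
            percents[comp.component_id] = float(comp.component_percent)
        unit = aggregate_components(slabs, percents)
        if len(unit) == 0:
            continue
        unit.insert(0, "map_unit_id", mu_id)
        unit["carbon_density"] = map_carbon_density(unit["bulk_density"], unit["om_fraction"])
        unit["soil_class_om"] = classify_soil(unit["om_fraction"].to_numpy())
        for col in ("soil_class_true", "soil_class_mapped"):
            if col in meta.columns:
                unit[col] = meta.loc[mu_id, col]
        frames.append(unit)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def map_carbon_density(bd, om):
    """Carbon density (gC cm^-3) from mapped BD and OM via van Bemmelen."""
    bd = np.asarray(bd, dtype=float)
    om_a = np.asarray(om, dtype=float)
    cd = bd * om_a * VAN_BEMMELEN
    return float(cd) if np.ndim(bd) == 0 and np.ndim(om_a) == 0 else cd


def classify_soil(om_fraction, threshold: float = ORGANIC_OM_THRESHOLD):
    """'organic' iff OM strictly exceeds the threshold, else 'mineral'."""
    om = np.asarray(om_fraction, dtype=float)
    if np.any((om[~np.isnan(om)] < 0) | (om[~np.isnan(om)] > 1)):
        raise ValueError("om_fraction must lie in [0, 1]")
    out = np.where(om > threshold, "organic", "mineral")
    return str(out) if np.ndim(om_fraction) == 0 else out


@dataclass
class AccuracyMatrix:
    """2x2 confusion matrix (rows = mapped, cols = true) with accuracy rates."""
    counts: pd.DataFrame
    users_accuracy: Dict[str, float]
    producers_accuracy: Dict[str, float]
    total_accuracy: float

    def commission_error(self, cls: str) -> float:
        """Share of mapped ``cls`` that is actually the other class."""
        return 1.0 - self.users_accuracy[cls]


def accuracy_assessment(mapped_classes: Sequence[str],
                        reference_classes: Sequence[str]) -> AccuracyMatrix:
    """User's, producer's, and total accuracy of a binary soil classification."""
    mapped = np.asarray(mapped_classes)
    true = np.asarray(reference_classes)
    if len(mapped) == 0:
        raise ValueError("empty classification input")
    if len(mapped) != len(true):
        raise ValueError("mapped and reference classes must be paired")
    classes = ["organic", "mineral"]
    counts = pd.DataFrame(0, index=classes, columns=classes)
    for m, t in zip(mapped, true):
        counts.loc[m, t] += 1
    users = {c: (counts.loc[c, c] / counts.loc[c].sum()) if counts.loc[c].sum() else np.nan
             for c in classes}
    producers = {c: (counts.loc[c, c] / counts[c].sum()) if counts[c].sum() else np.nan
                 for c in classes}
    total = float(np.trace(counts.to_numpy()) / counts.to_numpy().sum())
    return AccuracyMatrix(counts, users, producers, total)


def bias_correct_bd(map_points: pd.DataFrame, empirical_om, empirical_bd
                    ) -> Tuple[pd.DataFrame, MixingFit, MixingFit]:
    """Standardized-residual bias correction of mapped bulk densities.

    Parameters
    ----------
    map_points : DataFrame
        Columns ``om_fraction`` and ``bulk_density`` (one row per mapped
        point, e.g. horizon or slab values).
    empirical_om, empirical_bd : array-like
        Calibration OM-BD pairs defining the target curve and residual
        spread.

    Returns
    -------
    (corrected, map_fit, calibration_fit): ``corrected`` is a copy of
    ``map_points`` with ``bulk_density_corrected`` added; negative
    corrected values are assigned the minimum pre-correction map BD.
    """
    om = map_points["om_fraction"].to_numpy(dtype=float)
    bd = map_points["bulk_density"].to_numpy(dtype=float)
    ok = ~(np.isnan(om) | np.isnan(bd))
    map_fit = fit_mixing_model(om[ok], bd[ok])
    cal_fit = fit_mixing_model(empirical_om, empirical_bd)

    resid = bd - predict_bd(om, map_fit.k1, map_fit.k2)
    sigma_s = map_fit.residual_sd
    r_star = np.zeros_like(resid) if sigma_s == 0 else resid / sigma_s
    corrected_bd = predict_bd(om, cal_fit.k1, cal_fit.k2) + r_star * cal_fit.residual_sd
    min_bd = float(np.nanmin(bd))
    corrected_bd = np.where(corrected_bd < 0, min_bd, corrected_bd)
    corrected_bd = np.where(ok, corrected_bd, np.nan)

    out = map_points.copy()
    out["bulk_density_corrected"] = corrected_bd
    return out, map_fit, cal_fit
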