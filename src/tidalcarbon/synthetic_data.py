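"""Synthetic tidal-wetland soil-core and soil-map generators.

Everything downstream of this module (increment aggregation, mixing-model
fits, mixed-effects models, map scoring, stock accounting) is exercised on
data produced here, so the generators encode the statistical structure the
analysis assumes:

* a mixture of mineral-dominated (OM <= 0.132) and organic-dominated
  (OM > 0.132) cores, each class with a truncated-normal organic-matter
  distribution;
* bulk density tied to organic matter through the ideal mixing model
  (k1 = 0.098, k2 = 1.67 g cm^-3 by default) plus Gaussian noise;
* a submitter-level random intercept on carbon density (labs differ
  systematically in loss-on-ignition and bulk-density technique);
* SSURGO-like map-unit -> component -> horizon tables whose bulk densities
  can be generated with an inflated organic self-packing density
  (``k1_map_bias``) and whose soil classes can be randomly flipped
  (``misclassification_rate``), emulating the biases observed in national
  soil maps.

The class-mix default reproduces the composition of the assembled CONUS
core database (1533 estuarine emergent, 157 palustrine emergent, 46
estuarine forested/scrub, 87 palustrine forested/scrub, 134 unknown of
1959 cores); the organic-matter mixture parameters are calibrated so the
implied 10-cm-increment carbon density has mean ~0.027 and s.d.
~0.013 gC cm^-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_processing import OC_COEFFS_DEFAULT, om_to_oc
from .mixing_model import predict_bd
from .map_emulation import MapUnitTable

__all__ = [
    "SAL_VEG_CLASSES",
    "CLIMATE_ZONES",
    "POSITION_QUALITIES",
    "GeneratorConfig",
    "CoreSample",
    "Core",
    "generate_core_dataset",
    "generate_map_unit_table",
    "split_calibration_reference",
    "sample_om_bd_pairs",
    "cores_to_frame",
    "frame_to_cores",
    "EMULATION_CD_MEAN",
    "EMULATION_CD_SD",
]

SAL_VEG_CLASSES = (
    "estuarine_emergent",
    "estuarine_forested_scrub",
    "palustrine_emergent",
    "palustrine_forested_scrub",
    "unknown",
)
CLIMATE_ZONES = ("mediterranean", "subtropical", "temperate_warm", "temperate_cool")
POSITION_QUALITIES = ("gps", "map_figure", "site_description", "unusable")

#: Composition of the assembled CONUS core database.
DEFAULT_CLASS_COUNTS = {
    "estuarine_emergent": 1533,
    "palustrine_emergent": 157,
    "estuarine_forested_scrub": 46,
    "palustrine_forested_scrub": 87,
    "unknown": 134,
}
# the published class counts total 1957 of 1959 cores; normalize over the
# classified total so the proportions form a proper mix
DEFAULT_CLASS_MIX = {k: v / sum(DEFAULT_CLASS_COUNTS.values())
                     for k, v in DEFAULT_CLASS_COUNTS.items()}
DEFAULT_CLIMATE_MIX = {z: 0.25 for z in CLIMATE_ZONES}
DEFAULT_POSITION_MIX = {"gps": 0.70, "map_figure": 0.15, "site_description": 0.10, "unusable": 0.05}

#: How cores report their organic measurements (shares of the assembled
#: database: 1357 OM only, 475 OM+OC, 127 OC only).
REPORTING_MIX = {"om_only": 1357 / 1959, "om_and_oc": 475 / 1959, "oc_only": 127 / 1959}

#: Organic/mineral OM boundary used to assign core soil classes.
ORGANIC_OM_BOUNDARY = 0.132

#: Emulation targets for the increment-level carbon-density distribution.
EMULATION_CD_MEAN = 0.027  # gC cm^-3
EMULATION_CD_SD = 0.013    # gC cm^-3

#: Floor applied to generated bulk densities (g cm^-3).
BD_FLOOR = 0.01

#: OC denominator floor when translating the submitter carbon-density
#: intercept into a bulk-density shift (keeps the shift bounded in nearly
#: carbon-free mineral soils).
_SUBMITTER_OC_FLOOR = 0.05

_MISSING_OM_RATE_MAP = 0.05
_MISSING_BD_RATE_MAP = 0.03


def _validate_mix(mix: Mapping[str, float], allowed: Sequence[str], name: str):
    if set(mix) - set(allowed):
        raise ValueError(f"{name} has unknown classes: {set(mix) - set(allowed)}")
    vals = np.array(list(mix.values()), dtype=float)
    if np.any(vals < 0) or np.any(vals > 1) or not np.isclose(vals.sum(), 1.0, atol=1e-8):
        raise ValueError(f"{name} proportions must lie in [0, 1] and sum to 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic core and map generators.

    Densities are g cm^-3, the submitter random-intercept s.d. is
    gC cm^-3, and core length is cm.  The organic-matter mixture
    parameters (class means/s.d. of truncated normals below and above the
    13.2% boundary) are calibrated once so the generated increment carbon
    density matches the emulation targets (mean 0.027, s.d. 0.013
    gC cm^-3).
    """
    n_cores: int = 1959
    class_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    climate_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLIMATE_MIX))
    organic_fraction_of_cores: float = 0.47
    k1_true: float = 0.098
    k2_true: float = 1.67
    submitter_sd: float = 0.00624
    noise_sd_bd: float = 0.02
    core_length_mean: float = 55.0
    seed: int = 0
    n_submitters: int = 49
    om_mineral_mean: float = 0.076
    om_mineral_sd: float = 0.03
    om_organic_mean: float = 0.40
    om_organic_sd: float = 0.10
    om_within_core_sd: float = 0.02
    position_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_POSITION_MIX))

    def __post_init__(self):
        if self.n_cores < 1:
            raise ValueError("n_cores must be >= 1")
        _validate_mix(self.class_mix, SAL_VEG_CLASSES, "class_mix")
        _validate_mix(self.climate_mix, CLIMATE_ZONES, "climate_mix")
        _validate_mix(self.position_mix, POSITION_QUALITIES, "position_mix")
        if not 0.0 <= self.organic_fraction_of_cores <= 1.0:
            raise ValueError("organic_fraction_of_cores must lie in [0, 1]")
        if not 0.0 < self.k1_true < self.k2_true:
            raise ValueError("require 0 < k1_true < k2_true")
        for nm in ("submitter_sd", "noise_sd_bd", "om_mineral_sd", "om_organic_sd",
                   "om_within_core_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if self.core_length_mean <= 0:
            raise ValueError("core_length_mean must be positive")
        if self.n_submitters < 1:
            raise ValueError("n_submitters must be >= 1")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass
class CoreSample:
    """One measured depth interval of a core (NaN = missing)."""
    depth_top: float
    depth_bottom: float
    bulk_density: float
    om_fraction: float
    oc_fraction: float

    def __post_init__(self):
        if not self.depth_bottom > self.depth_top >= 0:
            raise ValueError("require depth_bottom > depth_top >= 0")


@dataclass
class Core:
    """A soil core: provenance metadata plus ordered depth samples."""
    core_id: str
    submitter_id: str
    climate: str
    sal_veg: str
    position_quality: str
    samples: List[CoreSample]

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_top_cm": [s.depth_top for s in self.samples],
                "depth_bottom_cm": [s.depth_bottom for s in self.samples],
                "bulk_density_g_cm3": [s.bulk_density for s in self.samples],
                "om_fraction": [s.om_fraction for s in self.samples],
                "oc_fraction": [s.oc_fraction for s in self.samples],
            }
        )


def _truncnorm_draw(rng, mean, sd, lo, hi, size=None):
    """Rejection-sampled truncated normal (sd may be 0 -> point mass)."""
    if sd == 0:
        val = np.clip(mean, lo, hi)
        return val if size is None else np.full(size, val)
    n = 1 if size is None else int(size)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return float(out[0]) if size is None else out


def _choice(rng, mix: Mapping[str, float]) -> str:
    keys = list(mix)
    return keys[rng.choice(len(keys), p=np.array([mix[k] for k in keys]))]


def _draw_om(rng, organic: bool, cfg: GeneratorConfig, size=None):
    if organic:
        return _truncnorm_draw(rng, cfg.om_organic_mean, cfg.om_organic_sd,
                               ORGANIC_OM_BOUNDARY, 1.0, size)
    return _truncnorm_draw(rng, cfg.om_mineral_mean, cfg.om_mineral_sd,
                           0.0, ORGANIC_OM_BOUNDARY, size)


def _bd_from_om(rng, om, cfg: GeneratorConfig, submitter_shift: float = 0.0,
                k1: Optional[float] = None):
    """Mixing-model BD at OM, plus submitter and measurement noise.

    ``submitter_shift`` is an additive carbon-density offset (gC cm^-3)
    realized as a BD shift of ``u / max(OC(OM), 0.05)`` so downstream
    carbon density moves by exactly ``u`` wherever OC >= 0.05 (i.e. in
    organic soils) and by a damped amount in nearly carbon-free soils.
    """
    om = np.asarray(om, dtype=float)
    bd = predict_bd(om, cfg.k1_true if k1 is None else k1, cfg.k2_true)
    if submitter_shift != 0.0:
        oc = np.maximum(om_to_oc(om, coeffs=OC_COEFFS_DEFAULT), _SUBMITTER_OC_FLOOR)
        bd = bd + submitter_shift / oc
    if cfg.noise_sd_bd > 0:
        bd = bd + rng.normal(0.0, cfg.noise_sd_bd, size=np.shape(om))
    return np.maximum(bd, BD_FLOOR)


def generate_core_dataset(config: GeneratorConfig) -> List[Core]:
    """Generate a deterministic collection of synthetic cores.

    A single pseudo-random stream is seeded from ``config.seed``; two
    calls with the same configuration produce identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    submitter_ids = [f"S{i:03d}" for i in range(config.n_submitters)]
    intercepts = (rng.normal(0.0, config.submitter_sd, size=config.n_submitters)
                  if config.submitter_sd > 0 else np.zeros(config.n_submitters))
    cores: List[Core] = []
    for i in range(config.n_cores):
        sub_idx = int(rng.integers(config.n_submitters))
        climate = _choice(rng, config.climate_mix)
        sal_veg = _choice(rng, config.class_mix)
        position = _choice(rng, config.position_mix)
        organic = bool(rng.random() < config.organic_fraction_of_cores)
        core_mu = _draw_om(rng, organic, config)
        length = max(5, int(round(rng.exponential(config.core_length_mean))))
        reporting = _choice(rng, REPORTING_MIX)

        samples: List[CoreSample] = []
        top = 0
        while top < length:
            thick = int(rng.choice([2, 5, 10], p=[0.3, 0.4, 0.3]))
            bottom = min(top + thick, length)
            lo, hi = ((ORGANIC_OM_BOUNDARY, 1.0) if organic else (0.0, ORGANIC_OM_BOUNDARY))
            om = float(np.clip(_truncnorm_draw(rng, core_mu, config.om_within_core_sd, lo, hi),
                               0.0, 1.0))
            bd = float(_bd_from_om(rng, om, config, submitter_shift=float(intercepts[sub_idx])))
            oc_true = om_to_oc(om)
            oc_meas = float(np.clip(oc_true + rng.normal(0.0, 0.005), 0.0, 1.0))
            om_rep = om if reporting in ("om_only", "om_and_oc") else np.nan
            oc_rep = oc_meas if reporting in ("om_and_oc", "oc_only") else np.nan
            samples.append(CoreSample(float(top), float(bottom), bd, om_rep, oc_rep))
            top = bottom
        cores.append(Core(f"C{i:04d}", submitter_ids[sub_idx], climate, sal_veg,
                          position, samples))
    return cores


def sample_om_bd_pairs(n: int, config: GeneratorConfig,
                       seed: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Raw OM-BD pairs from the generator's mixture and mixing curve.

    Convenience for exercising the mixing-model fitters without building
    full cores; no submitter effect is applied.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    organic = rng.random(n) < config.organic_fraction_of_cores
    om = np.empty(n)
    n_org = int(organic.sum())
    if n_org:
        om[organic] = _draw_om(rng, True, config, size=n_org)
    if n - n_org:
        om[~organic] = _draw_om(rng, False, config, size=n - n_org)
    bd = _bd_from_om(rng, om, config)
    return om, bd


def generate_map_unit_table(config: GeneratorConfig, k1_map_bias: float = 1.0,
                            misclassification_rate: float = 0.0,
                            n_map_units: int = 300) -> MapUnitTable:
    """Generate an SSURGO-like map-unit/component/horizon table.

    Horizon bulk densities follow the mixing model evaluated with
    ``k1_true * k1_map_bias`` (a bias multiplier > 1 inflates mapped BD in
    organic soils, emulating the inflated organic self-packing densities
    observed in national soil maps).  A fraction
    ``misclassification_rate`` of map units has its mapped soil class
    flipped relative to the generating (true) class.
    """
    if k1_map_bias <= 0:
        raise ValueError("k1_map_bias must be positive")
    if not 0.0 <= misclassification_rate <= 1.0:
        raise ValueError("misclassification_rate must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    k1_map = config.k1_true * k1_map_bias

    units, comps, hors = [], [], []
    for u in range(n_map_units):
        mu_id = f"MU{u:04d}"
        organic = bool(rng.random() < config.organic_fraction_of_cores)
        true_class = "organic" if organic else "mineral"
        flipped = bool(rng.random() < misclassification_rate)
        mapped_class = ({"organic": "mineral", "mineral": "organic"}[true_class]
                        if flipped else true_class)
        unit_mu = _draw_om(rng, organic, config)

        n_comp = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, 100), size=n_comp - 1, replace=False)) if n_comp > 1 else np.array([], dtype=int)
        percents = np.diff(np.concatenate([[0], cuts, [100]]))
        for c in range(n_comp):
            comp_id = f"{mu_id}_C{c}"
            hydric = bool(c == 0 or rng.random() < 0.9)
            comps.append({"map_unit_id": mu_id, "component_id": comp_id,
                          "hydric": hydric, "component_percent": int(percents[c])})
            top = 0
            while top < 100:
                thick = int(rng.choice([10, 20, 30, 40]))
                bottom = min(top + thick, 100)
                lo, hi = ((ORGANIC_OM_BOUNDARY, 1.0) if organic else (0.0, ORGANIC_OM_BOUNDARY))
                om = float(_truncnorm_draw(rng, unit_mu, config.om_within_core_sd, lo, hi))
                bd = float(_bd_from_om(rng, om, config, k1=k1_map))
                if rng.random() < _MISSING_BD_RATE_MAP:
                    bd = np.nan
                om_rep = np.nan if rng.random() < _MISSING_OM_RATE_MAP else om
                hors.append({"component_id": comp_id, "depth_top_cm": top,
                             "depth_bottom_cm": bottom,
                             "bulk_density_g_cm3": bd, "om_fraction": om_rep})
                top = bottom
        units.append({"map_unit_id": mu_id, "soil_class_true": true_class,
                      "soil_class_mapped": mapped_class})
    return MapUnitTable(
        map_units=pd.DataFrame(units),
        components=pd.DataFrame(comps),
        horizons=pd.DataFrame(hors),
    )


def split_calibration_reference(cores: Sequence[Core], fraction: float = 0.5,
                                seed: Optional[int] = None) -> Tuple[List[Core], List[Core]]:
    """Random core-level split into calibration and reference subsets.

    The split never divides a core's samples.  The reference subset is
    additionally screened to exclude cores with unusable position quality
    (those cannot be matched to mapped values).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(cores)
    n_cal = int(round(fraction * n))
    if n_cal == 0 or n_cal == n:
        raise ValueError("split would leave an empty partition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    calibration = [cores[i] for i in sorted(perm[:n_cal])]
    reference = [cores[i] for i in sorted(perm[n_cal:])
                 if cores[i].position_quality != "unusable"]
    return calibration, reference


_CSV_COLUMNS = ["core_id", "submitter_id", "climate", "sal_veg", "position_quality",
                "depth_top_cm", "depth_bottom_cm", "bulk_density_g_cm3",
                "om_fraction", "oc_fraction"]


def cores_to_frame(cores: Sequence[Core]) -> pd.DataFrame:
    """Flatten cores to the canonical CSV schema (empty field = missing)."""
    rows = []
    for c in cores:
        for s in c.samples:
            rows.append((c.core_id, c.submitter_id, c.climate, c.sal_veg,
                         c.position_quality, s.depth_top, s.depth_bottom,
                         s.bulk_density, s.om_fraction, s.oc_fraction))
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_cores(frame: pd.DataFrame) -> List[Core]:
    """Inverse of :func:`cores_to_frame`."""
    cores = []
    for cid, grp in frame.groupby("core_id", sort=False):
        meta = grp.iloc[0]
        samples = [CoreSample(float(r.depth_top_cm), float(r.depth_bottom_cm),
                              float(r.bulk_density_g_cm3), float(r.om_fraction),
                              float(r.oc_fraction))
                   for r in grp.sort_values("depth_top_cm").itertuples()]
        cores.append(Core(str(cid), meta["submitter_id"], meta["climate"],
                          meta["sal_veg"], meta["position_quality"], samples))
    return cores
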