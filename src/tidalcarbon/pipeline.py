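"""End-to-end analysis pipeline: generate -> process -> fit -> evaluate -> account.

Runs the full carbon-stock analysis on synthetic data: generate a core
dataset and an SSURGO-like map table, split cores into calibration and
reference subsets, standardize to 10-cm increments, fit the mixing model
(with bootstrap) and the organic/mineral threshold, select mixed-effects
carbon-density models by AICc, score every mapping strategy with
normalized skill metrics, bias-correct the mapped bulk densities, and
tabulate total stocks per area scenario.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import core_processing as cp
from . import map_emulation as me
from . import mixing_model as mm
from . import skill_metrics as sk
from . import stock_accounting as sa
from . import stock_models as sm
from . import synthetic_data as sd

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_AREAS = {"ccap_nwi": 2.67e6, "ccap_nwi_ssurgo": 1.97e6}

#: Strategies only defined where the soil map has coverage.
_SSURGO_ONLY = ("model_1", "model_1_applied", "ssurgo", "ssurgo_corrected")


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""
    generator: sd.GeneratorConfig = field(default_factory=sd.GeneratorConfig)
    split_fraction: float = 0.5
    n_boot_mixing: int = 1000
    n_boot_threshold: int = 200
    k1_map_bias: float = 2.7
    misclassification_rate: float = 0.232
    n_map_units: int = 300
    model1_candidates: Sequence[str] = ("climate", "sal_veg", "soil", "depth",
                                        "climate:sal_veg")
    model2_candidates: Sequence[str] = ("climate", "sal_veg", "depth",
                                        "climate:sal_veg")
    areas: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AREAS))
    oc_coeffs: str = "default"
    depth_m: float = 1.0

    @property
    def coeffs(self):
        return cp.OC_COEFFS_DEFAULT if self.oc_coeffs == "default" else cp.OC_COEFFS_ALT

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = sd.GeneratorConfig(**raw.pop("generator", {}))
        return cls(generator=gen, **raw)


def _strategy_pairs(ref_inc: pd.DataFrame, modeled: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "increment_top": ref_inc["increment_top"].to_numpy(),
        "modeled": modeled,
        "reference": ref_inc["carbon_density"].to_numpy(),
    })


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None) -> Dict[str, object]:
    """Run the full analysis; optionally write a report directory.

    Returns a dictionary with the intermediate tables, fits, per-strategy
    skill scores, the scenario stock table, and a JSON-serializable
    ``summary``.
    """
    gen = config.generator
    coeffs = config.coeffs

    cores = sd.generate_core_dataset(gen)
    calibration, reference = sd.split_calibration_reference(
        cores, fraction=config.split_fraction, seed=gen.seed + 1)
    cal_inc = cp.aggregate_dataset(calibration, coeffs=coeffs)
    # reference rows must carry complete covariates (soil class needs OM) so
    # every strategy is scored on the same paired observations
    ref_inc = cp.aggregate_dataset(reference, coeffs=coeffs).dropna(
        subset=["carbon_density", "om_fraction"]).reset_index(drop=True)

    cal_cd = cal_inc["carbon_density"].dropna()
    dist_tn = cp.fit_carbon_distribution(cal_cd, "truncated_normal")
    dist_ln = cp.fit_carbon_distribution(cal_cd, "log_normal")
    profile_summary = cp.summarize_depth_profiles(cal_inc)

    mix_pairs = cal_inc.dropna(subset=["om_fraction", "bulk_density"])
    mixing_fit = mm.bootstrap_mixing_fit(mix_pairs["om_fraction"], mix_pairs["bulk_density"],
                                         n_iter=config.n_boot_mixing, seed=gen.seed + 10)
    slab_fits, slab_trend = mm.fit_per_depth_slabs(cal_inc)
    threshold = mm.fit_segmented_threshold(
        mix_pairs["om_fraction"], mix_pairs["carbon_density"],
        n_boot=config.n_boot_threshold, seed=gen.seed + 11)

    # --- mixed-effects model selection ---
    sigma_c = float(cal_cd.std(ddof=1))
    model_data = cal_inc.dropna(subset=["carbon_density", "om_fraction"]).copy()
    dredge1 = sm.dredge_models(model_data, list(config.model1_candidates), sigma_c=sigma_c)
    dredge2 = sm.dredge_models(model_data, list(config.model2_candidates), sigma_c=sigma_c)
    model1, model2 = dredge1["fit"].iloc[0], dredge2["fit"].iloc[0]
    omega1 = (sm.omega_squared(model_data, model1.fixed_terms)
              if model1.fixed_terms else pd.Series(dtype=float))

    # --- soil-map emulation ---
    map_table = sd.generate_map_unit_table(
        gen, k1_map_bias=config.k1_map_bias,
        misclassification_rate=config.misclassification_rate,
        n_map_units=config.n_map_units)
    map_slabs = me.map_unit_slab_table(map_table)
    accuracy = me.accuracy_assessment(map_table.map_units["soil_class_mapped"],
                                      map_table.map_units["soil_class_true"])

    # bias-correct mapped bulk density against calibration pairs
    hor = map_table.horizons.rename(columns={"bulk_density_g_cm3": "bulk_density"})
    corrected, map_fit, cal_fit = me.bias_correct_bd(
        hor[["om_fraction", "bulk_density"]],
        mix_pairs["om_fraction"], mix_pairs["bulk_density"])
    corrected_table = me.MapUnitTable(
        map_table.map_units,
        map_table.components,
        map_table.horizons.assign(bulk_density_g_cm3=corrected["bulk_density_corrected"]),
    )
    corrected_slabs = me.map_unit_slab_table(corrected_table)
    corr_pts = corrected.dropna(subset=["om_fraction", "bulk_density_corrected"])
    corrected_fit = mm.fit_mixing_model(corr_pts["om_fraction"],
                                        corr_pts["bulk_density_corrected"])

    # --- strategies on the reference set ---
    rng = np.random.default_rng(gen.seed + 20)
    strategies: Dict[str, pd.DataFrame] = {}

    strategies["average"] = _strategy_pairs(
        ref_inc, np.full(len(ref_inc), float(cal_cd.mean())))
    strategies["model_1"] = _strategy_pairs(ref_inc, sm.predict_fixed(model1, ref_inc))
    strategies["model_2"] = _strategy_pairs(ref_inc, sm.predict_fixed(model2, ref_inc))

    # application phase: soil class comes from an error-prone map
    applied = ref_inc.copy()
    flip = rng.random(len(applied)) < config.misclassification_rate
    applied.loc[flip, "soil_class"] = applied.loc[flip, "soil_class"].map(
        {"organic": "mineral", "mineral": "organic"}).fillna(applied.loc[flip, "soil_class"])
    strategies["model_1_applied"] = _strategy_pairs(ref_inc, sm.predict_fixed(model1, applied))

    # SSURGO strategies: pair each reference increment with a mapped value
    def paired_map_values(slabs: pd.DataFrame) -> np.ndarray:
        by_slab = {int(t): g["carbon_density"].to_numpy()
                   for t, g in slabs.dropna(subset=["carbon_density"]).groupby("increment_top")}
        out = np.full(len(ref_inc), np.nan)
        for i, top in enumerate(ref_inc["increment_top"].to_numpy()):
            vals = by_slab.get(int(top))
            if vals is not None and len(vals):
                out[i] = vals[rng.integers(len(vals))]
        return out

    strategies["ssurgo"] = _strategy_pairs(ref_inc, paired_map_values(map_slabs))
    strategies["ssurgo_corrected"] = _strategy_pairs(ref_inc, paired_map_values(corrected_slabs))

    scores, verdicts = {}, {}
    for name, paired in strategies.items():
        per_slab = sk.evaluate_strategy(paired)
        scores[name] = per_slab
        verdicts[name] = sk.classify_accuracy_precision(per_slab)

    # --- stock accounting ---
    mean_density = {name: float(np.nanmean(df["modeled"])) * sa.GC_CM3_TO_KG_M3
                    for name, df in strategies.items()}
    # map-based strategies: area-wide density comes from the map itself
    mean_density["ssurgo"] = float(map_slabs["carbon_density"].mean()) * sa.GC_CM3_TO_KG_M3
    mean_density["ssurgo_corrected"] = (float(corrected_slabs["carbon_density"].mean())
                                        * sa.GC_CM3_TO_KG_M3)
    strategy_densities = {
        name: {scen: (mean_density[name]
                      if (scen == "ccap_nwi_ssurgo" or name not in _SSURGO_ONLY) else None)
               for scen in config.areas}
        for name in strategies
    }
    stocks = sa.scenario_table(strategy_densities, config.areas,
                               verdicts={k: v["verdict"] for k, v in verdicts.items()},
                               depth_m=config.depth_m)

    summary = {
        "n_cores": len(cores),
        "n_calibration_cores": len(calibration),
        "n_reference_cores": len(reference),
        "n_calibration_increments": int(len(cal_inc)),
        "carbon_density_mean_gc_cm3": dist_tn.mean,
        "carbon_density_sd_gc_cm3": dist_tn.sd,
        "carbon_density_se_gc_cm3": dist_tn.se,
        "loglik_truncated_normal": dist_tn.log_likelihood,
        "loglik_log_normal": dist_ln.log_likelihood,
        "k1_g_cm3": mixing_fit.k1,
        "k2_g_cm3": mixing_fit.k2,
        "k1_ci": list(mixing_fit.ci_k1),
        "k2_ci": list(mixing_fit.ci_k2),
        "k1_depth_range": ([float(slab_fits["k1"].min()), float(slab_fits["k1"].max())]
                           if len(slab_fits) else [None, None]),
        "threshold_om": threshold.breakpoint_om,
        "threshold_ci": list(threshold.ci),
        "r2_at_threshold": threshold.r2_at_breakpoint,
        "r2_at_020": threshold.r2_at_020,
        "r2_at_035": threshold.r2_at_035,
        "model1_terms": list(model1.fixed_terms),
        "model1_aicc": model1.aicc,
        "model1_pseudo_r2_marginal": model1.pseudo_r2_marginal,
        "model1_random_sd_standardized": model1.submitter_intercept_sd_standardized,
        "model2_terms": list(model2.fixed_terms),
        "model2_aicc": model2.aicc,
        "omega_squared": {k: float(v) for k, v in omega1.items()},
        "map_k1_g_cm3": map_fit.k1,
        "map_n_points": map_fit.n,
        "corrected_map_k1_g_cm3": corrected_fit.k1,
        "corrected_map_residual_sd": corrected_fit.residual_sd,
        "calibration_mixing_residual_sd": cal_fit.residual_sd,
        "map_total_accuracy": accuracy.total_accuracy,
        "map_mineral_commission_error": accuracy.commission_error("mineral"),
        "verdicts": {k: v["verdict"] for k, v in verdicts.items()},
        "mean_density_kg_m3": mean_density,
        "stocks_pg": {f"{r.strategy}:{r.scenario}": r.total_pg for r in stocks.itertuples()},
    }

    results = {
        "config": config,
        "cores": cores,
        "calibration_increments": cal_inc,
        "reference_increments": ref_inc,
        "distribution_fits": {"truncated_normal": dist_tn, "log_normal": dist_ln},
        "profile_summary": profile_summary,
        "mixing_fit": mixing_fit,
        "slab_fits": slab_fits,
        "slab_trend": slab_trend,
        "threshold": threshold,
        "dredge_model1": dredge1,
        "dredge_model2": dredge2,
        "model1": model1,
        "model2": model2,
        "omega_squared": omega1,
        "map_table": map_table,
        "map_slabs": map_slabs,
        "corrected_slabs": corrected_slabs,
        "accuracy": accuracy,
        "map_fit": map_fit,
        "skill_scores": scores,
        "verdicts": verdicts,
        "stock_table": stocks,
        "summary": summary,
    }
    if out_dir is not None:
        _write_report(results, out_dir)
    return results


def _write_report(results: Dict[str, object], out_dir) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    sd.cores_to_frame(results["cores"]).to_csv(d / "cores.csv", index=False)
    results["calibration_increments"].to_csv(d / "calibration_increments.csv", index=False)
    results["reference_increments"].to_csv(d / "reference_increments.csv", index=False)
    results["profile_summary"].to_csv(d / "depth_profile_summary.csv", index=False)
    results["slab_fits"].to_csv(d / "mixing_fits_by_depth.csv", index=False)
    results["map_table"].write_csvs(d / "map")
    results["map_slabs"].to_csv(d / "map_unit_slabs.csv", index=False)
    results["accuracy"].counts.to_csv(d / "accuracy_matrix.csv")
    pd.concat([df.assign(strategy=name) for name, df in results["skill_scores"].items()],
              ignore_index=True).to_csv(d / "skill_scores.csv", index=False)
    for name, df in results["skill_scores"].items():
        sk.target_diagram_coordinates(df).assign(strategy=name)
    results["stock_table"].to_csv(d / "stock_table.csv", index=False)
    dredge = results["dredge_model1"].drop(columns=["fit"]).copy()
    dredge["terms"] = dredge["terms"].map(lambda t: "+".join(t) if t else "(intercept)")
    dredge.to_csv(d / "model_selection.csv", index=False)
    (d / "summary.json").write_text(json.dumps(results["summary"], indent=2, default=float))
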