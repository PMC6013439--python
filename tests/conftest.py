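"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tidalcarbon import core_processing as cp
from tidalcarbon import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.GeneratorConfig:
    return sd.GeneratorConfig(n_cores=60, n_submitters=8, seed=42)


@pytest.fixture(scope="session")
def small_cores(small_config):
    return sd.generate_core_dataset(small_config)


@pytest.fixture(scope="session")
def large_increments():
    """A dataset with >=1000 increments for the moment-emulation check.

    Many submitter clusters (150) keep the cluster-bootstrap standard
    errors of the sample moments well estimated."""
    cfg = sd.GeneratorConfig(n_cores=240, n_submitters=150, seed=7)
    cores = sd.generate_core_dataset(cfg)
    inc = cp.aggregate_dataset(cores)
    return cfg, cores, inc


def brute_force_increments(samples: pd.DataFrame, max_depth: int = 100) -> pd.DataFrame:
    """Independent 1-cm oracle for core aggregation.

    Walks every centimeter cell explicitly (interval membership checks, no
    shared code with the implementation) and applies the >50% terminal
    extrapolation rule.
    """
    sam = samples.sort_values("depth_top_cm").reset_index(drop=True)
    deepest = sam["depth_bottom_cm"].max()
    last = sam.iloc[sam["depth_bottom_cm"].idxmax()]
    rows = []
    for top in range(0, max_depth, 10):
        cells = []
        for cm in range(top, top + 10):
            hit = sam[(sam["depth_top_cm"] <= cm) & (sam["depth_bottom_cm"] > cm)]
            if len(hit):
                cells.append(hit.iloc[0])
        coverage = len(cells)
        if coverage == 0:
            continue
        extrapolated = False
        if top < deepest < top + 10:
            if coverage > 5:
                cells.extend([last] * (10 - coverage))
                extrapolated = True
            else:
                continue
        frame = pd.DataFrame(cells)
        def nmean(col):
            v = frame[col].dropna()
            return float(v.mean()) if len(v) else np.nan
        bd, om, oc = (nmean("bulk_density_g_cm3"), nmean("om_fraction"),
                      nmean("oc_fraction"))
        rows.append({"increment_top": top, "bulk_density": bd, "om_fraction": om,
                     "oc_fraction": oc, "coverage_cm": coverage,
                     "extrapolated": extrapolated})
    return pd.DataFrame(rows)


def random_core_samples(rng: np.random.Generator) -> pd.DataFrame:
    """A random, possibly gappy, non-overlapping sample table."""
    rows, top = [], 0.0
    length = float(rng.integers(8, 140))
    while top < length:
        thick = float(rng.choice([1, 2, 3, 5, 8, 10]))
        bottom = min(top + thick, length)
        rows.append({
            "depth_top_cm": top,
            "depth_bottom_cm": bottom,
            "bulk_density_g_cm3": float(rng.uniform(0.05, 1.6)),
            "om_fraction": float(rng.uniform(0, 1)) if rng.random() > 0.1 else np.nan,
            "oc_fraction": float(rng.uniform(0, 0.5)) if rng.random() > 0.7 else np.nan,
        })
        top = bottom
        if rng.random() < 0.15:  # occasional unsampled gap
            top += float(rng.integers(1, 6))
    return pd.DataFrame(rows)
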