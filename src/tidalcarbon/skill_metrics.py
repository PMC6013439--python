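"""Standardized model-skill metrics for carbon-density mapping strategies.

All metrics are normalized by the standard deviation of the reference
values (sigma_r), so strategies are directly comparable:

    B*      = (mu_m - mu_r) / sigma_r                    normalized bias
    R       = (1/n) sum (m_i - mu_m)(r_i - mu_r) / (sigma_m sigma_r)
    sigma*  = sigma_m / sigma_r                          normalized s.d.
    RMSE*'  = sqrt(1 + sigma*^2 - 2 sigma* R)            unbiased RMSE
    RMSE*   = sqrt(RMSE*'^2 + B*^2)                      total RMSE

RMSE* below 1 means the strategy beats the trivial baseline of applying
the reference-mean value everywhere.  For target diagrams the x-axis is
RMSE*' signed by sign(sigma_m - sigma_r); the y-axis is B*.  Standard
deviations use the population denominator n, matching the 1/n correlation
definition; a perfect model therefore yields B* = 0, sigma* = R = 1 and
RMSE*' = RMSE* = 0 exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SkillScores",
    "skill_scores",
    "evaluate_strategy",
    "classify_accuracy_precision",
    "target_diagram_coordinates",
]


@dataclass
class SkillScores:
    """Normalized skill scores for one modeled-vs-reference comparison."""
    bias_star: float
    correlation: float
    sigma_star: float
    rmse_prime_star: float
    rmse_star: float
    sign_convention: int
    n: int
    depth_slab: Optional[int] = None

    @property
    def signed_rmse_prime(self) -> float:
        """Target-diagram x-coordinate: RMSE*' signed by sign(sigma_m - sigma_r)."""
        return self.sign_convention * self.rmse_prime_star


def skill_scores(modeled, reference, depth_slab: Optional[int] = None) -> SkillScores:
    """Compute B*, R, sigma*, RMSE*' and RMSE* for paired series.

    A constant modeled series (sigma_m = 0, e.g. the mean-baseline
    strategy) has R defined as 0, giving RMSE*' = 1 exactly.
    """
    m = np.asarray(modeled, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape:
        raise ValueError("modeled and reference must be paired and equal length")
    keep = ~(np.isnan(m) | np.isnan(r))
    m, r = m[keep], r[keep]
    n = len(m)
    if n < 2:
        raise ValueError("need at least 2 paired values")
    mu_m, mu_r = float(np.mean(m)), float(np.mean(r))
    sigma_m, sigma_r = float(np.std(m)), float(np.std(r))  # population n
    if np.ptp(m) == 0.0:
        # a constant strategy (e.g. the reference-mean baseline) has zero
        # spread by definition; guard against rounding in np.std
        sigma_m, mu_m = 0.0, float(m[0])
    if sigma_r == 0:
        raise ValueError("reference standard deviation is zero; scores undefined")
    bias_star = (mu_m - mu_r) / sigma_r
    if sigma_m == 0:
        corr = 0.0
    else:
        corr = float(np.mean((m - mu_m) * (r - mu_r)) / (sigma_m * sigma_r))
    sigma_star = sigma_m / sigma_r
    rmse_prime = math.sqrt(max(1.0 + sigma_star**2 - 2.0 * sigma_star * corr, 0.0))
    rmse_star = math.sqrt(rmse_prime**2 + bias_star**2)
    sign = 1 if sigma_m >= sigma_r else -1
    return SkillScores(bias_star, corr, sigma_star, rmse_prime, rmse_star, sign, n,
                       depth_slab)


def evaluate_strategy(paired: pd.DataFrame) -> pd.DataFrame:
    """Per-depth-slab skill scores for one mapping strategy.

    Parameters
    ----------
    paired : DataFrame
        Columns ``increment_top, modeled, reference`` with one row per
        paired observation.

    Returns
    -------
    DataFrame of scores per slab, including ``better_than_mean``
    (RMSE* < 1: the strategy beats applying the reference mean).
    """
    rows = []
    for top, grp in paired.groupby("increment_top"):
        sub = grp.dropna(subset=["modeled", "reference"])
        if len(sub) < 2:
            continue
        s = skill_scores(sub["modeled"], sub["reference"], depth_slab=int(top))
        rows.append({"increment_top": int(top), "bias_star": s.bias_star,
                     "correlation": s.correlation, "sigma_star": s.sigma_star,
                     "rmse_prime_star": s.rmse_prime_star, "rmse_star": s.rmse_star,
                     "signed_rmse_prime": s.signed_rmse_prime, "n": s.n,
                     "better_than_mean": s.rmse_star < 1.0})
    if not rows:
        raise ValueError("no slab had enough paired data")
    return pd.DataFrame(rows).sort_values("increment_top").reset_index(drop=True)


def classify_accuracy_precision(per_slab_scores: pd.DataFrame) -> Dict[str, object]:
    """Qualitative verdict from per-slab scores.

    A strategy is *accurate* when |B*| < 1 for every slab and *precise*
    when RMSE*' < 1 for every slab.
    """
    accurate = bool((per_slab_scores["bias_star"].abs() < 1.0).all())
    precise = bool((per_slab_scores["rmse_prime_star"] < 1.0).all())
    if accurate and precise:
        verdict = "Accurate and precise"
    elif accurate:
        verdict = "Accurate but not precise"
    else:
        direction = "Positively biased" if (per_slab_scores["bias_star"] > 0).any() \
            else "Negatively biased"
        verdict = f"{direction} and not precise" if not precise else f"{direction} but precise"
    return {"accurate": accurate, "precise": precise, "verdict": verdict}


def target_diagram_coordinates(per_slab_scores: pd.DataFrame) -> pd.DataFrame:
    """(x, y) coordinates for a target diagram: x = signed RMSE*', y = B*."""
    return per_slab_scores[["increment_top", "signed_rmse_prime", "bias_star"]].rename(
        columns={"signed_rmse_prime": "x", "bias_star": "y"})
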