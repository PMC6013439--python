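"""Random-intercept mixed-effects models of carbon density with AICc selection.

Carbon density (gC cm^-3) at the 10-cm-increment level is modeled as

    carbon_density ~ fixed categorical effects + (1 | submitter)

where candidate fixed effects are climate zone, salinity x vegetation
class, organic/mineral soil class, and depth increment (a 10-level
factor), plus their interactions.  Because syntheses combine labs with
different loss-on-ignition and bulk-density protocols, the submitter
random intercept absorbs lab-level bias.

Models are fitted by maximum likelihood (not REML) so AICc is comparable
across fixed-effect structures; ``dredge_models`` enumerates every
marginality-respecting subset of the candidate terms and ranks it by
AICc with Akaike weights.  Effect sizes are adjusted omega-squared values
computed from a Type-III ANOVA on the fixed-effects design (sum-to-zero
coding) — a reproducible approximation to the mixed-model ANOVA — and
variance explained is summarized with Nakagawa-Schielzeth marginal and
conditional pseudo-R^2.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "MixedModelFit",
    "fit_mixed_model",
    "aicc",
    "dredge_models",
    "omega_squared",
    "omega_squared_from_anova",
    "pseudo_r2",
    "nakagawa_r2",
    "predict_fixed",
]

CANDIDATE_MAIN_TERMS = ("climate", "sal_veg", "soil", "depth")

_TERM_TO_COLUMN = {"climate": "climate", "sal_veg": "sal_veg",
                   "soil": "soil_class", "depth": "increment_top"}


def _formula_piece(term: str, sum_coding: bool = False) -> str:
    parts = term.split(":")
    coding = ", Sum" if sum_coding else ""
    return ":".join(f"C({_TERM_TO_COLUMN[p]}{coding})" for p in parts)


def _build_formula(fixed_terms: Sequence[str], sum_coding: bool = False) -> str:
    if not fixed_terms:
        return "carbon_density ~ 1"
    rhs = " + ".join(_formula_piece(t, sum_coding) for t in fixed_terms)
    return f"carbon_density ~ {rhs}"


@dataclass
class MixedModelFit:
    """A fitted random-intercept model of carbon density."""
    fixed_terms: Tuple[str, ...]
    formula: str
    coefficients: pd.Series
    submitter_intercept_sd: float
    submitter_intercept_sd_standardized: float
    log_likelihood: float
    aicc: float
    pseudo_r2_marginal: float
    pseudo_r2_conditional: float
    n: int
    k_params: int
    converged: bool
    result: object  # statsmodels MixedLMResults
    design_info: object = None  # patsy DesignInfo of the full fixed design
    kept_columns: Optional[Sequence[str]] = None  # rank-pruned design columns
    train_levels: Optional[Dict[str, frozenset]] = None


def aicc(log_likelihood: float, k_params: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    AICc = AIC + 2k(k+1)/(n-k-1) with AIC = 2k - 2*logLik.
    """
    if n <= k_params + 1:
        raise ValueError("AICc undefined for n <= k_params + 1")
    aic = 2 * k_params - 2 * log_likelihood
    return aic + 2 * k_params * (k_params + 1) / (n - k_params - 1)


def _validate_records(records: pd.DataFrame, fixed_terms: Sequence[str]) -> pd.DataFrame:
    cols = {"carbon_density", "submitter_id"}
    for t in fixed_terms:
        cols.update(_TERM_TO_COLUMN[p] for p in t.split(":"))
    missing = cols - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns: {sorted(missing)}")
    data = records.dropna(subset=list(cols)).reset_index(drop=True)
    if data["submitter_id"].nunique() < 2:
        raise ValueError("need at least 2 submitters for a random intercept")
    return data


def fit_mixed_model(records: pd.DataFrame, fixed_terms: Sequence[str],
                    sigma_c: Optional[float] = None) -> MixedModelFit:
    """Fit a random-intercept linear mixed model by maximum likelihood.

    Parameters
    ----------
    records : DataFrame
        Increment-level rows with ``carbon_density``, ``submitter_id`` and
        the covariate columns (``climate``, ``sal_veg``, ``soil_class``,
        ``increment_top``).
    fixed_terms : sequence of str
        Terms from {climate, sal_veg, soil, depth} and ``a:b`` interactions.
    sigma_c : float, optional
        Calibration-set carbon-density s.d. used to standardize the random
        intercept; defaults to the s.d. of ``records['carbon_density']``.

    A singular random-effect variance produces a fit with a warning and a
    reported variance of (numerically) zero rather than an error.
    """
    fixed_terms = tuple(fixed_terms)
    data = _validate_records(records, fixed_terms)
    formula = _build_formula(fixed_terms)
    from patsy import dmatrices
    y, X = dmatrices(formula, data, return_type="dataframe")
    design_info = X.design_info
    # drop rank-deficient columns (empty interaction cells) via pivoted QR
    Xv = X.to_numpy()
    from scipy.linalg import qr as _qr
    _, R, piv = _qr(Xv, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > max(Xv.shape) * np.finfo(float).eps * (diag[0] if len(diag) else 1.0)))
    keep = np.zeros(Xv.shape[1], dtype=bool)
    keep[np.sort(piv[:rank])] = True
    X_kept = X.loc[:, X.columns[keep]]
    model = sm.MixedLM(y.iloc[:, 0], X_kept, groups=data["submitter_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        result = model.fit(reml=False, maxiter=500)
    re_var = float(np.asarray(result.cov_re)[0, 0]) if result.cov_re.size else 0.0
    re_sd = math.sqrt(max(re_var, 0.0))
    sd_ref = float(sigma_c) if sigma_c is not None else float(data["carbon_density"].std(ddof=1))

    n = int(result.nobs)
    k = len(result.fe_params) + 2  # fixed effects + RE variance + residual variance
    ll = float(result.llf)

    var_f, var_r, var_e = (float(np.var(X_kept.to_numpy() @ result.fe_params.to_numpy())),
                           re_var, float(result.scale))
    marg, cond = nakagawa_r2(var_f, var_r, var_e)

    covariate_cols = sorted({_TERM_TO_COLUMN[p] for t in fixed_terms for p in t.split(":")})
    return MixedModelFit(
        fixed_terms=fixed_terms,
        formula=formula,
        coefficients=result.fe_params,
        submitter_intercept_sd=re_sd,
        submitter_intercept_sd_standardized=(re_sd / sd_ref if sd_ref > 0 else np.nan),
        log_likelihood=ll,
        aicc=aicc(ll, k, n),
        pseudo_r2_marginal=marg,
        pseudo_r2_conditional=cond,
        n=n,
        k_params=k,
        converged=bool(result.converged),
        result=result,
        design_info=design_info,
        kept_columns=list(X_kept.columns),
        train_levels={c: frozenset(data[c].unique()) for c in covariate_cols},
    )


def nakagawa_r2(var_fixed: float, var_random: float, var_residual: float
                ) -> Tuple[float, float]:
    """Marginal and conditional pseudo-R^2 from variance components."""
    total = var_fixed + var_random + var_residual
    if total <= 0:
        return np.nan, np.nan
    return var_fixed / total, (var_fixed + var_random) / total


def pseudo_r2(fit: MixedModelFit) -> Tuple[float, float]:
    """(marginal, conditional) pseudo-R^2 of a fitted mixed model."""
    return fit.pseudo_r2_marginal, fit.pseudo_r2_conditional


def _marginality_ok(subset: Sequence[str]) -> bool:
    present = set(subset)
    for term in subset:
        parts = term.split(":")
        # every lower-order margin of an interaction must be present
        for r in range(1, len(parts)):
            for combo in itertools.combinations(parts, r):
                if ":".join(combo) not in present:
                    return False
    return True


def enumerate_structures(candidate_terms: Sequence[str]) -> List[Tuple[str, ...]]:
    """All marginality-respecting subsets of the candidate terms."""
    if 2 ** len(candidate_terms) > 4096:
        raise ValueError("refusing to enumerate more than 2^12 candidate structures")
    out = []
    for r in range(len(candidate_terms) + 1):
        for combo in itertools.combinations(candidate_terms, r):
            if _marginality_ok(combo):
                out.append(tuple(combo))
    return out


def dredge_models(records: pd.DataFrame, candidate_terms: Sequence[str],
                  sigma_c: Optional[float] = None) -> pd.DataFrame:
    """Fit every marginality-respecting fixed-effect subset; rank by AICc.

    Returns a DataFrame sorted by AICc with columns ``terms, aicc,
    delta_aicc, akaike_weight, log_likelihood, k_params, fit`` (the fit
    column holds the :class:`MixedModelFit` objects; row 0 is the top
    model).
    """
    structures = enumerate_structures(candidate_terms)
    rows = []
    for terms in structures:
        fit = fit_mixed_model(records, terms, sigma_c=sigma_c)
        rows.append({"terms": terms, "aicc": fit.aicc,
                     "log_likelihood": fit.log_likelihood,
                     "k_params": fit.k_params, "fit": fit})
    table = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    w = np.exp(-0.5 * table["delta_aicc"].to_numpy())
    table["akaike_weight"] = w / w.sum()
    return table


def omega_squared_from_anova(ss_term: float, df_term: float, ms_error: float,
                             ss_total: float) -> float:
    """Adjusted effect size: (SS - df * MS_err) / (SS_total + MS_err)."""
    if ss_total + ms_error == 0:
        raise ValueError("omega-squared undefined for zero total sum of squares")
    return (ss_term - df_term * ms_error) / (ss_total + ms_error)


def omega_squared(records: pd.DataFrame, fixed_terms: Sequence[str]) -> pd.Series:
    """Per-term adjusted omega-squared for the fixed-effects design.

    Computed from a Type-III ANOVA of an OLS fit with sum-to-zero factor
    coding (the random intercept is profiled out of this decomposition;
    the result approximates the mixed-model ANOVA effect sizes).
    """
    fixed_terms = tuple(fixed_terms)
    data = _validate_records(records, fixed_terms)
    formula = _build_formula(fixed_terms, sum_coding=True)
    ols_fit = smf.ols(formula, data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            table = anova_lm(ols_fit, typ=3)
            if not np.isfinite(table["sum_sq"]).all():
                raise ValueError("non-finite Type-III sums of squares")
        except Exception:
            # empty interaction cells make Type III ill-posed; Type II is the
            # standard fallback for unbalanced designs
            table = anova_lm(ols_fit, typ=2)
    table = table.drop(index=[i for i in ("Intercept",) if i in table.index])
    ms_error = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    ss_total = float(table["sum_sq"].sum())
    out = {}
    for idx in table.index:
        if idx == "Residual":
            continue
        out[_anova_row_to_term(idx)] = omega_squared_from_anova(
            float(table.loc[idx, "sum_sq"]), float(table.loc[idx, "df"]),
            ms_error, ss_total)
    return pd.Series(out)


def _anova_row_to_term(row_name: str) -> str:
    """Map 'C(soil_class, Sum)'-style ANOVA rows back to term names."""
    inverse = {v: k for k, v in _TERM_TO_COLUMN.items()}
    parts = []
    for piece in row_name.split(":"):
        inner = piece.strip()
        if inner.startswith("C(") :
            inner = inner[2:].split(",")[0].rstrip(") ")
        parts.append(inverse.get(inner, inner))
    return ":".join(parts)


def predict_fixed(fit: MixedModelFit, covariates: pd.DataFrame) -> np.ndarray:
    """Fixed-effects-only prediction (random intercept set to zero).

    Used both for validation (true covariates) and application (mapped
    covariates); an unseen factor level raises an error naming it.
    """
    data = covariates.copy()
    # verify levels before patsy does, to give a readable error
    for term in fit.fixed_terms:
        for p in term.split(":"):
            col = _TERM_TO_COLUMN[p]
            new = set(data[col].dropna().unique()) - set(fit.train_levels[col])
            if new:
                raise ValueError(f"unseen level(s) {sorted(map(str, new))} for factor {p!r}")
    if not fit.fixed_terms:
        return np.full(len(data), float(fit.coefficients.iloc[0]))
    from patsy import build_design_matrices
    (X,) = build_design_matrices([fit.design_info], data, return_type="dataframe")
    return X[fit.kept_columns].to_numpy() @ fit.coefficients.to_numpy()
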