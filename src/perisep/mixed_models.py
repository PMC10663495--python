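"""Nested linear mixed-effects models of component amplitude.

Three models of per-subject, per-condition mean amplitude are fitted by
maximum likelihood (not REML, because the likelihood-ratio tests compare
fixed-effect structures): m1 has Condition only, m2 adds Age (in days,
centered at the sample mean), m3 adds the Condition x Age interaction; all
include a random intercept per participant.  Nested pairs are compared by
LRT: chi2 = 2 * (llf_full - llf_reduced) against a chi-square with the
fixed-parameter-count difference as df.  Forward selection at alpha keeps
the richest model whose addition is significant.

Fixed-effect p-values use the between-subject residual df (n_subjects - 2);
this df convention is recorded in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLMResults

MODEL_IDS = ("m1", "m2", "m3")

_COND = "C(condition, Treatment('receding'))"
FORMULAS = {
    "m1": f"amplitude_uv ~ {_COND}",
    "m2": f"amplitude_uv ~ {_COND} + age_c",
    "m3": f"amplitude_uv ~ {_COND} * age_c",
}

COMPARISONS = (("m2", "m1"), ("m3", "m1"), ("m3", "m2"))


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float


@dataclass
class ModelComparison:
    """Fits and likelihood-ratio comparisons of the nested models for one component."""

    component: str
    fits: dict
    loglik: dict
    lrts: dict
    selected: str
    singular: dict
    fixed_df: int
    coefficients: pd.DataFrame


def _prepare(amps: pd.DataFrame, component: str) -> pd.DataFrame:
    data = amps[amps["component"] == component].copy()
    if data.empty:
        raise ValueError(f"component '{component}' not found")
    if "age_days" not in data.columns or data["age_days"].isna().any():
        raise ValueError("ages are required for the mixed-model analysis")
    counts = data.groupby("subject", observed=True)["condition"].nunique()
    if (counts < 2).any():
        raise ValueError("every subject needs an amplitude in both conditions")
    data["age_c"] = data["age_days"] - data["age_days"].mean()
    return data


def fit_models(amps: pd.DataFrame, component: str) -> dict[str, MixedLMResults]:
    """ML fits of m1, m2, m3 on one component's amplitudes."""
    data = _prepare(amps, component)
    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mid in MODEL_IDS:
            model = smf.mixedlm(FORMULAS[mid], data, groups=data["subject"])
            fits[mid] = model.fit(reml=False)
    return fits


def lrt(full: MixedLMResults, reduced: MixedLMResults) -> LRTResult:
    """Likelihood-ratio test of two nested ML fits on identical data."""
    if full.nobs != reduced.nobs:
        raise ValueError("models were fitted on different data")
    full_terms = set(full.model.exog_names)
    reduced_terms = set(reduced.model.exog_names)
    if not reduced_terms <= full_terms:
        raise ValueError("reduced model is not nested in the full model")
    if full.model.reml or reduced.model.reml:
        raise ValueError("LRT on fixed effects requires ML (not REML) fits")
    df = len(full_terms) - len(reduced_terms)
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(chi2=float(chi2), df=df, p=p)


def select_model(lrts: dict[str, LRTResult], alpha: float = 0.05) -> str:
    """Forward selection: m3 if m3-vs-m2 is significant, else m2 if m2-vs-m1 is, else m1."""
    if lrts["m3_vs_m2"].p < alpha:
        return "m3"
    if lrts["m2_vs_m1"].p < alpha:
        return "m2"
    return "m1"


def _coefficient_table(fits: dict, fixed_df: int) -> pd.DataFrame:
    rows = []
    for mid, res in fits.items():
        fe = res.fe_params
        for term in fe.index:
            est = float(fe[term])
            se = float(res.bse[term])
            t = est / se if se > 0 else np.nan
            p = 2.0 * stats.t.sf(abs(t), fixed_df) if np.isfinite(t) else np.nan
            rows.append(
                {
                    "model": mid,
                    "term": term,
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "df": fixed_df,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def compare_models(
    amps: pd.DataFrame, component: str, alpha: float = 0.05
) -> ModelComparison:
    """Fit the nested models for one component and run all three LRTs."""
    fits = fit_models(amps, component)
    lrts = {
        f"{full}_vs_{red}": lrt(fits[full], fits[red]) for full, red in COMPARISONS
    }
    n_subjects = amps.loc[amps["component"] == component, "subject"].nunique()
    fixed_df = n_subjects - 2
    singular = {
        mid: bool(np.all(np.asarray(res.cov_re) < 1e-8)) for mid, res in fits.items()
    }
    return ModelComparison(
        component=component,
        fits=fits,
        loglik={mid: float(res.llf) for mid, res in fits.items()},
        lrts=lrts,
        selected=select_model(lrts, alpha),
        singular=singular,
        fixed_df=fixed_df,
        coefficients=_coefficient_table(fits, fixed_df),
    )


def comparison_table(comparisons: list[ModelComparison]) -> pd.DataFrame:
    """One row per component with the three LRTs and the selected model."""
    rows = []
    for cmp_ in comparisons:
        row = {"component": cmp_.component}
        for key in ("m2_vs_m1", "m3_vs_m1", "m3_vs_m2"):
            r = cmp_.lrts[key]
            row[f"{key}_df"] = r.df
            row[f"{key}_chi2"] = r.chi2
            row[f"{key}_p"] = r.p
        row["selected"] = cmp_.selected
        row["singular"] = any(cmp_.singular.values())
        rows.append(row)
    return pd.DataFrame(rows)
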