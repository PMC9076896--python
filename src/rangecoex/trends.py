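"""Elevation-trend inference on growth rates and coexistence quantities.

Mixed-effects models with elevation (continuous, metres) crossed with a
grouping factor (species origin for growth rates; pair type for coexistence
quantities) as fixed effects and focal species or species pair as a random
intercept.  Fixed effects are tested with likelihood-ratio tests on models
fitted by maximum likelihood; the interaction is tested against the
both-mains model.  To propagate parameter uncertainty, the same model is
also fitted to each bootstrap replicate and a term or contrast is judged
significant when the 95% percentile interval of its per-replicate estimates
excludes zero.

Responses follow the transformation conventions of the coexistence module:
ln lambda, log coexistence metric, log niche overlap (= 1 - ND, which unlike
ND is positive), log |RFD| for pooled/sympatric analyses and signed ln RFD
for mixed-origin pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = ["TrendResult", "fit_trend", "per_replicate_test", "tally_outcomes"]


@dataclass
class TrendResult:
    """Result of one fixed-term test, possibly with bootstrap propagation."""

    term: str
    stat: float
    df: int
    p: float
    coefficients: pd.Series | None = None
    replicate_median: float | None = None
    replicate_ci: tuple[float, float] | None = None
    n_replicates_failed: int = 0
    flags: set = field(default_factory=set)

    @property
    def significant_after_propagation(self) -> bool | None:
        if self.replicate_ci is None:
            return None
        lo, hi = self.replicate_ci
        return bool(lo > 0.0 or hi < 0.0)


def _fit_ml(formula: str, data: pd.DataFrame, groups: str | None):
    """Maximum-likelihood fit: random-intercept mixed model, or OLS when no
    grouping column is given or the mixed fit fails/degenerates."""
    if groups is not None:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.mixedlm(formula, data, groups=data[groups]).fit(reml=False)
            if np.isfinite(res.llf) and res.converged:
                return res, set()
        except Exception:
            pass
    res = smf.ols(formula, data).fit()
    return res, {"fixed_effects_fallback"} if groups is not None else set()


def fit_trend(
    data: pd.DataFrame,
    response: str,
    group: str,
    random_effect: str | None = "species",
    elevation: str = "site_elevation_m",
    test: str = "interaction",
) -> TrendResult:
    """Likelihood-ratio test of an elevation-trend fixed effect.

    ``test='interaction'`` compares elevation*group against the both-mains
    model; ``test='elevation'`` compares elevation (no group terms in either
    model) against the intercept-only model.  Models are fitted by ML so the
    LRT is valid; a singular mixed fit falls back to fixed effects only.
    """
    df = data.dropna(subset=[response, elevation]).copy()
    if df[elevation].nunique() < 2:
        raise ValueError("need at least two elevations")
    if test == "interaction":
        if df[group].nunique() < 2:
            raise ValueError("need at least two groups for an interaction test")
        full_f = f"{response} ~ {elevation} * C({group})"
        red_f = f"{response} ~ {elevation} + C({group})"
        term = f"{elevation}:{group}"
    elif test == "elevation":
        full_f = f"{response} ~ {elevation}"
        red_f = f"{response} ~ 1"
        term = elevation
    else:
        raise ValueError(f"unknown test {test!r}")

    full, flags_f = _fit_ml(full_f, df, random_effect)
    red, flags_r = _fit_ml(red_f, df, random_effect)
    flags = flags_f | flags_r
    stat = max(2.0 * (full.llf - red.llf), 0.0)
    k_full = len(full.fe_params) if hasattr(full, "fe_params") else len(full.params)
    k_red = len(red.fe_params) if hasattr(red, "fe_params") else len(red.params)
    dof = max(k_full - k_red, 1)
    p = float(stats.chi2.sf(stat, dof))
    coefs = full.fe_params if hasattr(full, "fe_params") else full.params
    return TrendResult(term=term, stat=float(stat), df=dof, p=p,
                       coefficients=pd.Series(coefs), flags=flags)


def _contrast_value(params: pd.Series, contrast: str | dict[str, float]) -> float:
    if isinstance(contrast, str):
        matches = [n for n in params.index if contrast in n]
        if len(matches) != 1:
            raise KeyError(f"contrast {contrast!r} matches {matches} in {list(params.index)}")
        return float(params[matches[0]])
    return float(sum(w * params[n] for n, w in contrast.items()))


def per_replicate_test(
    data: pd.DataFrame,
    response: str,
    group: str | None,
    contrast: str | dict[str, float],
    random_effect: str | None = None,
    elevation: str = "site_elevation_m",
    replicate: str = "replicate",
) -> TrendResult:
    """Median and 95% percentile CI of a coefficient across replicates.

    Fits the trend model separately to every bootstrap replicate and
    collects the contrast; the term is significant after error propagation
    iff the interval excludes zero.  Replicates that fail to fit are dropped
    and counted.  By default the per-replicate fits are fixed-effects
    (random_effect=None): with one observation per context within a
    replicate the random intercept is typically unidentifiable, and the
    replicate spread itself carries the propagated uncertainty.
    """
    rhs = f"{elevation} * C({group})" if group is not None else elevation
    formula = f"{response} ~ {rhs}"
    values = []
    n_failed = 0
    for _, sub in data.dropna(subset=[response]).groupby(replicate, sort=True):
        try:
            res, _ = _fit_ml(formula, sub, random_effect)
            params = res.fe_params if hasattr(res, "fe_params") else res.params
            values.append(_contrast_value(pd.Series(params), contrast))
        except (KeyError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if len(values) < 2:
        raise ValueError("fewer than two replicates could be fitted")
    med, lo, hi = np.percentile(values, [50.0, 2.5, 97.5])
    name = contrast if isinstance(contrast, str) else "+".join(contrast)
    return TrendResult(
        term=name,
        stat=np.nan,
        df=0,
        p=np.nan,
        replicate_median=float(med),
        replicate_ci=(float(lo), float(hi)),
        n_replicates_failed=n_failed,
    )


def tally_outcomes(
    pairs: pd.DataFrame,
    site: float | None = None,
    pair_type: str | None = None,
) -> dict:
    """Bootstrap-mean counts of coexisting vs non-coexisting pairs.

    Per replicate, counts pairs classified as stable coexistence and pairs
    classified as exclusion or priority effect within the stratum; reports
    the means, percentile 95% CIs and the mean coexisting fraction relative
    to the stratum's classified pairs.
    """
    df = pairs[pairs["outcome"].notna()]
    if site is not None:
        df = df[df["site_elevation_m"] == site]
    if pair_type is not None:
        df = df[df["pair_type"] == pair_type]
    if df.empty:
        return {
            "n_replicates": 0,
            "mean_coexisting": np.nan,
            "mean_not_coexisting": np.nan,
            "ci_coexisting": (np.nan, np.nan),
            "ci_not_coexisting": (np.nan, np.nan),
            "mean_fraction_coexisting": np.nan,
        }
    co, nco = [], []
    for _, sub in df.groupby("replicate", dropna=False, sort=True):
        n_co = int((sub["outcome"] == "stable_coexistence").sum())
        co.append(n_co)
        nco.append(len(sub) - n_co)
    co_arr, nco_arr = np.asarray(co, float), np.asarray(nco, float)

    def _ci(a):
        if len(a) < 2:
            return (float(a[0]), float(a[0]))
        lo, hi = np.percentile(a, [2.5, 97.5])
        return (float(lo), float(hi))

    tot = co_arr + nco_arr
    frac = np.divide(co_arr, tot, out=np.full_like(co_arr, np.nan), where=tot > 0)
    return {
        "n_replicates": len(co),
        "mean_coexisting": float(co_arr.mean()),
        "mean_not_coexisting": float(nco_arr.mean()),
        "ci_coexisting": _ci(co_arr),
        "ci_not_coexisting": _ci(nco_arr),
        "mean_fraction_coexisting": float(np.nanmean(frac)),
    }
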