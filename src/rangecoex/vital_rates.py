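"""Size-structured vital-rate regressions with AICc model selection.

Six vital rates describe the annual life cycle of a focal plant of
log-biomass ``z``: survival ``s(z)``, growth ``G(z'|z)`` (Gaussian mean and
residual SD), flowering probability ``p_fl(z)``, seed production ``f(z)``,
size-independent germination ``g`` and establishment ``e``, and the recruit
size density ``phi(z')``.  Survival and flowering are binomial GLMs with a
logit link; growth and log seed production are Gaussian linear models; g and
e are raw proportions from sowing trials; recruit size is a Gaussian fitted
to first-observation sizes.

For each species and size-dependent rate, every hierarchy-valid submodel of a
full model in size, site and background competitor is fitted and the model
with the smallest AICc is retained.  Coefficient vectors and their
covariance matrices are kept for parametric-bootstrap resampling.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy.special import expit

__all__ = [
    "ModelSpec",
    "VitalRateFit",
    "VitalRateSet",
    "DemographyModel",
    "aicc",
    "enumerate_nested_models",
    "fit_vital_rate",
    "select_by_aicc",
    "fit_recruitment",
    "fit_offspring_size",
    "fit_demography",
    "PROB_CLIP",
]

#: probability predictions are clipped to this open interval
PROB_CLIP = 1e-12

VALID_TERMS = ("z", "site", "background", "z:site", "z:background", "site:background")

FULL_TERMS = frozenset({"z", "site", "background", "z:site", "z:background"})

_RESPONSES = ("survival", "growth", "flowering", "fecundity", "offspring_size")

_BINOMIAL = {"survival", "flowering"}

_TERM_TO_PATSY = {
    "z": "z",
    "site": "C(site)",
    "background": "C(background)",
    "z:site": "z:C(site)",
    "z:background": "z:C(background)",
    "site:background": "C(site):C(background)",
}


def _hierarchy_valid(terms: frozenset[str]) -> bool:
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            if a not in terms or b not in terms:
                return False
    return True


@dataclass(frozen=True)
class ModelSpec:
    """A vital-rate regression structure: response, family and term set.

    The intercept is always included; ``terms`` is a subset of
    ``{"z", "site", "background", "z:site", "z:background", "site:background"}``
    and must respect marginality (an interaction requires both mains).
    """

    response: str
    terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.response not in _RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        terms = frozenset(self.terms)
        object.__setattr__(self, "terms", terms)
        unknown = terms - set(VALID_TERMS)
        if unknown:
            raise ValueError(f"unknown terms {sorted(unknown)}")
        if not _hierarchy_valid(terms):
            raise ValueError(
                f"terms {sorted(terms)} violate marginality "
                "(interaction without its main effects)"
            )

    @property
    def family(self) -> str:
        return "binomial-logit" if self.response in _BINOMIAL else "gaussian-identity"

    @property
    def sorted_terms(self) -> tuple[str, ...]:
        return tuple(t for t in VALID_TERMS if t in self.terms)

    def formula_rhs(self) -> str:
        rhs = ["1"] + [_TERM_TO_PATSY[t] for t in self.sorted_terms]
        return " + ".join(rhs)


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion corrected for small samples.

    ``AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1)``; requires ``n > k+1``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def enumerate_nested_models(full: ModelSpec) -> list[ModelSpec]:
    """All hierarchy-valid submodels of ``full``, intercept-only included."""
    terms = sorted(full.terms)
    out = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            s = frozenset(combo)
            if _hierarchy_valid(s):
                out.append(ModelSpec(full.response, s))
    return out


@dataclass
class VitalRateFit:
    """A fitted vital-rate regression.

    ``coef``/``vcov`` are on the linear-predictor scale; ``design_info`` is
    the patsy design for rebuilding model matrices at prediction time.
    ``sigma`` is the Gaussian residual SD (None for binomial).  ``flags``
    marks degenerate or failed fits ('degenerate', 'failed', 'ineligible').
    """

    spec: ModelSpec
    coef: np.ndarray
    coef_names: list[str]
    vcov: np.ndarray
    loglik: float
    n_obs: int
    k_params: int
    aicc: float
    design_info: object | None = None
    sigma: float | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def valid(self) -> bool:
        return not ({"failed", "ineligible"} & self.flags)

    def linear_predictor(self, df: pd.DataFrame, coef: np.ndarray | None = None) -> np.ndarray:
        c = self.coef if coef is None else np.asarray(coef, dtype=float)
        if self.design_info is None:
            return np.full(len(df), float(c[0]))
        (X,) = patsy.build_design_matrices([self.design_info], df)
        return np.asarray(X) @ c

    def predict(self, df: pd.DataFrame, coef: np.ndarray | None = None) -> np.ndarray:
        eta = self.linear_predictor(df, coef)
        if self.spec.family == "binomial-logit":
            return np.clip(expit(eta), PROB_CLIP, 1.0 - PROB_CLIP)
        return eta


def _prepare(records: pd.DataFrame, response: str) -> pd.DataFrame:
    """Extract the (y, z, site, background) analysis frame for one response."""
    df = pd.DataFrame(
        {
            "z": records["size_t"].to_numpy(dtype=float),
            "site": records["site_elevation_m"].astype(str).to_numpy(),
            "background": records["background"].fillna("none").astype(str).to_numpy(),
        }
    )
    if response == "survival":
        df["y"] = records["survived"].to_numpy(dtype=float)
    elif response == "growth":
        df["y"] = records["size_t1"].to_numpy(dtype=float)
        df = df[(records["survived"].to_numpy() == 1) & np.isfinite(df["y"])]
    elif response == "flowering":
        df["y"] = records["flowered"].to_numpy(dtype=float)
        df = df[np.isfinite(df["y"])]
    elif response == "fecundity":
        seeds = records["seeds"].to_numpy(dtype=float)
        df["y"] = np.log1p(seeds)
        df = df[(records["flowered"].to_numpy() == 1) & np.isfinite(df["y"])]
    else:
        raise ValueError(f"no tabular preparation for response {response!r}")
    return df.reset_index(drop=True)


def fit_vital_rate(records: pd.DataFrame, spec: ModelSpec) -> VitalRateFit:
    """Maximum-likelihood fit of one vital-rate regression.

    Binomial responses that are all-zero or all-one yield an intercept-only
    fit at a clipped probability with zero variance, flagged 'degenerate'.
    Non-convergence or perfect separation flags the fit 'failed'; too few
    rows for AICc flags it 'ineligible'.  Flagged fits are excluded from
    AICc selection.
    """
    df = _prepare(records, spec.response)
    y = df["y"].to_numpy(dtype=float)
    n = len(df)
    binomial = spec.family == "binomial-logit"

    if binomial and n > 0 and (y.min() == y.max()):
        p = np.clip(y.mean(), PROB_CLIP, 1.0 - PROB_CLIP)
        coef = np.array([np.log(p / (1.0 - p))])
        ll = float(n * (y.mean() * np.log(p) + (1 - y.mean()) * np.log(1 - p)))
        return VitalRateFit(
            spec=ModelSpec(spec.response, frozenset()),
            coef=coef,
            coef_names=["Intercept"],
            vcov=np.zeros((1, 1)),
            loglik=ll,
            n_obs=n,
            k_params=1,
            aicc=aicc(ll, 1, n) if n > 2 else np.inf,
            design_info=None,
            flags={"degenerate"},
        )

    try:
        ymat, X = patsy.dmatrices("y ~ " + spec.formula_rhs(), df, return_type="dataframe")
    except Exception:
        return _failed_fit(spec, n)
    k_lin = X.shape[1]
    k = k_lin + (0 if binomial else 1)  # +1: Gaussian residual variance
    if n < k_lin + 2:
        f = _failed_fit(spec, n)
        f.flags = {"ineligible"}
        return f

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            if binomial:
                res = sm.GLM(np.asarray(ymat).ravel(), np.asarray(X), family=sm.families.Binomial()).fit()
            else:
                res = sm.OLS(np.asarray(ymat).ravel(), np.asarray(X)).fit()
    except Exception:
        return _failed_fit(spec, n)

    coef = np.asarray(res.params, dtype=float)
    vcov = np.asarray(res.cov_params(), dtype=float)
    if not (np.all(np.isfinite(coef)) and np.all(np.isfinite(vcov))):
        return _failed_fit(spec, n)
    ll = float(res.llf)
    sigma = None
    if not binomial:
        resid = np.asarray(res.resid)
        dof = max(n - k_lin, 1)
        sigma = float(np.sqrt(resid @ resid / dof))
    try:
        a = aicc(ll, k, n)
    except ValueError:
        a = np.inf
    fit = VitalRateFit(
        spec=spec,
        coef=coef,
        coef_names=list(X.columns),
        vcov=vcov,
        loglik=ll,
        n_obs=n,
        k_params=k,
        aicc=a,
        design_info=X.design_info,
        sigma=sigma,
    )
    if not np.isfinite(a):
        fit.flags.add("ineligible")
    return fit


def _failed_fit(spec: ModelSpec, n: int) -> VitalRateFit:
    return VitalRateFit(
        spec=spec,
        coef=np.array([np.nan]),
        coef_names=["Intercept"],
        vcov=np.array([[np.nan]]),
        loglik=np.nan,
        n_obs=n,
        k_params=1,
        aicc=np.inf,
        flags={"failed"},
    )


def select_by_aicc(fits: list[VitalRateFit]) -> VitalRateFit:
    """Minimum-AICc fit; ties go to fewer parameters, then term order."""
    valid = [f for f in fits if f.valid and np.isfinite(f.aicc)]
    if not valid:
        # degenerate fits are still usable as a last resort
        valid = [f for f in fits if "failed" not in f.flags]
    if not valid:
        raise ValueError("no valid fits to select from")
    return min(valid, key=lambda f: (f.aicc, f.k_params, f.spec.sorted_terms))


def fit_recruitment(trials: pd.DataFrame) -> pd.DataFrame:
    """Germination and establishment proportions per species x site.

    ``g = n_germinated / n_sown``; ``e = n_established / n_germinated``.
    A zero germination count yields ``e = 0`` flagged undefined.
    """
    t = trials.copy()
    sown = t["n_sown"].to_numpy(dtype=float)
    germ = t["n_germinated"].to_numpy(dtype=float)
    est = t["n_established"].to_numpy(dtype=float)
    if np.any(sown < 1):
        raise ValueError("n_sown must be >= 1")
    if np.any(germ > sown) or np.any(est > germ) or np.any(est < 0):
        raise ValueError("need n_established <= n_germinated <= n_sown and all >= 0")
    t["g"] = germ / sown
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(germ > 0, est / np.maximum(germ, 1), 0.0)
    t["e"] = e
    t["e_undefined"] = germ == 0
    return t


def fit_offspring_size(sizes: np.ndarray) -> tuple[float, float]:
    """Gaussian recruit-size density: mean and SD of first-observation sizes."""
    s = np.asarray(sizes, dtype=float)
    s = s[np.isfinite(s)]
    if len(s) < 2:
        raise ValueError("need >= 2 recruit sizes")
    return float(s.mean()), float(s.std(ddof=1))


@dataclass
class VitalRateSet:
    """Callable vital rates for one (species, site, background) context.

    Probabilities are clipped to the open unit interval; ``fecundity``
    returns the expected seed count of a flowering plant (non-negative).
    """

    survival: object  # z -> probability
    growth_mean: object  # z -> mean size next year
    growth_sd: float
    flowering: object  # z -> probability
    fecundity: object  # z -> expected seeds | flowering
    germination: float
    establishment: float
    recruit_mean: float
    recruit_sd: float

    def __post_init__(self) -> None:
        if not (self.growth_sd > 0 and self.recruit_sd > 0):
            raise ValueError("growth_sd and recruit_sd must be > 0")
        ge = self.germination * self.establishment
        if not (0.0 <= ge < 1.0 + 1e-12):
            raise ValueError("germination x establishment must lie in [0, 1)")


#: vital rates whose parameters are resampled in the parametric bootstrap
SIZE_DEPENDENT = ("survival", "growth", "flowering", "fecundity")


class DemographyModel:
    """Selected vital-rate fits for every species, plus recruitment rates.

    The central fitted object of the pipeline: it exposes, for any
    (species, site elevation, background) context, a :class:`VitalRateSet`
    whose size-dependent components evaluate the selected regressions --
    optionally at bootstrap-resampled coefficient vectors.
    """

    def __init__(
        self,
        fits: dict[str, dict[str, VitalRateFit]],
        recruitment: pd.DataFrame,
        offspring: dict[str, tuple[float, float]],
        selection_tables: dict[str, pd.DataFrame] | None = None,
    ) -> None:
        self.fits = fits
        self.recruitment = fit_recruitment(recruitment) if "g" not in recruitment else recruitment
        self.offspring = offspring
        self.selection_tables = selection_tables or {}

    @property
    def species(self) -> list[str]:
        return sorted(self.fits)

    def _recruit_rates(self, species: str, site_elevation: float) -> tuple[float, float]:
        r = self.recruitment
        row = r[(r["species"] == species) & (r["site_elevation_m"] == site_elevation)]
        if len(row) == 0:
            raise KeyError(f"no recruitment trial for {species} at {site_elevation} m")
        return float(row["g"].iloc[0]), float(row["e"].iloc[0])

    def vital_rate_set(
        self,
        species: str,
        site_elevation: float,
        background: str | None = None,
        coef_overrides: dict[str, np.ndarray] | None = None,
    ) -> VitalRateSet:
        if species not in self.fits:
            raise KeyError(f"unknown species {species!r}")
        fits = self.fits[species]
        over = coef_overrides or {}
        bg = "none" if background is None else str(background)
        site = str(site_elevation)

        def _frame(z: np.ndarray) -> pd.DataFrame:
            z = np.atleast_1d(np.asarray(z, dtype=float))
            return pd.DataFrame({"z": z, "site": site, "background": bg})

        def _predictor(resp: str):
            fit = fits[resp]
            coef = over.get(resp)
            return lambda z: fit.predict(_frame(z), coef=coef)

        fec_fit = fits["fecundity"]
        fec_coef = over.get("fecundity")

        def fecundity(z: np.ndarray) -> np.ndarray:
            # Gaussian fit on log(seeds + 1); back-transform without smearing
            eta = fec_fit.linear_predictor(_frame(z), coef=fec_coef)
            return np.maximum(np.expm1(eta), 0.0)

        g, e = self._recruit_rates(species, site_elevation)
        mu_r, sd_r = self.offspring[species]
        return VitalRateSet(
            survival=_predictor("survival"),
            growth_mean=_predictor("growth"),
            growth_sd=float(fits["growth"].sigma),
            flowering=_predictor("flowering"),
            fecundity=fecundity,
            germination=g,
            establishment=e,
            recruit_mean=mu_r,
            recruit_sd=sd_r,
        )


def fit_demography(
    records: pd.DataFrame,
    recruitment: pd.DataFrame,
    full_terms: frozenset[str] = FULL_TERMS,
    select: bool = True,
    include_replacements: bool = True,
) -> DemographyModel:
    """Fit and AICc-select all vital-rate models for every species.

    Transitions are pooled across years.  ``include_replacements=False``
    drops replacement individuals from the survival model only (their
    first-transition records may reflect transplant shock).
    """
    fits: dict[str, dict[str, VitalRateFit]] = {}
    offspring: dict[str, tuple[float, float]] = {}
    tables: dict[str, pd.DataFrame] = {}
    for species, sub in records.groupby("species", sort=True):
        sp_fits: dict[str, VitalRateFit] = {}
        rows = []
        for response in SIZE_DEPENDENT:
            data = sub
            if response == "survival" and not include_replacements:
                data = sub[sub["is_replacement"] == 0]
            full = ModelSpec(response, full_terms)
            candidates = enumerate_nested_models(full) if select else [full]
            cand_fits = [fit_vital_rate(data, spec) for spec in candidates]
            best = select_by_aicc(cand_fits)
            sp_fits[response] = best
            for f in cand_fits:
                rows.append(
                    {
                        "response": response,
                        "terms": "+".join(f.spec.sorted_terms) or "1",
                        "k": f.k_params,
                        "n": f.n_obs,
                        "loglik": f.loglik,
                        "aicc": f.aicc,
                        "selected": f is best,
                    }
                )
        # recruit-size density from each individual's first recorded size
        # (initial transplants and replacements enter at recruit size)
        first_obs = sub.sort_values("year").groupby("individual_id", sort=False).head(1)
        new_sizes = first_obs["size_t"].to_numpy(dtype=float)
        offspring[species] = fit_offspring_size(new_sizes)
        fits[str(species)] = sp_fits
        tables[str(species)] = pd.DataFrame(rows)
    return DemographyModel(fits, recruitment, offspring, tables)
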