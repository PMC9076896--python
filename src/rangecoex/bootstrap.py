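"""Parametric bootstrap of vital-rate parameters.

Estimation uncertainty in the size-dependent vital rates (survival, growth,
flowering, fecundity) is propagated to every growth rate and coexistence
quantity by resampling each selected model's coefficient vector from a
multivariate normal centred at the estimates with the fitted covariance
matrix.  One coherent draw per species x vital rate per replicate is shared
across all kernels that use the model; size-independent quantities
(germination, establishment, residual SDs, recruit-size density) are held
fixed.  Default: 500 replicates; summaries are medians with percentile 95%
confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexistence import pair_table
from .ipm import Mesh, build_kernel, lambda_of, make_mesh
from .vital_rates import SIZE_DEPENDENT, DemographyModel, VitalRateFit

__all__ = ["BootstrapEnsemble", "draw_parameters", "run_bootstrap", "summarize"]


def _psd_vcov(vcov: np.ndarray) -> np.ndarray:
    """Nearest-PSD repair by clipping negative eigenvalues at zero."""
    vcov = np.asarray(vcov, dtype=float)
    vcov = 0.5 * (vcov + vcov.T)
    w = np.linalg.eigvalsh(vcov)
    if w.min() >= -1e-10 * max(abs(w.max()), 1.0):
        return vcov
    warnings.warn("covariance matrix not PSD; clipping negative eigenvalues")
    w, V = np.linalg.eigh(vcov)
    return (V * np.clip(w, 0.0, None)) @ V.T


def draw_parameters(fit: VitalRateFit, rng: np.random.Generator) -> np.ndarray:
    """One multivariate-normal draw of a fit's coefficient vector."""
    vcov = _psd_vcov(fit.vcov)
    if not np.any(vcov):
        return fit.coef.copy()
    return rng.multivariate_normal(fit.coef, vcov, method="eigh")


@dataclass
class BootstrapEnsemble:
    """Growth rates and coexistence quantities for every bootstrap replicate.

    ``lambdas`` is long-format (replicate, species, site_elevation_m,
    background, lambda, ln_lambda); ``pairs`` is the per-replicate output of
    :func:`rangecoex.coexistence.pair_table` (None when no pairs were
    requested).  Replicate 0 with ``B`` replicates numbered 1..B; failed
    replicates are excluded and counted.
    """

    B: int
    seed: int
    lambdas: pd.DataFrame
    pairs: pd.DataFrame | None = None
    n_failed: int = 0
    failed_replicates: list[int] = field(default_factory=list)

    def summarize_lambda(self) -> pd.DataFrame:
        rows = []
        for key, sub in self.lambdas.groupby(
            ["species", "site_elevation_m", "background"], sort=True
        ):
            med, lo, hi = summarize(sub["ln_lambda"].to_numpy())
            rows.append(
                {
                    "species": key[0],
                    "site_elevation_m": key[1],
                    "background": key[2],
                    "ln_lambda_median": med,
                    "ln_lambda_lo95": lo,
                    "ln_lambda_hi95": hi,
                }
            )
        return pd.DataFrame(rows)


def summarize(values) -> tuple[float, float, float]:
    """Median and percentile 95% CI (linear interpolation) across replicates."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("need >= 2 valid replicates to summarize")
    med, lo, hi = np.percentile(v, [50.0, 2.5, 97.5])
    return float(med), float(lo), float(hi)


class _KernelContext:
    """Precomputed design matrices for one (species, site, background) kernel.

    The mesh midpoints and factor levels are fixed across replicates, so the
    model matrices can be built once; each replicate is then four
    matrix-vector products plus kernel assembly.
    """

    def __init__(
        self,
        demog: DemographyModel,
        species: str,
        site: float,
        background: str | None,
        mesh: Mesh,
    ) -> None:
        import pandas as pd
        import patsy

        self.species = species
        self.site = site
        self.background = "none" if background is None else str(background)
        self.mesh = mesh
        df = pd.DataFrame(
            {"z": mesh.midpoints, "site": str(site), "background": self.background}
        )
        self.fits = demog.fits[species]
        self.X: dict[str, np.ndarray] = {}
        for resp in SIZE_DEPENDENT:
            di = self.fits[resp].design_info
            if di is None:
                self.X[resp] = np.ones((mesh.n_bins, 1))
            else:
                (X,) = patsy.build_design_matrices([di], df)
                self.X[resp] = np.asarray(X)
        base = demog.vital_rate_set(species, site, background)
        self.growth_sd = base.growth_sd
        self.germination = base.germination
        self.establishment = base.establishment
        self.recruit_mean = base.recruit_mean
        self.recruit_sd = base.recruit_sd

    def vital_rate_set(self, overrides: dict[str, np.ndarray] | None):
        from .vital_rates import PROB_CLIP, VitalRateSet

        over = overrides or {}

        def coef(resp):
            return over.get(resp, self.fits[resp].coef)

        def prob(resp):
            from scipy.special import expit

            eta = self.X[resp] @ coef(resp)
            return np.clip(expit(eta), PROB_CLIP, 1.0 - PROB_CLIP)

        return VitalRateSet(
            survival=lambda z: prob("survival"),
            growth_mean=lambda z: self.X["growth"] @ coef("growth"),
            growth_sd=self.growth_sd,
            flowering=lambda z: prob("flowering"),
            fecundity=lambda z: np.maximum(np.expm1(self.X["fecundity"] @ coef("fecundity")), 0.0),
            germination=self.germination,
            establishment=self.establishment,
            recruit_mean=self.recruit_mean,
            recruit_sd=self.recruit_sd,
        )


def _replicate_lambdas(
    kernel_contexts: list[_KernelContext],
    overrides: dict[str, dict[str, np.ndarray]] | None,
    replicate: int,
) -> list[dict]:
    rows = []
    for ctx in kernel_contexts:
        over = overrides.get(ctx.species) if overrides else None
        vr = ctx.vital_rate_set(over)
        est = lambda_of(build_kernel(vr, ctx.mesh))
        rows.append(
            {
                "replicate": replicate,
                "species": ctx.species,
                "site_elevation_m": ctx.site,
                "background": ctx.background,
                "lambda": est.lambda_,
                "ln_lambda": est.ln_lambda,
            }
        )
    return rows


def run_bootstrap(
    demog: DemographyModel,
    records: pd.DataFrame,
    contexts: list[tuple[str, float, str | None]],
    B: int = 500,
    seed: int = 0,
    origins: dict[str, str] | None = None,
    n_bins: int = 100,
    include_point_estimate: bool = True,
) -> BootstrapEnsemble:
    """Run the full parametric bootstrap over a set of kernel contexts.

    Each replicate draws one coefficient vector per species x size-dependent
    vital rate (shared across that species' kernels), rebuilds every kernel
    and recomputes every lambda; when ``origins`` is given, the pairwise
    coexistence table is computed per replicate as well.  Meshes are built
    once per species from its observed sizes.  Deterministic given ``seed``.
    Replicate-level numerical failures are dropped and counted.
    """
    meshes: dict[str, Mesh] = {}
    for species in {c[0] for c in contexts}:
        sub = records[records["species"] == species]
        sizes = np.concatenate(
            [sub["size_t"].to_numpy(dtype=float), sub["size_t1"].to_numpy(dtype=float)]
        )
        meshes[species] = make_mesh(sizes, n_bins=n_bins)
    kernel_contexts = [
        _KernelContext(demog, sp, site, bg, meshes[sp]) for sp, site, bg in contexts
    ]

    lam_rows: list[dict] = []
    failed: list[int] = []
    if include_point_estimate:
        lam_rows += _replicate_lambdas(kernel_contexts, None, replicate=0)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B)
    species_list = sorted({c[0] for c in contexts})
    for b in range(1, B + 1):
        rng = np.random.default_rng(children[b - 1])
        try:
            overrides = {
                sp: {
                    resp: draw_parameters(demog.fits[sp][resp], rng)
                    for resp in SIZE_DEPENDENT
                }
                for sp in species_list
            }
            lam_rows += _replicate_lambdas(kernel_contexts, overrides, replicate=b)
        except (ValueError, np.linalg.LinAlgError):
            failed.append(b)

    lambdas = pd.DataFrame(lam_rows)
    pairs = None
    if origins is not None and not lambdas.empty:
        reps = lambdas[lambdas["replicate"] > 0] if B > 0 else lambdas
        if not reps.empty:
            pairs = pair_table(reps, origins)
    return BootstrapEnsemble(
        B=B,
        seed=seed,
        lambdas=lambdas,
        pairs=pairs,
        n_failed=len(failed),
        failed_replicates=failed,
    )
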