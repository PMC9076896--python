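"""Synthetic transplant-experiment demographic data with known truth.

Emulates a reciprocal-transplant competition experiment along an elevation
gradient: focal plants of lowland- and highland-origin species are grown at
three sites (890, 1400 and 1900 m a.s.l.), either without neighbours or
inside an established background monoculture, and followed over annual
censuses.  Each species carries true size-dependent vital-rate surfaces
(survival, growth, flowering, fecundity as functions of log biomass ``z``,
site elevation and background competitor) plus size-independent germination,
establishment and recruit-size parameters, so every downstream estimate has
a ground-truth oracle.

Scenarios
---------
``neutral``
    All elevation slopes are exactly zero: true lambda is identical at every
    site, for every species and background.
``range_limited``
    Lowland vital rates decline with elevation and highland rates decline
    towards low elevation, so intrinsic and invasion growth rates fall
    beyond each group's range edge.
``facilitation_mix``
    As neutral, but a fraction of interspecific background effects are
    positive (facilitative), exercising the negative-sensitivity paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ipm import Mesh, build_kernel, lambda_of
from .vital_rates import VitalRateSet

__all__ = [
    "SpeciesSpec",
    "ExperimentDesign",
    "SyntheticDataset",
    "generate_species_pool",
    "default_pair_list",
    "simulate_individuals",
    "true_vital_rate_set",
    "true_lambda",
    "write_dataset",
    "SCENARIOS",
    "ELEV_CENTER",
    "ELEV_SCALE",
]

SCENARIOS = ("neutral", "range_limited", "facilitation_mix")

#: elevation covariate used inside true linear predictors: (E - 1400) / 500
ELEV_CENTER = 1400.0
ELEV_SCALE = 500.0

_RATES = ("survival", "growth", "flowering", "fecundity")


def _elev_x(elevation_m: float) -> float:
    return (float(elevation_m) - ELEV_CENTER) / ELEV_SCALE


@dataclass
class SpeciesSpec:
    """True vital-rate parameter surfaces for one species.

    Linear predictors are ``b0 + bz * z + be * x + comp``, with ``x`` the
    scaled elevation and ``comp`` the additive effect of the background
    competitor (zero without neighbours).  Survival and flowering use a
    logit link, fecundity a log link (expected seeds of a flowering plant),
    growth is the Gaussian mean of next year's size.
    """

    species_id: str
    origin: str  # 'lowland' | 'highland'
    surv: tuple[float, float, float]
    grow: tuple[float, float, float]
    grow_sd: float
    flow: tuple[float, float, float]
    fec: tuple[float, float, float]
    germination: float
    establishment: float
    recruit_mean: float
    recruit_sd: float
    # background species id -> per-rate additive effects on the linear predictor
    comp: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.origin not in ("lowland", "highland"):
            raise ValueError(f"origin must be lowland/highland, got {self.origin!r}")
        if not (self.grow_sd > 0 and self.recruit_sd > 0):
            raise ValueError("grow_sd and recruit_sd must be > 0")
        ge = self.germination * self.establishment
        if not (0.0 < ge < 1.0):
            raise ValueError("germination x establishment must lie in (0, 1)")

    def _comp(self, rate: str, background: str | None) -> float:
        if background is None:
            return 0.0
        try:
            return self.comp[background][rate]
        except KeyError:
            raise KeyError(
                f"{self.species_id}: no competition effect for background {background!r}"
            ) from None

    def _linpred(self, rate: str, z, elevation_m: float, background: str | None):
        b0, bz, be = getattr(self, {"survival": "surv", "growth": "grow",
                                    "flowering": "flow", "fecundity": "fec"}[rate])
        z = np.asarray(z, dtype=float)
        return b0 + bz * z + be * _elev_x(elevation_m) + self._comp(rate, background)

    def survival_prob(self, z, elevation_m, background=None):
        eta = self._linpred("survival", z, elevation_m, background)
        return 1.0 / (1.0 + np.exp(-eta))

    def growth_mean(self, z, elevation_m, background=None):
        return self._linpred("growth", z, elevation_m, background)

    def flowering_prob(self, z, elevation_m, background=None):
        eta = self._linpred("flowering", z, elevation_m, background)
        return 1.0 / (1.0 + np.exp(-eta))

    def seed_mean(self, z, elevation_m, background=None):
        return np.exp(self._linpred("fecundity", z, elevation_m, background))


@dataclass
class ExperimentDesign:
    """Layout of the transplant experiment.

    ``pair_list`` holds (focal, background) treatments with background
    ``None`` for the no-competition plots; the default covers every focal
    alone, every intraspecific monoculture and all ordered interspecific
    pairs.  ``n_individuals_per_treatment`` defaults to the field design's
    nine focals per species, competitor and site.
    """

    site_elevations: tuple[float, ...] = (890.0, 1400.0, 1900.0)
    n_individuals_per_treatment: int = 9
    n_transitions: int = 3
    pair_list: list[tuple[str, str | None]] | None = None
    rng_seed: int = 0
    n_sown: int = 1000
    drop_backgrounds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        elevs = tuple(float(e) for e in self.site_elevations)
        if any(b <= a for a, b in zip(elevs, elevs[1:])):
            raise ValueError("site elevations must be strictly increasing")
        self.site_elevations = elevs
        if self.n_individuals_per_treatment < 1 or self.n_transitions < 1:
            raise ValueError("n_individuals_per_treatment and n_transitions must be >= 1")


def default_pair_list(pool: list[SpeciesSpec]) -> list[tuple[str, str | None]]:
    ids = [s.species_id for s in pool]
    pairs: list[tuple[str, str | None]] = [(f, None) for f in ids]
    pairs += [(f, f) for f in ids]
    pairs += [(f, b) for f in ids for b in ids if f != b]
    return pairs


@dataclass
class SyntheticDataset:
    """Simulated records plus the generating truth."""

    records: pd.DataFrame
    recruitment_trials: pd.DataFrame
    pool: list[SpeciesSpec]
    design: ExperimentDesign

    def species(self, species_id: str) -> SpeciesSpec:
        for s in self.pool:
            if s.species_id == species_id:
                return s
        raise KeyError(species_id)

    def true_lambda_table(self, n_bins: int = 100) -> pd.DataFrame:
        """True lambda for every treatment x site in the design."""
        pairs = self.design.pair_list or default_pair_list(self.pool)
        rows = []
        for focal, background in pairs:
            spec = self.species(focal)
            for elev in self.design.site_elevations:
                lam = true_lambda(spec, elev, background, n_bins=n_bins)
                rows.append(
                    {
                        "species": focal,
                        "origin": spec.origin,
                        "site_elevation_m": elev,
                        "background": background if background is not None else "none",
                        "lambda": lam,
                        "ln_lambda": np.log(lam) if lam > 0 else -np.inf,
                    }
                )
        return pd.DataFrame(rows)


# --- species-pool generation -------------------------------------------------

# Baseline vital-rate parameters: a short-lived perennial forb/grass on a log
# dry-biomass scale (z roughly -1.5..4 g), annual census.  Interspecific
# neighbours depress survival/growth/fecundity; intraspecific competition is
# somewhat stronger (self-limitation), giving positive niche differences.
_BASE = {
    "surv": (0.9, 0.8),  # logit intercept, size slope
    "grow": (0.9, 0.6),
    "grow_sd": 0.45,
    "flow": (-1.0, 1.0),
    "fec": (2.2, 0.5),  # log expected seeds
    "germination": 0.30,
    "establishment": 0.20,
    "recruit_mean": 0.0,
    "recruit_sd": 0.5,
}

# elevation slopes (per scaled elevation unit) under range_limited; the sign
# is flipped between origins so each group declines beyond its range edge
_ELEV_SLOPES = {"surv": 0.55, "grow": 0.25, "flow": 0.3, "fec": 0.25}

# additive competition effects on linear predictors (interspecific baseline;
# intraspecific effects are scaled up by _INTRA_FACTOR, so niche differences
# are positive and coexistence is common inside each group's range)
_COMP_BASE = {"survival": -0.6, "growth": -0.25, "flowering": -0.35, "fecundity": -0.45}
_INTRA_FACTOR = 1.8
_COMP_JITTER = 0.45  # multiplicative spread across pairs


def generate_species_pool(
    n_lowland: int,
    n_highland: int,
    scenario: str,
    rng_seed: int,
) -> list[SpeciesSpec]:
    """Generate a reproducible species pool for one scenario.

    Lowland species are named ``L1..``, highland ``H1..``.  Per-species
    jitter keeps species distinct; under ``neutral`` all elevation slopes
    are exactly zero; under ``facilitation_mix`` a quarter of interspecific
    background effects are flipped positive.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if n_lowland < 1 or n_highland < 1:
        raise ValueError("need at least one species per origin group")
    rng = np.random.default_rng(rng_seed)
    ids = [f"L{i+1}" for i in range(n_lowland)] + [f"H{i+1}" for i in range(n_highland)]
    origins = ["lowland"] * n_lowland + ["highland"] * n_highland

    specs: list[SpeciesSpec] = []
    for sid, origin in zip(ids, origins):
        sign = 0.0
        if scenario == "range_limited":
            sign = -1.0 if origin == "lowland" else 1.0
        surv_b0 = _BASE["surv"][0] + rng.normal(0, 0.2)
        grow_b0 = _BASE["grow"][0] + rng.normal(0, 0.08)
        flow_b0 = _BASE["flow"][0] + rng.normal(0, 0.2)
        fec_b0 = _BASE["fec"][0] + rng.normal(0, 0.15)
        specs.append(
            SpeciesSpec(
                species_id=sid,
                origin=origin,
                surv=(surv_b0, _BASE["surv"][1], sign * _ELEV_SLOPES["surv"]),
                grow=(grow_b0, _BASE["grow"][1], sign * _ELEV_SLOPES["grow"]),
                grow_sd=_BASE["grow_sd"],
                flow=(flow_b0, _BASE["flow"][1], sign * _ELEV_SLOPES["flow"]),
                fec=(fec_b0, _BASE["fec"][1], sign * _ELEV_SLOPES["fec"]),
                germination=_BASE["germination"],
                establishment=_BASE["establishment"],
                recruit_mean=_BASE["recruit_mean"],
                recruit_sd=_BASE["recruit_sd"],
            )
        )

    # pairwise competition effects, drawn after all ids are known
    for spec in specs:
        for other in ids:
            intra = other == spec.species_id
            scale = _INTRA_FACTOR if intra else 1.0
            mult = scale * np.exp(rng.normal(0, _COMP_JITTER))
            eff = {r: _COMP_BASE[r] * mult for r in _COMP_BASE}
            if scenario == "facilitation_mix" and not intra and rng.random() < 0.25:
                eff = {r: -0.35 * v for r, v in eff.items()}  # mild facilitation
            spec.comp[other] = eff
    return specs


# --- ground-truth IPM --------------------------------------------------------

def true_vital_rate_set(
    spec: SpeciesSpec, elevation_m: float, background: str | None = None
) -> VitalRateSet:
    """Package a species' true parameter surfaces for kernel assembly."""
    return VitalRateSet(
        survival=lambda z: spec.survival_prob(z, elevation_m, background),
        growth_mean=lambda z: spec.growth_mean(z, elevation_m, background),
        growth_sd=spec.grow_sd,
        flowering=lambda z: spec.flowering_prob(z, elevation_m, background),
        fecundity=lambda z: spec.seed_mean(z, elevation_m, background),
        germination=spec.germination,
        establishment=spec.establishment,
        recruit_mean=spec.recruit_mean,
        recruit_sd=spec.recruit_sd,
    )


def true_mesh(spec: SpeciesSpec, elevation_m: float, background: str | None = None,
              n_bins: int = 100) -> Mesh:
    """Size mesh wide enough for the species' stationary size distribution."""
    b0, bz, _ = spec.grow
    eta0 = float(spec.growth_mean(0.0, elevation_m, background))
    if bz < 1.0:
        z_star = eta0 / (1.0 - bz)
        sd_stat = spec.grow_sd / np.sqrt(max(1.0 - bz**2, 1e-6))
    else:
        z_star = eta0
        sd_stat = 4.0 * spec.grow_sd
    lo = min(spec.recruit_mean - 4.0 * spec.recruit_sd, z_star - 4.0 * sd_stat)
    hi = max(spec.recruit_mean + 4.0 * spec.recruit_sd, z_star + 4.0 * sd_stat)
    return Mesh(lo, hi, n_bins)


def true_lambda(
    spec: SpeciesSpec,
    elevation_m: float,
    background: str | None = None,
    n_bins: int = 100,
) -> float:
    """Ground-truth lambda from the true parameter surfaces (no estimation)."""
    vr = true_vital_rate_set(spec, elevation_m, background)
    mesh = true_mesh(spec, elevation_m, background, n_bins=n_bins)
    return lambda_of(build_kernel(vr, mesh)).lambda_


# --- individual-level simulation ---------------------------------------------

def simulate_individuals(pool: list[SpeciesSpec], design: ExperimentDesign) -> SyntheticDataset:
    """Simulate annual demographic records for every treatment.

    Each treatment (focal x background x site) follows ``n`` planting
    positions over ``n_transitions`` annual transitions.  A position's
    occupant dies with probability ``1 - s(z)``; dead occupants are replaced
    at the next census by a fresh transplant (flagged ``is_replacement``)
    whose size is drawn from the recruit-size density, mirroring the
    replanting of dead focals.  Flowering and seed set are recorded at the
    start-of-transition census regardless of subsequent survival.
    """
    by_id = {s.species_id: s for s in pool}
    pairs = design.pair_list if design.pair_list is not None else default_pair_list(pool)
    for focal, background in pairs:
        if focal not in by_id or (background is not None and background not in by_id):
            raise KeyError(f"design references unknown species in pair {(focal, background)}")
    if design.drop_backgrounds:
        pairs = [p for p in pairs if p[1] not in design.drop_backgrounds]

    rng = np.random.default_rng(design.rng_seed)
    rows = []
    counter = 0
    for focal, background in pairs:
        spec = by_id[focal]
        bg_label = background if background is not None else "none"
        for elev in design.site_elevations:
            for slot in range(design.n_individuals_per_treatment):
                counter += 1
                ind_id = f"{focal}_{bg_label}_{int(elev)}_{slot}"
                size = spec.recruit_mean + spec.recruit_sd * rng.standard_normal()
                replacement = 0
                gen = 0
                for year in range(design.n_transitions):
                    s = float(spec.survival_prob(size, elev, background))
                    survived = int(rng.random() < s)
                    if survived:
                        size_t1 = float(
                            spec.growth_mean(size, elev, background)
                            + spec.grow_sd * rng.standard_normal()
                        )
                    else:
                        size_t1 = np.nan
                    p_fl = float(spec.flowering_prob(size, elev, background))
                    flowered = int(rng.random() < p_fl)
                    seeds = (
                        int(rng.poisson(float(spec.seed_mean(size, elev, background))))
                        if flowered
                        else 0
                    )
                    rows.append(
                        (
                            f"{ind_id}_g{gen}",
                            focal,
                            spec.origin,
                            elev,
                            bg_label,
                            year,
                            size,
                            survived,
                            size_t1,
                            flowered,
                            seeds,
                            replacement,
                        )
                    )
                    if survived:
                        size = size_t1
                    else:
                        # replanted next census as a new individual
                        size = spec.recruit_mean + spec.recruit_sd * rng.standard_normal()
                        replacement = 1
                        gen += 1

    records = pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "species",
            "origin",
            "site_elevation_m",
            "background",
            "year",
            "size_t",
            "survived",
            "size_t1",
            "flowered",
            "seeds",
            "is_replacement",
        ],
    )

    trial_rows = []
    for spec in pool:
        for elev in design.site_elevations:
            germ = int(rng.binomial(design.n_sown, spec.germination))
            est = int(rng.binomial(germ, spec.establishment)) if germ > 0 else 0
            trial_rows.append(
                {
                    "species": spec.species_id,
                    "site_elevation_m": elev,
                    "n_sown": design.n_sown,
                    "n_germinated": germ,
                    "n_established": est,
                }
            )
    trials = pd.DataFrame(trial_rows)
    return SyntheticDataset(records=records, recruitment_trials=trials, pool=pool, design=design)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write records, recruitment trials and the true-lambda table as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.csv",
        "recruitment": outdir / "recruitment.csv",
        "true_lambda": outdir / "true_lambda.csv",
    }
    dataset.records.to_csv(paths["records"], index=False)
    dataset.recruitment_trials.to_csv(paths["recruitment"], index=False)
    dataset.true_lambda_table().to_csv(paths["true_lambda"], index=False)
    return paths
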