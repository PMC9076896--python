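"""Pairwise coexistence: sensitivities, niche and fitness differences.

The sensitivity of focal species i to competition from resident j is the
proportional reduction of its log growth rate when invading j's equilibrium
monoculture:

    S_ij = 1 - ln(lambda_ij) / ln(lambda_i)

(lambda_ij the invasion rate, lambda_i the intrinsic rate).  Negative
sensitivities mark facilitation.  For a pair, the niche difference is one
minus the geometric mean of the two sensitivities and the relative fitness
difference their geometric standard deviation:

    ND  = 1 - sqrt(S_ij * S_ji)
    RFD = sqrt(S_ji / S_ij)

Stable coexistence requires mutual invasibility, equivalently
``1 / (RFD * (1 - ND)) > 1`` — this quantity is the coexistence metric,
larger values meaning more strongly stabilized coexistence.  Facilitative
pairs (any non-positive sensitivity) are excluded from ND/RFD/metric but
retained for growth-rate analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoexistencePair",
    "sensitivity",
    "niche_fitness",
    "classify",
    "pair_table",
    "pair_type_of",
    "orient_pair",
]

OUTCOMES = ("stable_coexistence", "competitive_exclusion", "priority_effect")


def sensitivity(ln_lambda_invasion: float, ln_lambda_intrinsic: float) -> tuple[float, set]:
    """Sensitivity to competition with validity flags.

    Returns ``(S, flags)``; ``flags`` may contain ``sensitivity_undefined``
    (intrinsic rate exactly at the boundary ln lambda = 0) or
    ``intrinsic_nonpersistent`` (ln lambda_i < 0, where S keeps its algebraic
    definition but no longer maps onto the invasion criterion).
    """
    flags: set = set()
    if ln_lambda_intrinsic == 0.0 or not np.isfinite(ln_lambda_intrinsic):
        flags.add("sensitivity_undefined")
        return np.nan, flags
    if ln_lambda_intrinsic < 0.0:
        flags.add("intrinsic_nonpersistent")
    return 1.0 - ln_lambda_invasion / ln_lambda_intrinsic, flags


def niche_fitness(S_ij: float, S_ji: float) -> tuple[float, float, float]:
    """Niche difference, relative fitness difference, coexistence metric.

    Requires both sensitivities strictly positive; facilitative pairs must
    be filtered out by the caller (see :func:`pair_table`).  ``RFD`` follows
    the pair's ordering convention (it may be < 1); the metric uses the
    >=1-oriented fitness difference so that it is invariant to exchanging
    the two species, which makes ``metric = 1/max(S_ij, S_ji)`` exactly.
    """
    if not (S_ij > 0 and S_ji > 0):
        raise ValueError("niche/fitness differences require positive sensitivities")
    nd = 1.0 - np.sqrt(S_ij * S_ji)
    rfd = np.sqrt(S_ji / S_ij)
    metric = 1.0 / (max(rfd, 1.0 / rfd) * (1.0 - nd))
    return float(nd), float(rfd), float(metric)


def classify(
    S_ij: float,
    S_ji: float,
    ln_intrinsic_i: float | None = None,
    ln_intrinsic_j: float | None = None,
    ln_invasion_i: float | None = None,
    ln_invasion_j: float | None = None,
) -> str:
    """Competitive outcome from the mutual-invasibility criteria.

    Species i invades j's monoculture iff S_ij < 1 (equivalently
    ln lambda_ij > 0 when ln lambda_i > 0).  Both invade: stable
    coexistence; neither: priority effect; exactly one: competitive
    exclusion by the invader.  When an intrinsic rate is negative the
    S < 1 mapping breaks down, so invasion is then read directly off the
    sign of ln lambda_invasion if provided.
    """

    def invades(S, ln_int, ln_inv) -> bool:
        if ln_int is not None and ln_int < 0 and ln_inv is not None:
            return ln_inv > 0
        return S < 1.0

    i_inv = invades(S_ij, ln_intrinsic_i, ln_invasion_i)
    j_inv = invades(S_ji, ln_intrinsic_j, ln_invasion_j)
    if i_inv and j_inv:
        return "stable_coexistence"
    if not i_inv and not j_inv:
        return "priority_effect"
    return "competitive_exclusion"


def pair_type_of(origin_i: str, origin_j: str) -> str:
    if origin_i == origin_j:
        return "lowland-lowland" if origin_i == "lowland" else "highland-highland"
    return "lowland-highland"


def orient_pair(a: str, b: str, origins: dict[str, str]) -> tuple[str, str]:
    """Ordering convention: for mixed pairs i = highland, j = lowland, so
    ln(RFD) < 0 means the lowland species is competitively dominant; for
    sympatric pairs the order is lexicographic."""
    oa, ob = origins[a], origins[b]
    if oa != ob:
        return (a, b) if oa == "highland" else (b, a)
    return (a, b) if a <= b else (b, a)


@dataclass
class CoexistencePair:
    """Coexistence quantities for one ordered pair at one site."""

    species_i: str
    species_j: str
    pair_type: str
    site_elevation_m: float
    S_ij: float
    S_ji: float
    ND: float = np.nan
    niche_overlap: float = np.nan
    RFD: float = np.nan
    ln_RFD: float = np.nan
    metric: float = np.nan
    outcome: str | None = None
    replicate_id: int | None = None
    flags: set = field(default_factory=set)


def _lambda_lookup(df: pd.DataFrame) -> dict[tuple, float]:
    key = zip(df["species"], df["site_elevation_m"], df["background"])
    return dict(zip(key, df["ln_lambda"]))


def pair_table(
    lambdas: pd.DataFrame,
    origins: dict[str, str],
    pairs: list[tuple[str, str]] | None = None,
    replicate_id: int | None = None,
) -> pd.DataFrame:
    """All pairwise coexistence quantities from a table of growth rates.

    ``lambdas`` needs columns species / site_elevation_m / background /
    ln_lambda, with background 'none' rows holding intrinsic rates.  If a
    ``replicate`` column is present the table is computed per replicate.
    Pairs with a facilitative direction keep their outcome classification
    but carry no ND/RFD/metric; pairs with a non-persistent intrinsic rate
    keep ND/RFD (sensitivities are defined regardless) and are flagged.
    """
    if "replicate" in lambdas.columns:
        frames = [
            pair_table(sub.drop(columns="replicate"), origins, pairs, replicate_id=int(rep))
            for rep, sub in lambdas.groupby("replicate", sort=True)
        ]
        return pd.concat(frames, ignore_index=True)

    lut = _lambda_lookup(lambdas)
    sites = sorted(lambdas["site_elevation_m"].unique())
    species = sorted({s for s in lambdas["species"].unique() if s in origins})
    if pairs is None:
        pairs = list(itertools.combinations(species, 2))

    rows = []
    for a, b in pairs:
        i, j = orient_pair(a, b, origins)
        ptype = pair_type_of(origins[i], origins[j])
        for site in sites:
            try:
                ln_i = lut[(i, site, "none")]
                ln_j = lut[(j, site, "none")]
                ln_ij = lut[(i, site, j)]
                ln_ji = lut[(j, site, i)]
            except KeyError:
                continue  # missing context: pair not measured at this site
            S_ij, fl_i = sensitivity(ln_ij, ln_i)
            S_ji, fl_j = sensitivity(ln_ji, ln_j)
            flags = fl_i | fl_j
            pair = CoexistencePair(
                species_i=i,
                species_j=j,
                pair_type=ptype,
                site_elevation_m=site,
                S_ij=S_ij,
                S_ji=S_ji,
                replicate_id=replicate_id,
                flags=flags,
            )
            if "sensitivity_undefined" not in flags:
                pair.outcome = classify(S_ij, S_ji, ln_i, ln_j, ln_ij, ln_ji)
                if S_ij > 0 and S_ji > 0:
                    nd, rfd, metric = niche_fitness(S_ij, S_ji)
                    pair.ND = nd
                    pair.niche_overlap = 1.0 - nd
                    pair.RFD = rfd
                    pair.ln_RFD = float(np.log(rfd))
                    pair.metric = metric
                else:
                    pair.flags.add("facilitative_excluded")
            rows.append(
                {
                    "species_i": pair.species_i,
                    "species_j": pair.species_j,
                    "pair": f"{pair.species_i}:{pair.species_j}",
                    "pair_type": pair.pair_type,
                    "site_elevation_m": pair.site_elevation_m,
                    "replicate": replicate_id,
                    "S_ij": pair.S_ij,
                    "S_ji": pair.S_ji,
                    "ND": pair.ND,
                    "niche_overlap": pair.niche_overlap,
                    "RFD": pair.RFD,
                    "ln_RFD": pair.ln_RFD,
                    "metric": pair.metric,
                    "outcome": pair.outcome,
                    "flags": ";".join(sorted(pair.flags)),
                }
            )
    return pd.DataFrame(rows)
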