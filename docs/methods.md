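# Methods

## The demographic model

One annual census-to-census transition of an individual plant of log dry
aboveground biomass `z` is governed by six vital rates: survival `s(z)`,
growth `G(z'|z)` (Gaussian with fitted mean `mu_G(z)` and residual SD
`sigma_G`), flowering probability `p_fl(z)`, expected seed production of a
flowering plant `f(z)`, size-independent germination `g` and establishment
`e`, and the recruit-size density `phi(z')` (Gaussian, `mu_R`, `sigma_R`).
The census is pre-reproductive: seeds produced at `t` appear as established
seedlings at `t+1` with probability `g·e`, so the projection kernel is
`K(z',z) = s(z) G(z'|z) + p_fl(z) f(z) g e phi(z')` and the population
growth rate `lambda` is its dominant eigenvalue. Intrinsic rates come from
kernels fitted to plants without neighbours; invasion rates from plants
inside a resident monoculture, under the assumptions that the monoculture
is at equilibrium and focal individuals interact only with the background
species. `check_equilibrium` audits the first assumption by classifying the
resident-on-resident kernel's `|ln lambda|` against a tolerance (default
0.05, configurable — the cutoff is a reporting convention, not an estimate).

## Discretization

Kernels are discretized on a uniform mesh of 100 midpoints spanning the
observed size range extended by 10% on each side (both configurable).
Eviction — density mass falling off the mesh — is corrected by
renormalizing each growth column and the recruit density to unit mass, so
the survival-growth column mass equals `s(z)` exactly. The alternative
(mesh expansion) was rejected for simplicity; the mesh-refinement test
(lambda changes < 0.1% from 100 to 400 bins on smooth rates) validates the
choice. The spectral radius and stable size distribution come from a dense
eigendecomposition; an independent power-iteration oracle guards it in the
tests.

## Vital-rate estimation

Size-dependent rates are fitted per species by maximum likelihood with
statsmodels (binomial GLM for survival and flowering; ordinary least
squares for growth and for log(seeds+1) of flowering individuals, the
latter back-transformed with a plain `exp(eta)-1`, no smearing correction).
Transitions are pooled across years; site enters as a 3-level factor and
background competitor (including "none") as a factor. The default full
model is `z + site + background + z:site + z:background`; all
hierarchy-valid submodels (including intercept-only) are fitted and the
smallest-AICc model kept, ties going to fewer parameters. This borrows
strength across sites and competitors when the data cannot support the full
structure. Degenerate binomial responses (all 0/1) collapse to a clipped
intercept-only fit with zero variance; separation and non-convergence are
flagged and excluded from selection. `g` and `e` are raw proportions
(germinated/sown, established/germinated), size-independent by assumption;
the recruit-size density is fitted to each individual's first recorded
size, which in the generator equals the recruit distribution (transplanted
seedlings and replacements enter at recruit size). Probability predictions
are clipped to (1e-12, 1-1e-12). Replacement individuals are included in
all fits by default (`include_replacements=False` drops them from survival
only).

## Parametric bootstrap

Coefficient vectors of the four size-dependent rates are resampled from
multivariate normals with the fitted means and covariance matrices, one
coherent draw per species x rate per replicate, shared across every kernel
that uses the model. Size-independent quantities (`g`, `e`, `sigma_G`,
recruit density) are held fixed. Default 500 replicates; summaries are
medians with percentile 2.5/97.5 intervals. Non-PSD covariance matrices
are repaired by clipping negative eigenvalues at zero (with a warning).
Model selection runs once, before resampling. A consequence of resampling
only the size-dependent rates is that bootstrap CIs quantify the propagated
(regression-parameter) uncertainty, not the total sampling uncertainty of
`ln lambda`: variance decomposition on synthetic data shows the fixed
components contribute a comparable share. The CI-calibration experiment in
the tests therefore supplies the estimator with the true size-independent
components and checks coverage of the propagated part (observed ~91-95% at
nominal 95%).

## Coexistence quantities

`S_ij = 1 - ln(lambda_ij)/ln(lambda_i)`; `ND = 1 - sqrt(S_ij S_ji)`;
`RFD = sqrt(S_ji/S_ij)` under the ordering convention i = highland,
j = lowland for mixed-origin pairs (so `ln RFD < 0` means lowland
dominance) and lexicographic order for sympatric pairs. The coexistence
metric `1/(RFD(1-ND))` uses the >=1-oriented fitness difference, making it
exchange-invariant and identically `1/max(S_ij, S_ji)`. Outcomes are
classified from the invasion criteria (both `S < 1`: stable coexistence;
neither: priority effect; one: exclusion by the invader), which the tests
prove equivalent to the oriented ND/RFD inequality rules away from the
`S = 1` boundary. Pairs with a facilitative direction (`S <= 0`) are
excluded from ND/RFD/metric but still classified and kept in growth-rate
analyses; pairs whose intrinsic `ln lambda < 0` keep ND/RFD (sensitivities
are defined regardless) with a flag, and their invasion status is read
directly off the sign of `ln lambda_invasion` since `S < 1` no longer maps
onto invasion.

## Trend inference

Responses (`ln lambda`, log coexistence metric, log niche overlap
`= 1 - ND` — used instead of ND because ND can be negative — log |RFD|
pooled/sympatric, signed `ln RFD` for mixed pairs) are modelled with
elevation (continuous, metres) crossed with origin or pair type as fixed
effects and species or pair as a random intercept, fitted by ML
(statsmodels MixedLM). Fixed terms are tested by likelihood-ratio chi-square
against the model without the term (interaction vs both mains); singular
mixed fits fall back to fixed-effects OLS with a flag. The primary analysis
fits bootstrap means per context; uncertainty propagation refits the model
per replicate (fixed-effects by default — within one replicate each context
contributes one observation, so the random intercept is weakly identified,
and the replicate spread itself carries the propagated uncertainty) and
judges a coefficient significant when its 95% percentile interval excludes
zero. Outcome tallies count coexisting vs non-coexisting pairs per
replicate and report means with percentile CIs. No multiple-testing
correction is applied across responses.

## Synthetic data generator

The generator emulates the transplant design: 14 species (7 lowland, 7
highland) by default, three sites at 890/1400/1900 m, no-competition plots
and background monocultures, 9 individuals per focal x competitor x site,
three annual transitions, dead focals replaced at the next census and
flagged. True vital rates are linear predictors in `z` and scaled elevation
`x = (E-1400)/500` with additive background effects; baseline parameters
describe a short-lived perennial on a log-biomass scale (survival logit
`0.9 + 0.8 z`, growth `0.9 + 0.6 z` with SD 0.45, flowering logit
`-1 + z`, log seeds `2.2 + 0.5 z`, `g = 0.3`, `e = 0.2`, recruits
`N(0, 0.5^2)`), jittered per species. Interspecific competition depresses
the linear predictors (survival -0.6, growth -0.25, flowering -0.35,
fecundity -0.45, log-normally jittered across pairs); intraspecific effects
are 1.8x stronger, giving positive niche differences and ~1-2% yr^-1-scale
dynamics with `ln lambda_intrinsic` roughly 0 to 0.7. Scenarios: `neutral`
(elevation slopes exactly zero — no true elevation signal anywhere),
`range_limited` (each origin's rates decline beyond its range edge:
survival slope 0.55, growth 0.25, flowering 0.30, fecundity 0.25 per
elevation unit, sign by origin), and `facilitation_mix` (a quarter of
interspecific effects flipped mildly positive). Recruitment trials sow 1000
seeds per species x site, matching the high-density sowing of the emulated
protocol; this keeps `g`,`e` noise subordinate to the demographic
estimation the recovery experiments measure.

What the generator does not emulate: within-season mortality, spatial
arrangement, year effects (true rates are time-constant, matching the
pooled-years estimation), allometric size estimation (sizes are log
biomass directly), seed banks, and any special biennial life cycle.
Passing tests therefore show the estimation pipeline recovers a world that
satisfies the model's assumptions; they do not certify robustness to
assumption violations in field data.

## Problem sizes in the validation suite

The validation experiments run at desk scale: lambda recovery uses 500
individuals per treatment over 20 seeds (median |ln lambda error| < 0.05);
AICc selection consistency 50 runs at n = 3000; bootstrap coverage 200
simulations at B = 100 with 60 individuals; trend-test calibration 200
null and 100 alternative simulated response tables (42 rows each, the
14-species x 3-site layout); the qualitative elevation-pattern check a
3+3-species community at 30 individuals per treatment. The acceptance
script uses the same community with B = 100 bootstrap replicates and 8
recovery seeds.

## Known limitations

- Fecundity is fitted on log(seeds+1) and back-transformed without
  smearing; under Poisson-like seed counts this biases `f(z)` slightly
  downward (visible as a ~0.02 downward tilt in `ln lambda` recovery at
  small n).
- Bootstrap CIs exclude size-independent-parameter uncertainty (see above).
- The equilibrium tolerance and the per-replicate fixed-effects choice are
  conventions; both are configurable.
- Facilitative pairs are wholly excluded from ND/RFD whenever either
  direction is non-positive.
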