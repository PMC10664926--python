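# Methods

This note records the statistical models implemented in `incidentalg`,
the conventions and numerical choices behind them, what the synthetic
generators do and do not emulate, and known limitations.

## The estimand

For a monitoring period and stratum ("class" — here a site-season), the
overall probability that a carcass arriving in the period is available
and incidentally detected factorises approximately as

    g ≈ p · r · a

- `p` — detection probability per search opportunity, estimated from
  decoy trials as found/available;
- `r` — mean probability of persisting from a uniformly distributed
  arrival time to the end-of-interval detection opportunity;
- `a` — density-weighted area adjustment: the expected fraction of
  carcasses falling where detection is possible, times the fraction of
  turbines visited.

Classes combine by weighted average (`ḡ = Σ wᵢ gᵢ`, uniform 0.25 per
season when temporal collision risk is treated as uniform); multi-year
averages follow the same rule with effort weights. A season with
suspended effort (winter access shutdown, mature crops) contributes
`g = 0` at full weight.

### Conventions

- **Seasons** are site-specific date ranges, closed at both ends; winter
  may wrap the calendar-year boundary and is split into two sub-ranges
  internally. Feb 29 is collapsed onto Feb 28 so common-year calendars
  tile leap years.
- **Density quartiles** bin fall distance at inclusive upper bounds
  33 / 45 / 61 m (near / near-mid / far-mid / far); distances are
  continuous, so 33.0 m is "near" and 33.001 m is "near-mid".
- **Availability**: a decoy is excluded only if it was neither found nor
  recoverable after the trial month; decoys recovered late count as
  available-and-not-found.
- **Rounding** is presentation-only: estimates are carried at full
  precision and rounded half-up to 2 decimals in reports.

## Detection GLMM

Per-decoy detection is Bernoulli on the logit scale with fixed effects
from {season, viewshed class, density quartile} plus two-way
interactions, and a site random intercept `b ~ N(0, σ²)` — the only
random term, which keeps the marginal likelihood a product of
one-dimensional integrals over sites. Each integral is evaluated by
**adaptive Gauss–Hermite quadrature** (default 15 nodes): the integrand
is re-centred at its mode (found by per-site Newton iteration) and
scaled by the curvature there; Laplace is the 1-node special case. The
fit maximises this marginal likelihood over (β, log σ) with L-BFGS-B,
started from a ridge-stabilised IRLS logistic fit, with up to three
random restarts. A weak ridge (10⁻⁴ on β) keeps estimates finite under
complete separation — strata with all-found or none-found outcomes do
occur in realistic data. A boundary fit is reported as σ = 0, not an
error. The implementation agrees with an independent reference mixed-
model fitter (nAGQ = 15) to ~10⁻³ on shared test problems, and with a
plain IRLS fit when σ is pinned at 0.

**Coding.** Main effects use treatment coding against the first
domain-ordered level (spring, low, near); interactions enter as full
cell products, with linearly dependent columns dropped greedily. A model
containing season×viewshed therefore spans both main effects, and the
64 possible term subsets collapse to **18 distinct column spaces**,
which is the candidate set ranked by AICc
(`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`, k counting fixed effects,
intercept and the variance). Best-supported models are those within 2
AICc of the minimum.

**Prediction intervals** are parametric bootstrap: coefficient draws
from the asymptotic normal (observed information of the marginal
likelihood, by central finite differences), plus a fresh random
intercept per draw when predicting for an unseen site; percentile
intervals, deterministic given the seed.

## Persistence

Removal times are interval-censored by the check schedule: the
likelihood contribution of an observed removal is
`S(last_present) − S(first_absent)`, right-censored records contribute
`S(last_present)`. Four location-scale families are supported
(exponential, Weibull, log-logistic, log-normal — the field-standard
quartet, an assumption since trial protocols vary), fitted by maximum
likelihood (via lifelines' interval-censoring fitters) and compared by
AICc. Then

    r(I) = (1/I) ∫₀ᴵ S(u) du

(uniform arrival in the interval preceding a search, persistence
required to the search at its end), evaluated by adaptive quadrature at
absolute tolerance 10⁻⁸, or in closed form for the exponential family
(`r = (1 − e^{−I/λ})·λ/I`, the oracle used in tests). Medians invert S
numerically to 10⁻⁶ days. Seasonal persistence is handled by stratified
fits, not shared-parameter regression.

## Area adjustment

The carcass fall-distance density is a **truncated gamma** on [0, 100 m]
calibrated by least squares so its quartiles match 33 / 45 / 61 m; the
calibrated model has its mode near 40 m and reproduces every property
the bin definitions imply. (A truncated Weibull is available as an
alternative family.) On a per-turbine grid of viewshed classes (default
1-m cells, membership by cell centre), each cell gets carcass mass
`f(r)/(2πr) × cell area`; the centre cell uses the equal-area-disc mass
to avoid the 1/r singularity. The density-weighted proportion (DWP) is
the viewable share of that mass — it exceeds the unweighted viewable
proportion whenever blocked area is concentrated far from the turbine,
where carcass density is low. Site-level
`a = mean(DWP over searched turbines) × n_searched/n_total`; unsearched
turbines are assumed similar to searched ones and enter only through the
count. DWP agrees with a 10⁵-draw Monte Carlo of carcass positions
within 3 SE plus a ~0.5% cell-discretisation allowance.

## Uncertainty in g

The published uncertainty machinery for g is not specified at the level
of a recipe, so this package uses a transparent parametric Monte Carlo
whose coverage is testable:

- `p` — Jeffreys posterior Beta(found + ½, available − found + ½);
- persistence — parameter draws from the fit's asymptotic normal, taken
  on the log scale for positive parameters, each mapped to an r draw;
- `a` — held fixed (it is a deterministic function of mapped inputs).

Per-class g draws are `p·r·a` products (with a point multi-search uplift
factor when more than one opportunity per interval is configured —
exact at J = 1, the default). Classes sharing one persistence fit share
its estimation error, so **one r-draw vector is drawn per fit and reused
across those classes**; drawing r independently per class would average
the common error away and visibly under-cover the combined interval.
Combined intervals are percentiles of the weighted draw mixture; a
moment-matched Beta summarises the combined g for downstream use.

Measured calibration: at study-representative conditions (four seasons
of ~40 trials with detection 0.3–0.6, a 50-carcass persistence trial),
the 90% combined interval covers the true g in ~90% of replicates. At
seasonal detection probabilities near 0.8 with the same n, coverage
drops to ~85%: equal-tailed binomial intervals under-cover near the
short tail at small n (discreteness), a known limitation rather than an
implementation artifact.

## Rare-event mortality bound

Observed count x relates to total mortality M by x | M ~ Binomial(M, g).
The prior on M is the marginal of M | λ ~ Poisson(λ) under the Jeffreys
rate prior π(λ) ∝ λ^{−1/2}:

    π(m) = Γ(m + ½)/m!,    posterior  p(m|x) ∝ C(m,x) gˣ(1−g)^{m−x} π(m).

All mass functions are computed in log space (log-gamma arithmetic; no
overflow for m up to 10⁷), truncated adaptively until the geometric tail
bound is below 10⁻⁸. `M*` is the smallest m whose cumulative posterior
reaches 1 − α (ties resolved by "smallest m", i.e. ≥). The
beta-binomial variant mixes the binomial over g ~ Beta(α_g, β_g); its
posterior tail decays like m^{−(α_g+½)}, so α_g > ½ is required for
propriety.

**Fixed g versus estimated g.** Against the published 5 × 5 reference
grid of M* at α = 0.50, the fixed-g posterior reproduces 21 of 25 cells
exactly; at g = 0.10 with x ≥ 1 it returns a bound one lower, with the
posterior CDF within 0.003 of the 0.5 threshold at the published value.
Those four cells are reproduced exactly by the beta-binomial variant
whenever g carries the estimate uncertainty of a realistic trial
programme (effective sample sizes from a few hundred up; the unit tests
pin both behaviours). In practice g is always an estimate, so the
beta-binomial route is the recommended one for reporting; the fixed-g
route is retained as the transparent limiting case.

Monotonicity holds throughout: M* is non-increasing in g and in the
credibility parameter α, and non-decreasing in x.

## Synthetic data

The generators emulate the *monitoring process*, not eagle biology:
placement counts uniform on 11–16 per site-month, uniform bearings,
fall distances from the calibrated truncated gamma, viewshed classes
from a site mixture, Bernoulli detection on the logit scale, a
configurable unavailability rate (default 7.8%), interval-censored
persistence from a chosen family, and patch-structured viewshed grids
with optional occlusion wedges. Default effect sizes (logit intercept
−2.94, density-quartile effects −0.52/−1.02/−1.36, season×viewshed cell
effects of 1.8–4.4 with the spring-high cell as reference, site SD
0.89) mirror reported field-trial magnitudes; they are presets, not
ground truth. Each generator draws from an independent child stream of
the master seed, so adding a pipeline stage never perturbs another
stage's draws, and equal seeds give byte-identical outputs.

What passing tests on these data do **not** show: real O&M behaviour
(search images, fatigue, reporting gaps), decoy-versus-carcass
detectability differences, partial carcasses and feather spots, snow
burial dynamics, or spatial correlation between viewshed class and
fall distance. Parameter-recovery results demonstrate internal
consistency of the estimation chain, not field validity.

## Problem sizes and defaults

| quantity | default | rationale |
|---|---|---|
| search interval I | 30 d | typical monthly turbine-visitation schedule |
| detection decay k | 0.67 | the single published estimate |
| opportunities per interval J | 1 | conservative: at least one visit assumed |
| seasonal weights | 0.25 each | uniform temporal risk |
| credibility α | 0.50 | standard reporting level for M* |
| quadrature nodes | 15 | marginal log-likelihood stable to <10⁻⁶ vs 21 |
| ridge on β | 10⁻⁴ | finite estimates under separation; deviance shift <10⁻⁶ |
| Monte Carlo draws | 2000 | interval endpoints stable to ~0.01 |
| grid resolution | 1 m | DWP within ~0.5% of continuum |

Recovery simulations in the test suite use 100 replicates at roughly
study scale (six sites × 12 months ≈ 1000 trials for the GLMM; 50
carcasses for persistence; four seasons of ~40 trials end to end),
which keeps the full suite within a routine CI run while leaving Monte
Carlo error well below the tested margins.

## Known limitations

- The GLMM covariance comes from a finite-difference observed
  information; for near-boundary σ it is regularised by eigenvalue
  clipping and should be read as approximate.
- Equal-tailed binomial/Jeffreys intervals under-cover at small n with
  extreme p (discreteness), which propagates into combined g intervals.
- `effective_detection` with J > 1 treats k as exact and scales
  uncertainty by a point uplift factor (first-order).
- Viewshed classes are inputs; no line-of-sight computation from
  elevation models is attempted, and the 100-m disc is a hard boundary
  (roadside visibility beyond it is ignored).
- Persistence families are fitted independently per stratum; no shared
  covariate regression across seasons or sites.
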