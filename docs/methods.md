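# Methods

## Case classification and filtering

Cases are female breast cancer records with a SEER-parallel summary stage
code. Stages 0–1 are classified early, 2–7 late; unknown stage (empty,
"U", NaN) is excluded with a tally. Six demographic subgroups cross race
{black, non-black} with age bands [0, 50), [50, 70), [70, ∞). The age-70
boundary is assigned to the oldest band so that the band definitions are
consistent with the regression's reference category (age ≥ 70); the two
younger bands enter the model as dummies. Race labels are mapped
case-insensitively against a configurable set of "black" labels; anything
else is non-black.

## Distances

All coordinates are planar meters (a projected CRS); the package performs
no geographic-coordinate math. Travel distance is shortest road-network
distance to the nearest mammography facility: origins and facilities are
snapped to their single nearest network node by a straight-line leg, and
the reported distance is snap leg + shortest path + snap leg, minimised
over facilities (one multi-source Dijkstra from facility pseudo-nodes
serves all origins). An origin exactly coincident with a facility has
distance zero. Zone origins are population-weighted centroids of member
blocks (weights: total female population); block origins are geometric
centroids. A straight-line fallback for network-free or disconnected
inputs is opt-in and always flagged `method=euclidean` in the output.
Summaries (min/max/mean/median) are reported in kilometers; the median of
an even-count sample is the midpoint of the central pair.

## Monte Carlo disaggregation

Within one replicate, cases are processed sequentially in input order.
For a case in zone z and subgroup g, current block counts of g in z are
normalised to cumulative shares on [0, 1) (half-open intervals, zero-count
blocks get empty intervals); a uniform draw selects the containing
interval. The receiving block's count of g is then decremented by one and
the shares are rebuilt before the next draw — true sampling without
replacement, whose per-replicate occupancy law is multivariate
hypergeometric (the test suite checks this against exact enumeration and
`scipy.stats.multivariate_hypergeom`). Exhausted blocks drop out
automatically via empty intervals.

Degenerate inputs: a (zone, subgroup) with more cases than residents
raises a capacity error before any replicate runs (an opt-in
with-replacement override exists and is flagged in the run metadata); a
(zone, subgroup) with zero census population falls back, with a logged and
recorded warning, to assignment proportional to the zone's total female
population (no decrement), configurable to a hard error.

Randomness: one master seed feeds `numpy.random.SeedSequence.spawn`, one
child stream per replicate, making the full n × R assignment matrix
bit-reproducible from (master seed, R) and replicates mutually
independent.

## The two-level model

logit P(y_ij = 1) = γ₀₀ + β₁·AGE<50 + β₂·AGE50–70 + β₃·BLACK + γ₀₁·d_j + U₀j,
with U₀j ~ N(0, τ²) per spatial unit and the level-1 residual fixed at the
standard logistic latent-scale variance π²/3 (not estimated). Reference
categories: non-black, age ≥ 70. Distance enters untransformed in meters,
so γ₀₁ is O(10⁻⁵) on realistic geographies.

Estimation maximises the marginal likelihood with the random intercept
integrated out by Gauss–Hermite quadrature (default 15 nodes), using
L-BFGS-B with an analytic gradient; τ is optimised on the log scale.
Design columns are rescaled internally (distance is O(10⁴) meters) for
conditioning. Non-adaptive quadrature is used: at the unit sizes and
τ² ≤ ~0.2 of all study conditions here, estimates move by < 2·10⁻⁴ between
7 and 15 nodes and < 10⁻⁵ between 15 and 31 (tested); adaptive centering
would add per-unit mode searches with no measurable benefit in this
regime. Fits were spot-validated against `lme4::glmer` (nAGQ = 15), which
agrees to ~5 decimals on coefficients, standard errors, τ² and
log-likelihood.

Because the log-likelihood is flat in log τ as τ → 0 (its τ-gradient
vanishes at zero by node symmetry), small-τ iterates stall above the
boundary; whenever the τ² = 0 profile (a plain logistic fit by Newton
iteration) matches the optimum within 10⁻³ log-likelihood units, the fit
is reported as a boundary fit with τ² = 0 exactly and the plain-logistic
coefficients. Wald standard errors come from the observed information
(central-difference Hessian of the marginal log-likelihood at the MLE;
fixed-effect block only for boundary fits); a singular information matrix
is flagged as possible separation and pseudo-inverted. Units with a
single case are retained — block-level fits require it — with
identifiability resting on the pooled τ². One-sided p-values (used for
the distance test at α = 0.1) halve the two-sided Wald p in the direction
of the estimated sign.

`predict_risk` is the population-median prediction (U₀j = 0): the
inverse-logit of the linear predictor for a given profile and distance.

## Level comparison

One fit per replicate column at the block level (warm-started from the
previous replicate's solution; non-converged fits are excluded with a
count, and more than 10% failures aborts the analysis). Per variable the
replicate distribution is summarised by mean, min, max and a histogram
(Freedman–Diaconis bins, 20-bin fallback for degenerate IQR).
`inside_range` uses the closed interval [min, max]; `sign_change` compares
the zone coefficient's sign against the replicate mean's. Predicted-risk
contrasts default to 0 and 20 km.

The envelope [min, max] measures *imputation* uncertainty only: the
demographic covariates are fixed case attributes, so their replicate
spread (typically ±0.02 on the logit scale) is far smaller than their
case-sampling standard errors (~0.15–0.2 at ~1000 cases); the distance
coefficient, whose covariate is re-measured every replicate, has an
envelope comparable to its sampling error. Coverage statements about the
envelope therefore concern the imputation mechanism, not total inferential
uncertainty.

## Synthetic generator

Blocks are a square grid (default 12 × 12, 2 km spacing) tiled by
rectangular zones (3 × 3 blocks, 16 zones); the road network is the
4-neighbour lattice on block centroids. Block totals follow
exp(−g·r/r_max) (largest-remainder rounding; g = 0 uniform, g = 3 strongly
monocentric). The black population (county share 6–10%) is allocated by a
two-component mixture: fraction s (the segregation knob) to the contiguous
20% of blocks nearest the centre, weighted by block total, the remainder
proportionally everywhere; s = 0 is proportional mixing, s = 1 full
concentration. Age structure interpolates a zone-level elderly share from
centre to edge; within-block race × age counts are multinomial. Facilities
sit on block centroids, either spread over above-median-density blocks
("dispersed") or all inside the densest zone ("clustered").

Cases are distinct persons drawn without replacement across all
block × subgroup cells (multivariate hypergeometric), which guarantees the
disaggregation capacity invariant by construction. Each case's late-stage
indicator comes from the true logistic model using its true block's
network distance, its subgroup dummies, and a block-level random intercept
(τ² = 0.1 by default — area-level variance for late-stage diagnosis is
small in the multilevel cancer literature). Released cases carry only
their zone label, a representative age within band, diagnosis year, and a
stage code (a ~5–6% unstaged fraction exercises the filtering); the truth
table retains block, distance and outcome.

Preset scale matches the study regime the package targets: ~1100 / ~800
cases per county with late shares ≈ 0.39 / 0.32, subgroup case mixes with
small black cells, and true coefficients of the magnitude seen in
county-level late-stage models (age effects 0.3–0.7, black effect 0.4–1.1,
distance ~10⁻⁵–10⁻⁶ per meter; intercepts −0.75 / −1.34 chosen to hit the
target late shares given each preset's covariate mix). The generator does
**not** emulate: realistic street networks or block geometries,
variable-sized zones, within-band age–incidence gradients, or
registry/census undercount mismatch. Passing tests therefore demonstrate
the mechanics and the direction of aggregation effects, not their
real-county magnitudes — in particular the spectacular zone-level
distance-coefficient reversal seen on real bifurcated geographies is only
partially reproduced (the zone estimate degrades relative to block
estimates in ~70% of seeds, but rarely escapes the block envelope, whose
distance spread is wide).

## Problem sizes used by tests and experiments

Analysis drivers default to R = 100 replicates; distributional oracles use
R = 4,000–10,000 draws on 2–3-block toys; the repeated-seed experiments
use 50 seeds with R = 200 (recovery, `kane_like`) and R = 100 (contrast,
`peoria_like`); the conservation check runs one county-scale matrix at
R = 1000. These sizes give Monte Carlo standard errors well inside the
asserted tolerances while keeping a full run in minutes on one core.
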