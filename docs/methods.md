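# Methods

`paleoniche` implements a deep-time niche-dynamics and dispersal analysis as a
set of composable stages over a time-calibrated phylogeny with fossil
(non-contemporaneous) tips. This note documents the models, their
assumptions, the tunable parameters, the synthetic-data generator, and the
numerical choices, in that order. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Trees and the Brownian covariance

All comparative machinery is built on the covariance implied by Brownian
motion (BM) on a rooted tree: `cov(i, j) = sigma^2 * t_ij`, with `t_ij` the
root-to-MRCA path length shared by nodes i and j. Nothing assumes
ultrametricity — fossil tips simply have shorter root-to-tip depths — so
phylogenetic signal, ancestral reconstruction, PGLS and the model suite all
apply unchanged to trees mixing extant and extinct tips. Branch lengths are
in My, ages in Ma with the youngest tip at 0.

## Ancestral states and phylogenetic signal

- **Continuous ASR** is the GLS/BLUP estimator: internal states are the
  conditional expectations given tips, with the root (trait mean) profiled
  out by GLS. Prediction variances include the GLS-root uncertainty term
  `var(mu) * (1 - w'1)^2`; on BM simulations the resulting 95% intervals
  cover true node values at close to nominal rate (asserted 92–98% in the
  suite).
- **Discrete ASR** uses a one-rate symmetric Mk model, rate ML-fit, with
  marginal posteriors from the standard up/down pass and a flat root prior.
  A single observed state pins the rate at the lower boundary and the root
  posterior at 1 — reported, not an error.
- **Pagel's lambda** scales shared covariance off-diagonals; the search
  interval is `[0, lambda_max]` where `lambda_max` is found by bisection on
  Cholesky success, so values above 1 are attainable whenever the transformed
  covariance stays positive definite. p-values are likelihood-ratio tests
  against lambda = 0.
- **Blomberg's K** follows the standard MSE0/MSE construction with the GLS
  root estimate and the Brownian expectation
  `(tr C - n / (1'C^-1 1)) / (n - 1)`. Significance is a tip-shuffling
  permutation test; with the default 10,000 permutations the smallest
  reportable p is 1/10,001 ≈ 0.0001.

## Trait-evolution model suite

Nine models are ML-fit and compared by AICc (`AICc = -2logL + 2k +
2k(k+1)/(n-k-1)`): white noise (WN), BM, linear rate trend (RT), directional
mean trend / drift (MT — identifiable here because fossil tips break
ultrametricity), delta (DT, node-depth power), lambda (LB), kappa (KP,
branch-length power), early burst (EB, exponentially decaying rate), and a
single-optimum OU with the root at the optimum (non-ultrametric covariance
`sigma^2/(2a) e^{-a d_ij}(1 - e^{-2a s_ij})`). The trend models use the
standard parameterizations; whether a given published "rate trend"/"mean
trend" matches these exactly cannot be established from names alone, so the
mapping is: RT = time-linear rate, MT = BM plus drift. Each one-parameter
transform is profiled (sigma^2 and the mean analytically), optimized by a
coarse grid plus bounded refinement. On fossil-bearing trees the
three-parameter transforms have genuinely more latitude than on ultrametric
trees, and AICc selects against BM somewhat more often; the BM-recovery
property (BM within 2 AICc of the best model in >= 80% of BM simulations) is
therefore checked on ultrametric pure-birth trees, its standard setting.

## Rate through time

In place of a reversible-jump shift model, rate through time is a clearly
labelled proxy: each internal node's squared standardized contrast (a local
`sigma^2` estimate under BM) is assigned to the node's age, averaged per time
bin, with percentile-bootstrap CIs. The proxy is flat (slope CI covering 0)
under constant-rate BM and declines under a planted early burst — exactly the
qualitative claims it is used to test. It does not detect discrete shifts.

## Niche modeling (ENM)

The suitability model is the linear-feature maximum-entropy (MaxEnt) Gibbs
distribution over background cells: `q(x) ∝ exp(w·z(x))` with features
scaled to [0, 1] by background min/max, fit by minimizing the convex
L1-regularized objective. Regularization is
`beta_f = reg_multiplier * sd_f(presences) / sqrt(n_presences)` with
`reg_multiplier = 1.5` by default; at the optimum each feature's model
expectation lies within `beta_f` of its presence mean (KKT, asserted).
Optimization is split-variable L-BFGS-B followed by an active-set Newton
polish to machine precision. Output defaults to the complementary log-log
transform `P = 1 - exp(-e^H q)` (H the entropy of q), with a raw-density
switch; the three suitability classes are `P > 0.5` suitable,
`0.3 < P <= 0.5` less suitable, `P <= 0.3` unsuitable (the boundary points
0.5 and 0.3 fall in the lower class, since only the middle band is stated as
an open interval).

Variable screening groups variables at `|r| >= 0.8` (configurable) and keeps
the group member with the largest PCA contribution, computed over the
leading components covering 80% of variance (weighting over all components
of a correlation PCA is identically 1/p and cannot discriminate). Spatial
thinning is greedy in input order (first kept wins) with great-circle
distances, default radius 6 km. Evaluation uses random presence splits
(default 20% test, 10 replicates) and reports replicate-averaged AUC of
presences against the background.

Because the features are linear only, a unimodal (Gaussian-in-temperature)
niche is deliberately outside the model class; the power property (training
AUC > 0.8) is demonstrated with a loglinear planted suitability, the matched
generator/model pair. The default scenario's Gaussian niche yields lower AUC
(~0.7), which is the expected behaviour, not a defect.

## Niche position and breadth (OMI)

Sites are weighted by total abundance; environment variables are centred and
standardized under those weights. A species' niche position (NP,
marginality) is the squared distance of its abundance-weighted centroid from
the origin; niche breadth (NB, tolerance) is the abundance-weighted variance
of its sites about that centroid; canonical weights are eigenvectors of the
species-weighted marginality cross-product. Presence records are converted
to abundance by counting records per grid cell. Species-weighted NP sums to
the cross-product trace (conservation, asserted to 1e-8), and all outputs
are invariant to affine rescaling of any variable — which also means NB
measures spread *relative to* the bin's overall environmental variance, so a
planted "expansion" must widen within-species spread relative to
between-species structure to register.

Two aggregation schemes are provided. The fine scheme uses 10-My bins except
for two 20-My bins spanning 105–65 Ma (16 bins for a 170-Ma root; the exact
published edges are not available, so the reconstruction closes with short
110–105 and 5–0 bins and is configurable). The coarse scheme defaults to
period boundaries 170/145/100/66/23/0 Ma — a documented guess, configurable.
Bins are half-open [older, younger), the youngest closed at 0.

## Causal inference (CCM)

Convergent cross-mapping embeds the putative *effect* series by time delay
(dimension E, lag tau), cross-maps the putative *cause* by simplex projection
(E+1 nearest neighbours, exponential distance weights), and measures skill
as the Pearson correlation of mapped versus observed cause. Defaults E=2,
tau=1; heuristics (`choose_embedding`: first 1/e autocorrelation crossing
for tau, a false-nearest-neighbour sweep for E) are available and their
choices returned for logging. Significance comes from phase-randomized
surrogates of the cause (default 100, seeded). The *convergent* flag demands
(i) a skill increase of more than 0.05 from the smallest to the largest
library — an any-sign slope criterion would be a coin flip on uncoupled
noise — and (ii) final skill above the surrogate null's 99th percentile,
chosen so the detector's false-alarm rate sits safely below the 5% control
requirement it must satisfy. Skill is invariant to affine rescaling of
either series.

## Historical biogeography

Ranges are nonempty subsets of up to eight realms (PA, OR, IN, SA, AT, AU,
NA, NT), default maximum range size 2 (state space 36 for 8 realms;
configurable to the full 255). Anagenesis is a CTMC: realm b is gained from
range R at rate `d * sum_{a in R} m(a, b)` and lost at `e` per resident realm
(only for ranges of size >= 2; the empty range is excluded). The multipliers
m follow the three barrier classes — 0.75 adjacent, 0.5 one barrier, 1e-6
isolated — and change across epochs; branches crossing an epoch boundary are
spliced deterministically at the boundary age. Cladogenesis weight tables:
DEC (single-area sympatry, subset sympatry, single-area vicariance),
DIVALIKE (single-area sympatry plus unrestricted vicariance, no subset
sympatry), BAYAREALIKE (identical inheritance), each optionally with
founder-event speciation (+j) into an outside realm, all outcomes
equal-weighted within class and normalized. The root prior is flat over
range states. ML fitting is Nelder–Mead in log(d), log(e) (and j), with
out-of-box proposals rejected inside the objective so the matrix exponential
never sees unbounded rates; models are compared by AICc.

Biogeographic stochastic mapping samples node ranges from conditional
likelihoods, then branch histories from endpoint-conditioned CTMC bridges:
rejection sampling (forced first jump when endpoints differ) capped at 1,000
attempts, then an exact uniformization bridge. Dispersal events (anagenetic
gains and cladogenetic founder events) are binned per My; realm-pair
percentages attribute each gain of realm b from range R to the resident
realm with the largest multiplier toward b (ties by realm order), and sum
to 100. Dispersal rate d is well recovered (median relative error ~24% at
64 tips in the suite); extirpation e is only weakly identified from extant
tip ranges — its estimate tends toward the boundary, a known property of
this model family, and the suite bounds it only to order of magnitude.

## Dispersal frequency versus wing length

The per-My dispersal-event series is binarized at its mean (1 = frequent).
The HMM reading adopted here: hidden state = dispersal regime, emission =
Gaussian wing length (WL) per regime; Baum–Welch is initialized from the
observed regimes, which afterwards label the states (state 1 = frequent).
The EM log-likelihood is asserted non-decreasing each iteration; degenerate
emission variances are floored at 1e-6 with a warning. An alternative
reading (observed regimes, WL as covariate) is noted but not implemented.
Pooling 10,000 simulated (regime, WL) sequences from the fitted model, a
logistic regression of regime on WL gives the threshold `-b0/b1` (the
P = 0.5 crossing); perfect separation is flagged and the threshold taken as
the separating-gap midpoint. Kernel densities use Silverman's bandwidth.
Group contrasts (e.g. falcate vs oval wings) use Welch's t and a Mann–Whitney
test whose null is exact (full enumeration) when both groups have <= 10
observations.

## Atmosphere

Moist-air density follows Dalton's partial-pressure decomposition
`rho = (P - Pv)/(R_d T) + Pv/(R_v T)` with R_d = 287.1 and
R_v = 461.5 J/(kg K); viscosity follows Sutherland's law with S = 110.4 K
and the standard air reference mu_ref = 1.716e-5 Pa s at T_ref = 273.15 K
(the reference point is not fixed by the cited constants and is a documented
default). Vapour pressure is taken as an input directly. The CFD
field-condition builder emits six transient sets ({v, rho, mu} × {max, min},
others at their means), one steady set (mean v and mu with minimum rho, the
adverse low-density case), and a min/mean/max summary. The flow solver
itself is out of scope.

## Habitability maps

Per-bin niche thresholds (min/max of tip and interpolated branch values per
variable) projected onto the bin's climate slice give a habitable mask —
single-variable mode (habitat mean annual temperature) or the intersection
over several variables. Habitable cells are split by accessibility: graph
reachability from the occupied realms over dispersal edges with multiplier
above 1e-6, in the epoch containing the bin. This reachability rule is this
package's concretization of "habitable but inaccessible" — no algorithm is
fixed by the source material — and is recorded in each map's metadata.

## The synthetic-data generator

The generator *is* the study conditions; all downstream tests are statements
about data with this structure.

- **Tree**: forward birth–death from two lineages at the root age
  (default 170 Ma), conditioned by bounded retry on at least `n_extant`
  survivors and pruned to exactly `n_extant` (default 25) random extant
  tips. Fossils are constant-rate Poisson samples on the complete tree
  (default conditioned to `n_fossil` = 25), grafted as 1e-6-My pendant tips
  so the tree stays binary with positive branch lengths. Default rates
  0.025/0.010 per My give a realistic ~50-tip clade over 170 My.
- **Traits**: niche optimum by BM (sigma^2 = 0.05 per My, root 16 degC);
  wing length by BM (0.02 mm^2/My) with a +0.025 mm/My directional trend
  from a 4-mm root, plus a +2 mm shift on falcate-wing lineages; wing shape
  by a 2-state Mk process (0.004/My). Node values are retained as ground
  truth.
- **Climate**: 36×18-cell (10-degree) grids per 10-My slice; area-weighted
  global mean temperature equals `14 + 0.05 * age` degC exactly when noise
  is off (a 8.5 degC secular cooling over 170 My, in the range of
  Cretaceous-to-present reconstructions); cosine latitudinal gradient;
  precipitation and other fields are deterministic functions of latitude
  plus spatially autocorrelated (Gaussian-filtered) noise. The real fields'
  spatial autocorrelation is unknown; the filtered-noise model is a free
  choice. Elevation is one smooth static field.
- **Occurrences**: per tip, records drawn from the slice nearest its age
  with probability proportional to a Gaussian suitability in temperature
  centred on the tip's own niche optimum (width 6 degC); the record's
  11-variable environment is read exactly from the chosen cell. No plate
  rotation: paleocoordinates equal coordinates.
- **Realm history**: 4 epochs; each realm pair drawn from the barrier
  classes with probabilities (0.45, 0.35, 0.20); a random spanning chain
  connects a core of the realms (all but at most two), leaving some realms
  potentially isolated in an epoch so the habitable-but-inaccessible class
  is attainable.
- **Ranges**: simulated forward under DEC (d = 0.015, e = 0.004 per My)
  with the planted coupling: the dispersal rate is scaled by
  `exp(beta * (E[WL at age] - WL_ref))`, beta = 1 per mm — wing elongation
  through time accelerates dispersal, the signal the downstream Spearman /
  HMM / logistic stage must recover.
- **Atmosphere**: temperature from the record's habitat temperature,
  pressure by barometric decay with elevation, vapour pressure from a random
  relative humidity (0.3–0.9) times the Magnus saturation pressure, wind
  lognormal around ~3 m/s.

What the generator does not emulate: real plate rotations, real WorldClim
layers, spatial sampling biases of the fossil record, taphonomic loss
correlated with environment, or niche multidimensionality beyond the planted
temperature axis. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted signals under these idealized
conditions — not that the pipeline would reach the same conclusions on any
real dataset.

## Problem sizes and runtime

The default full pipeline (25+25 tips, 8 realms, six biogeographic model
variants, 200 stochastic maps, 10,000 HMM simulations) completes in roughly
a minute on one CPU. The statistical test suite uses: 200 BM simulations at
128 tips for the K/lambda calibrations (499 permutations per white-noise
type-I replicate); 50 replicates of 64-tip two-realm DEC recovery; 2,000
unconditional simulations for the simulation-versus-pruning agreement; 20
seeded replicates each for the cross-mapping benchmark and its noise
control; and 50 end-to-end replicates at a reduced scenario size (20 extant
+ 10 fossil tips, 4 realms, 40 stochastic maps) for the planted
dispersal/wing-length signal. These sizes are the package's chosen
trade-off between statistical resolution and a test suite that runs in a
few minutes.

## Known limitations

- The biogeographic state space is truncated at range size 2 by default;
  analyses of clades with genuinely wide ranges need `max_range_size`
  raised, at combinatorial cost.
- Extirpation rate e is weakly identified (see above).
- The rate-through-time proxy cannot localize discrete rate shifts.
- The HMM reading of the dispersal/WL integration is one of at least two
  defensible readings (documented above).
- CCM on short paleo series (tens of points) has limited embedding room;
  results should be read jointly with the plain correlations.
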