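# Methods

This note documents the models implemented in `paleorange`, the choices
made where the design was genuinely open, what the synthetic-data
generators emulate, and the package's known limitations. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The time-stratified DEC model

Geographic range evolution follows the dispersal–extinction–
cladogenesis (DEC) model: a lineage's range is a non-empty set of
discrete areas, evolving as a continuous-time Markov chain.

**Anagenetic process.** Along a branch, a range `R` gains an
unoccupied area `a` at rate `d × |{b ∈ R : adjacency[b, a] = 1}|`
(dispersal, `d` per source–destination pair per Myr, equal across
pairs) and loses an occupied area at rate `e` per area per Myr
(extirpation). Losing the last area is global extinction — an
absorbing null state that no tip can exhibit. Connectivity is
piecewise-constant in time: each time slice carries a symmetric 0/1
adjacency matrix, and within a slice the state space is restricted to
ranges that form a connected subgraph of that slice's adjacency graph
and contain at most `max_range_size` areas (default 5, the size of the
largest ancestral ranges the analysis is expected to rank). The
default four slices follow the major geological reorganizations:
358.9–201.3 Ma (assembled Pangea), 201.3–66 Ma (Pangea breakup),
66–23 Ma (Paleogene) and 23–0 Ma (Neogene to present). Boundary times
belong to the younger slice (half-open intervals, youngest closed at
the present).

Choices where conventions vary:

* The model's global state space is the union over slices of the
  per-slice allowed ranges, plus the null range. A range not allowed in
  the current slice keeps its slot but has a zero rate row there (it is
  frozen); no probability mass is remapped at slice boundaries, and
  such states receive zero marginal probability at nodes dated inside
  that slice.
* An extirpation whose remainder range is disconnected in (and hence
  absent from) the state space is dropped rather than remapped; the
  diagonal is minus the realized row sum. This matches pruned-state-
  space practice in DEC implementations.
* Cladogenetic outcomes whose daughter range is absent from the state
  space contribute zero likelihood; the cladogenetic distribution is
  *not* renormalized over the remainder (the combinatorial enumeration
  below defines it).

**Cladogenetic process.** At a node, a single-area range is copied to
both daughters (sympatry). A widespread range draws uniformly from:
subset sympatry — one daughter a single occupied area, the other the
full range, both orders — and vicariance — a disjoint split covering
the range with at least one single-area daughter, both orders. A range
of size `k > 1` therefore has `4k` outcomes minus duplicates (six for
`k = 2`). Wide vicariance (both daughters multi-area) and founder-event
jumps are deliberately absent.

**Likelihood.** Felsenstein pruning from the tips; each branch is cut
at slice boundaries and each segment propagated by the exponential of
that slice's generator (dense `expm` for state spaces up to 160,
`expm_multiply` on the sparse generator above that). Partial
likelihood vectors are rescaled per node to avoid underflow. The root
likelihood is the plain (unnormalized-flat) sum over ranges allowed in
the root's slice — the Lagrange convention, under which a dataset with
no possible events has log-likelihood exactly 0. Fossil tips enter as
ordinary tips at their ages; an ambiguously coded fossil ('?' in the
range file) assigns tip likelihood 1 to every range containing its
observed areas.

**Survival conditioning.** By default the likelihood is *not*
conditioned on survival (classic DEC behavior). With
`condition_on_survival=True` it is divided by the probability that
every sampled tip lineage avoids the null state, computed by a second
pruning pass in which every tip vector is the indicator of non-null
allowed states. This matters whenever the data were filtered for
survival (as simulated recovery data must be): without it the
extirpation-rate MLE collapses to zero, because the unconditioned
likelihood charges `e` for the survival of every observed lineage.

**Estimation.** `DECModel.fit()` maximizes the likelihood over
`(d, e)` by L-BFGS-B on log rates, bounds `[1e-8, 10]` per Myr, three
starting points by default. Standard errors come from the numerical
observed information in log-rate space (delta method back to natural
scale); they are asymptotic and unreliable when a rate sits at the
boundary. `DECResults.ancestral_ranges()` computes *marginal*
ancestral-range probabilities by the standard outside (re-rooting)
pass, normalizes them per node, ranks them, and flags the "equally
likely" set — ranges whose log marginal likelihood is within 2 units
of the best. Joint ("global") reconstruction is not implemented.

## Event extraction

Events are counted from point estimates (the best range per node), as
a custom post-processing script would, not by stochastic mapping.

* At each internal node the cladogenetic scenario of the best parent
  range minimizing total implied anagenetic change (symmetric
  difference to the daughters' best ranges) is selected; ties prefer
  fewer dispersals, then enumeration order. The node is classified
  sympatry / subset sympatry / vicariance; configurations no scenario
  explains cleanly are logged as "anagenetic-adjusted", never raised.
  Per-node minimization is globally minimal because corner choices do
  not interact across nodes.
* Differences between a daughter's inherited corner range and its best
  range become branch events: one dispersal per gained area, with the
  full source range recorded (so the "out of" tally adds one count per
  source area — deliberately an overcount when the source is
  widespread), and one extirpation per lost area.
* Anagenetic events are dated at branch midpoints. If the event is
  impossible in the midpoint's slice (no source area adjacent to the
  gained area), the date snaps to the midpoint of the nearest
  sub-interval of the branch where it is possible; events possible in
  no slice keep the midpoint and carry an "unconstrained" flag.
* Summaries tally per-area counts, high- versus low-latitude aggregates
  (default high: WP, EP, WN, EN, GR, AN — a documented, overridable
  guess, since the source aggregation does not list its members), the
  vicariance total, and extirpations per time bin (default Cenozoic
  versus older).

A consequence worth knowing: given only node ranges, a vicariance
followed by a regain on a daughter branch is indistinguishable from
subset sympatry, so extracted totals are the *minimal* counts
consistent with the estimates — a lower bound on the latent history's
gross counts. The tests assert exact agreement with an independent
exhaustive-enumeration oracle of that minimum.

## Directional Brownian motion for latitude

Latitude evolves as Brownian motion with rate `sigma2` plus a
piecewise-constant drift: bin `k` (default bins = the four geological
slices) contributes `mu_k` degrees/Myr, so a branch increment is
Normal(Σ_k mu_k t_k, sigma2 t). Traits are divided by 10 before
analysis to help mixing; all reported values are mapped back to
degrees. Inference is MCMC with node-state augmentation:
Metropolis-Hastings with multiplicative proposals for `sigma2`,
additive for each `mu_k`, and sliding-window updates for single latent
node states, with proposal widths auto-tuned during burn-in only.
Defaults: 100,000 elementary updates, 10% burn-in, thinning 100. A
posterior sample of trees can be supplied; the tree index is resampled
every 1,000 updates, parameters carry over, latent states are
re-initialized. A fossil tip attached by a zero-length branch (sampled
ancestor) pins its parent's latent state to the observed value, and
the zero-length edge carries no density.

The exact likelihood and prior parameterization of the originally
published variable-trend implementation is not fully specified in
print; this module is a documented, testable realization of the model
family. Priors (rescaled scale): `sigma2` half-Cauchy(1), `mu_k`
Normal(0, 10²), root state Normal(0, 50²). On an ultrametric tree with
a single bin the trend and the root state are exactly confounded —
fossil tips at varying ages are what make the trend identifiable, which
is why the recovery experiments simulate fossil-bearing trees.

The latitudinal span through time interpolates each lineage's latitude
linearly between sampled node states on a time grid and pools all
lineage values per grid time across posterior samples; both a quantile
envelope (default 2.5–97.5%) and the absolute min/max are available,
since the corresponding published figure does not state which it shows.

## Synthetic data

The generators define the study conditions the tests and the
acceptance script run under.

* **FBD trees** (`simulate_fbd_tree`): forward constant-rate
  birth–death from an origin, Poisson(ψ) fossil sampling along
  lineages, Bernoulli(ρ) sampling of extant tips, pruned to sampled
  tips; fossil samples with sampled descendants become zero-length
  terminal branches (sampled ancestors), keeping the tree strictly
  binary. Rejection until at least two tips survive — expectations
  conditional on that event are what the calibration tests check.
* **DEC histories** (`simulate_dec_history`): Gillespie along branches
  with slice-dependent rates, cladogenetic draws at nodes, a full
  event log whose replay reproduces every branch's end state. Lineages
  hitting the null range are marked extinct-in-place.
  `simulate_dec_history_conditioned` draws from the *exact*
  distribution of the process given that every tip survives (a Doob
  h-transform: survival-below vectors from a pruning pass, conditional
  root/cladogenesis draws, per-branch rejection against the end
  state's survival probability). Recovery experiments use it paired
  with the survival-conditioned likelihood so the estimator is
  correctly specified; naive alternatives (pruning dead tips, or
  resampling each branch until it survives) measurably bias the
  extirpation-rate MLE (toward zero, or upward, respectively).
* **Latitudes** (`simulate_latitudes`): root from the prior or a given
  value, then Normal increments per branch.
* **Study-scale fixture** (`make_paper_like_fixture`): an FBD tree
  rejected into windows of roughly 260–390 extant tips, 38–85 fossil
  tips and a 296–358.8 Ma root; the 14-area, four-slice geography with
  coarse paleogeographic adjacency (Pangea; Laurasia/Gondwana;
  Paleogene remnant corridors through Greenland and Antarctica; the
  modern configuration); DEC rates d = 0.0006, e = 0.02 with
  survival-conditioned branches, tuned so at least 95% of tips are
  single-area (emulating the extreme endemism of the motivating
  group, where about 3% of species occupy more than one area);
  fossils coded ambiguously; directional-BM latitudes from +25° with a
  mild poleward-then-equatorward trend (+0.04, +0.04, −0.06, −0.2
  deg/Myr across the four slices, σ² = 1.2 deg²/Myr), truncated at
  ±89° when written (plain BM is unbounded; coordinates are not).
  About 65% of extant and 80% of fossil tips receive latitude values,
  emulating incomplete occurrence and paleolatitude data. Everything
  is bit-reproducible under a fixed seed.

What passing tests on these data do *not* show: the generators assume
rate homogeneity across lineages, exact tip ages, a correctly specified
geography and a binary consensus tree; real datasets violate all four,
and ambiguity in fossil placement or dating is not propagated here.

## Problem sizes and numerics

The test suite runs the recovery experiments at 20 replicates of
150–280-tip trees (DEC) and 10 replicates of 70–160-tip trees with
300,000 MCMC updates (trend); `scripts/acceptance.py` re-runs the same
experiments at 8 and 5 replicates respectively — sizes chosen to keep
a full from-scratch run to a few minutes — plus the full pipeline on
the study-scale fixture with a single optimizer start. Matrix
exponentials switch from dense to sparse `expm_multiply` above 160
states (the 14-area geography has 342 reachable states). Branch
segments shorter than 1e-12 Myr are skipped; zero-length edges in the
latitude model get a 1e-8 Myr variance floor if they are not pinned.

Known limitations:

* The extirpation rate is intrinsically weakly identified at realistic
  rates: the observed information per ~200-tip dataset puts the
  standard error of log e near 0.5, so individual-dataset MLEs scatter
  two-fold around the truth even though the estimator is unbiased (a
  pooled-likelihood check across 120 datasets recovers both rates
  within 15%). The recovery tests document where this lands relative
  to their thresholds.
* Ancestral estimates are marginal; joint reconstruction and
  stochastic mapping of events are not implemented.
* Dispersal-rate multipliers between area pairs, founder-event
  speciation and wide vicariance are out of scope by design.
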