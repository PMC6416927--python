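# Methods

This note documents the models, the numerical choices, and the synthetic
data behind `dupdyn`, and what the tests do and do not establish about
behavior on real data.

## Ancestral-state model

Discrete characters — expression quartiles {0,1,2,3} or binding-site
presence {0,1} — evolve along a rooted family tree under a homogeneous
continuous-time Markov chain with generator Q (rows sum to zero,
P(t) = exp(Qt)). Three rate parameterizations are available:

* `equal` — one exchange rate (the binary case is the symmetric two-state
  chain); 1 parameter;
* `symmetric` — q_ij = q_ji free; k(k−1)/2 parameters (default);
* `free` — all off-diagonal rates; k(k−1) parameters.

The root prior is uniform (no outgroup information survives midpoint
rooting, and nothing in the data identifies a root frequency vector).
Missing tip values contribute a partial likelihood of 1 in every state,
i.e. they are marginalized rather than treated as a fifth character state;
this is a deliberate simplification of pipelines that model "ambiguous"
as its own state, and it is the main modeling choice a user comparing
against such pipelines should be aware of.

Likelihoods use the pruning recursion vectorized across items; for the
symmetric parameterizations P(t) for all edges comes from one real
eigendecomposition of Q. Marginal posteriors at internal nodes use an
inside–outside pass (outside vectors propagated root-to-tips), which
equals brute-force enumeration over internal assignments to < 1e-9 on
small trees (property-tested).

Rates are estimated by maximizing the log-likelihood over log-rates with
Nelder–Mead (derivative-free; gradient methods overshoot onto the flat
high-rate plateau of the surface, where P(t) is effectively stationary and
the optimizer stalls). Log-rates are clipped to [ln 1e-8, ln 1e4].
Multi-start: initial rates log-uniform on [0.01, 3].

**Consensus calls.** The fit + reconstruction is repeated `consensus_runs`
(default 100) times from independent random initializations. A run votes
for a state at a node × item when its marginal posterior exceeds
`posterior_min` (0.5). The modal state is called when its support strictly
exceeds `consensus_min` (50); otherwise the call is ambiguous and
downstream analyses drop that item. Because every restart typically
converges to the same ML optimum on well-behaved data, the consensus
mainly filters items whose posterior hovers at the threshold under
slightly different fitted rates.

Posteriors are well calibrated when the fitted model family contains the
generating process: in simulations, realized accuracy of called states
tracks the mean posterior of the calls. Recovery accuracy is therefore
governed by tree depth relative to the rate — on near-saturated trees the
procedure (correctly) refuses to call most deep ancestors rather than
guessing.

## Discretization and rooting

Quartile states use the empirical 25/50/75 percentiles of all non-missing
values in an experiment (a named group of condition columns; by default
each column). A value's state is the number of boundaries strictly below
it, so boundary ties collapse downward and a constant experiment maps
to state 0. Experiments with fewer than 4 values become all-missing with
a warning. The Diff subset is elementwise stress − control on the log2
scale under an explicit stress↔control pairing map; the pairing is user
input because it is not recoverable from condition names in general.

Midpoint rooting finds the tree diameter from the flattened array view and
places the root half-way along it, handling the degenerate case where the
midpoint falls exactly on a node (the bundled dendropy `reroot_at_midpoint`
mis-roots that case, so the search is done here and dendropy only performs
the edge reroot). Branch lengths are used exactly as given — no rescaling.

## Pair partitioning and nulls

Classification is per item: O/I/II by comparing both extant states to the
called ancestral state; any ambiguous/missing value drops the item (not
the pair). Two resampling nulls are used:

* **state grids** — ancestral values are permuted against extant values
  (equivalently, re-paired draws from the two pools), preserving both
  marginal totals in every replicate; z = (obs − mean)/sd per cell, with
  sd = 0 cells reported as NaN;
* **pair-state fractions** — gene B of each pair is re-paired at random
  within a stratum (e.g. WGD event), keeping each gene's own retention
  profile. Stratification matters: pairs from one WGD event share an age,
  and pooling ages into one permutation pool would deflate the expected
  partitioned fraction by twice the between-age variance of the retention
  probability and bias z negative. A pooled statistic with within-stratum
  permutation is reported alongside per-stratum rows.

The asymmetry score is Y = |2F_A − 1| over a pair's partitioned items,
computed only when n ≥ `min_partitioned` (5; the site path uses
`min_sites`, same default, same code). Ties (k_A = n/2) designate the
ancestral copy by a draw from the run RNG so runs are reproducible. The
null redraws k_A ~ Binomial(n, ½) per pair, grouped by the observed n;
both the replicate-mean distribution and the pooled per-pair draws are
exposed, and the observed-vs-null test defaults to Welch's t on per-pair
values (testing means-of-means against per-pair values is ambiguous in
the two-sample framing; the choice is configurable by using
`replicate_means` directly). E[Y | n] is computed exactly by binomial
enumeration (0.375 at n=5, 0.3125 at n=6) and is non-increasing in n.

Novel-site analysis counts sites present in an extant copy but absent in
the called ancestor. The sign test is a one-sided exact binomial over
pairs with ≥ 1 novel site (direction: non-ancestral copy has more); the
pooled 2×2 table is copy type × (novel vs inherited) sites with the
conditional-odds-ratio estimate, central exact CI, and Fisher's exact p.

## Kinetic models

Pair model (column-stochastic generator, states O/I/II):

    d/dt (O,I,II)^T = [[-x,  y,      0],
                       [ x, -(y+w),  z],
                       [ 0,  w,     -z]] (O,I,II)^T

Single-copy model (states O/+/−) is implemented in the mass-conserving
form [[-(x+y), w, z], [x, -w, 0], [y, 0, -z]]: the sign-flipped (−y)
variant sometimes written for its third row does not conserve probability
(columns must sum to zero), so the conserving correction is used without
further reinterpretation.

Solutions use eigendecomposition of the 3×3 generator vectorized over
time points, with a matrix-exponential fallback when the eigenvector
matrix is ill-conditioned (near-defective spectra); analytic vs adaptive
numeric integration agrees to < 1e-7 over t ∈ [0, 5] (tested on random
rate draws). Initial conditions default to (1, 0, 0) — everything starts
with the ancestral state retained — and are configurable.

Fitting maximizes the categorical log-likelihood Σ log p_class(d_S) over
per-observation (class, d_S) data — no time binning, which avoids an
arbitrary bin choice; binned curve export for plotting is a presentation
concern, not a fitting one. Rates are tied into groups by variant: `one`
(x=y=w=z), `two` (pair: {x,y}|{w,z}; single-copy: {x,w}|{y,z}, i.e. the
up-branch vs down-branch rates, so the O→−/O→+ ratio is y/x), `four`
(all free), or any explicit partition of {x,y,w,z}. Optimization is
Nelder–Mead over log-rates (clipped to [1e-8, 1e3]) from `n_starts`
random initializations (default 20); estimates within 1e-6 of a bound
are flagged as boundary solutions. The LRT uses 2ΔlnL against χ² with
df = difference in free-rate counts and requires strict nesting of the
rate groups.

## Retention modeling

R_g,w uses the printed odds-ratio formula; its 95% CI is the central exact
conditional (noncentral hypergeometric) interval via
`scipy.stats.contingency.odds_ratio(kind="conditional")`, verified in the
tests against an independent inversion built from binomial coefficients
and bisection. Group filtering keeps 100–2000 genes (inclusive) and ≥ 20
duplicate pairs. Feature pre-filtering removes blacklisted (e.g.
d_S-derived), mostly-missing (> 50%) and constant features, then keeps one
representative per cluster of |r| > 0.7 features, preferring in order
(1) stronger marginal correlation with the odds, (2) not-derived features,
(3) fewer conflicts; this priority order is a design choice where the
criteria can conflict.

The linear model regresses the odds ratio itself (a log-odds option
exists) on features, unweighted by group size (a weighting flag is a
natural extension; unweighted is the default because nothing in the
procedure defines weights). Backward elimination drops the
largest-p-value coefficient each step and returns the visited model with
the globally maximal F-statistic — elimination runs to the end rather than
stopping at the first local F maximum, so "maximized" is global over the
elimination path. Importance per retained feature is the drop in R² when
that feature alone is removed. Leave-one-group-out reruns the whole
elimination per omission and reports per-parameter mean/sd/relative sd;
failed refits are recorded and excluded.

## Synthetic data

Generators are seed-deterministic from a single `numpy.random.Generator`
stream. Trees come from a coalescent-style join process with exponential
height increments (mean edge scale 0.3 by default; the cohort generator
exposes `mean_edge` — the analysis drivers use 0.12, a moderate-divergence
regime in which most ancestors are inferable). States evolve by sampling
the CTMC kernel per edge; pair fates are drawn from the analytic kinetic
distribution at t = d_S, with event-specific d_S windows ordered
alpha < beta < gamma (0.3–1.0, 1.0–2.0, 2.0–3.5) to mimic WGD age
ordering. Group feature tables draw features Uniform(0,1), set latent
odds = intercept + Xβ + N(0, noise_sd) (floored at 0.01), and draw
duplicate counts binomially around the implied retention probability; a
background pool 400× the grouped genes keeps the complement's odds within
~0.4% of the nominal background so empirical R converges to the latent
odds as counts grow.

What the synthetic cohorts do **not** emulate: microarray noise spectra
and normalization artifacts, correlated conditions within real time
series (beyond the series annotations used by the robustness subsets),
gene-tree/species-tree discordance, rate heterogeneity across sites or
branches, and selection-driven correlation between expression and site
loss. Passing tests therefore demonstrate correctness of the estimators
and calibration of the resampling nulls under the stated models — not
robustness to those real-data complications.

## Problem sizes and defaults

Analysis-driver cohort: 20 families × 6 tips, 24 conditions, 10 sites,
30 consensus runs (the pipeline default is 100, matching the procedure's
support semantics; 30 keeps the demo run to a few minutes and behaves the
same because restarts converge to the same optimum). Validation
experiments in the test suite use 5000 pairs × 20 replicates for kinetic
rate recovery, 200 simulations at 400 pairs for LRT type-I calibration,
500 pairs × 12 items for the partitioned-excess checks, and 20 seeds of
the 20-group/11-feature retention benchmark.

## Known limitations

* Consensus support reflects restart stability, not posterior sampling;
  it is not a Bayesian credibility measure.
* The kinetic models assume one global rate set across families and
  events; per-event fits with shared parameters are out of scope.
* Midpoint rooting is used for all trees regardless of clock violations —
  consistent with treating it as the least-bad universal choice, but
  rooting error propagates into which node is "the" pair ancestor.
* With few observations the four-parameter kinetic fit can run y or z to
  a bound (they are weakly identified when almost no mass returns from
  I/II); boundary flags mark such fits.
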