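# dupdyn

Retention and divergence dynamics of duplicate genes created by whole-genome
duplication (WGD), for molecular evolution researchers studying
subfunctionalization and neofunctionalization — in particular the fate of
transcription-factor (TF) duplicates in *Arabidopsis thaliana*-style data,
where all genes duplicate at once (the α, β and γ events) and are then
differentially lost.

The package implements four connected analyses:

1. **Retention odds and linear modeling** (`dupdyn.retention`). For a
   function group *g* and WGD event *w*, retention is summarized by the odds
   ratio

   R<sub>g,w</sub> = (D<sub>g,w</sub> / S<sub>g,w</sub>) / (D<sub>¬g,w</sub> / S<sub>¬g,w</sub>)

   of WGD-duplicate (D) to WGD-singleton (S) counts inside vs outside the
   group, with an exact conditional 95% CI. A linear model relating
   R<sub>g,w</sub> to group features is pruned by backward elimination
   (drop the feature with the largest p-value, refit, keep the visited model
   maximizing the overall F-statistic) with leave-one-group-out robustness.

2. **Ancestral-state inference** (`dupdyn.ancestral`). Expression is
   discretized into quartile states 0–3 per experiment; family trees are
   midpoint rooted; discrete characters (quartiles, or 0/1 binding-site
   presence) evolve under a continuous-time Markov chain whose rates are fit
   by maximum likelihood with the Felsenstein pruning recursion. Marginal
   posteriors at internal nodes come from an inside–outside pass. The fit is
   repeated from 100 random initializations and a state is *called* only
   when the same state wins in more than 50 runs with posterior > 0.5 —
   everything else is ambiguous and excluded downstream.

3. **Pair partitioning and asymmetry** (`dupdyn.pairs`, `dupdyn.asymmetry`).
   Each duplicate pair × item is classed O (both copies retain the ancestral
   state), I (exactly one; "partitioned") or II (neither). Observed grids and
   pair-state fractions are tested against permutation nulls (pooled
   re-pairing). Per pair, asymmetry of inheritance is
   Y = |2F<sub>A</sub> − 1| over its n ≥ 5 partitioned items, tested against
   a grouped Bernoulli null (k<sub>A</sub> ~ Binomial(n, ½), keeping the
   observed n distribution); E[Y | n] is also computed exactly by
   enumeration. Novel binding sites (present in a copy, absent in the
   ancestor) are compared between ancestral and non-ancestral copies with an
   exact sign test and a pooled 2×2 odds ratio.

4. **Kinetic ODE models** (`dupdyn.dynamics`). Loss of ancestral states is
   modeled by three-state systems — pair states (O, I, II) with rates
   x: O→I, y: I→O, w: I→II, z: II→I, and single-copy states (O, +, −) —
   solved analytically by eigendecomposition and fit by maximum likelihood
   to (class, d<sub>S</sub>) observations, with d<sub>S</sub> (synonymous
   substitution rate between paralogs) as the time proxy. Constrained
   variants (one-, two-, four-parameter) are compared by likelihood-ratio
   tests.

`dupdyn.simulate` generates full synthetic cohorts (trees, Markov-evolved
states, pair fates drawn from the analytic kinetics, group feature tables
with known coefficients) so every stage can be validated against recorded
ground truth without any external data.

## Worked example

The numbered drivers in `analysis/` run one synthetic cohort (20 families,
24 expression conditions, 10 binding sites) through every stage, writing
tables under `results/analysis/`:

```sh
cd analysis
python 01_simulate_cohort.py
python 02_infer_ancestral_states.py
python 03_partition_pairs.py
python 04_asymmetry.py
python 05_fit_state_dynamics.py
python 06_retention_model.py
```

Output from one run (seed 20240901):

```
ancestral_calls.tsv: 1825/2400 called (76.0%); median posterior 0.84
402 classified pair x condition items
  class  O: 65.4%
  class  I: 33.6%
  class II: 1.0%
observed mean Y: 0.269
null mean Y:     0.291
O->I vs I->II rate ratio (two-parameter): 26.2
selected features: ['f1', 'f2']
R^2 = 0.771, F = 28.6, p = 3.67e-06
```

Reading this: three quarters of ancestor × condition states were callable
at the consensus thresholds; two thirds of pair-items kept the ancestral
quartile in both copies and a third were partitioned. Because this cohort
evolves *neutrally* (both copies drift independently), observed asymmetry Y
matches the Bernoulli null — the asymmetric regimes are exercised with
known-truth generators in the test suite. The kinetic fit correctly finds
first-copy loss much faster than second-copy loss for this cohort, and
backward elimination recovers exactly the two informative features (true
coefficients 1.5 and −0.8, fitted 1.56 and −0.87) out of 11 candidates.

The same pipeline is scriptable as `dupdyn all --config cfg.yaml --seed N
--out DIR` (or per stage: `dupdyn simulate`, `dupdyn ancestral`, ...).

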