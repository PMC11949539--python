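# Methods

## Problem and model

Given a binary presence/absence sample — one row per sampled unit (a host
colony, a site), one column per target species — the prevalence of a species
is the proportion of units where it is present, reported in percent. The
question the package answers is not "what is the prevalence?" but "was the
sampling effort sufficient to pin it down?", and if so, what is the minimum
number of samples k* that would have sufficed.

The estimator works on the empirical subsampling curve. For every subsample
size k = 1..k_MAX (k_MAX = number of scored units for that group/species
pair), a size-k subset is drawn uniformly without replacement and its
prevalence recorded; averaging over `n_replicates` replicates gives the mean
prevalence curve m(k). Under without-replacement sampling the size-k
proportion follows a hypergeometric law: its expectation equals the observed
proportion at every k (the curve is flat in expectation) and its standard
error is

    SE(k) = 100 * sqrt( p(1-p)/k * (N-k)/(N-1) )   [percentage points]

which decays like 1/sqrt(k) and is driven to zero at k = N by the
finite-population correction. The curve's noise, not its level, carries the
information: k* is the point where the noise has died down.

## Stability criterion

The detector scans windows of `successive_points` (x, default 10)
consecutive means, starting at s = 1, 2, .... A window qualifies iff

1. every within-window successive difference d(k) = |m(k) - m(k-1)|
   satisfies d(k) < y / sqrt(k), where y = `mean_diff_threshold`
   (default 2 percentage points). The sqrt(k) correction matches the
   1/sqrt(k) decay of the sampling noise, so the criterion is equally
   demanding at every k; the index k is the later member of each pair.
2. the window's range Δ = max - min of its x means satisfies
   Δ < z = `delta_threshold` (default 1 percentage point), uncorrected.

All comparisons are strict; ties at a threshold fail. The first qualifying
window wins, and the stability point k* is the index of that window's **last**
mean, k* = s + x - 1: the number of samples one must actually have collected
for the criterion to be verifiable. The estimated prevalence is m(k*); the
tail value m(k_MAX) (= the observed prevalence, exactly) is reported
alongside. If no window qualifies, or the curve is shorter than the window,
the verdict is "na": the effort is insufficient.

Two readings of the window rule are defensible (x means spanning x-1
differences vs x differences spanning x+1 means; sqrt correction indexed by
the later vs earlier member of a pair; k* at the window's start vs end). All
are implemented behind keyword switches on `detect_stability`. The defaults
(x means, later index, window end) were fixed by validation: on the
simulation design below they reproduce the reference behaviour of the
procedure — grid grand mean ≈ 30-31 samples, ≈ 21 at extreme prevalences,
≈ 35-37 at mid prevalences, repeat-run mean ≈ 33-41 — whereas start-of-window
reporting gives systematically smaller values (grand mean ≈ 22).

## Resampling modes

`cumulative` (default): each replicate draws one random permutation of the
units and reads every k off its prefixes. Each m(k) has the exact
hypergeometric marginal, and successive means within a replicate are strongly
correlated (a size-k+1 subsample extends the size-k one), so the averaged
curve is smooth and the windowed criterion is meaningful at realistic k. This
is also the fast mode: one curve costs O(n_replicates · N log N).

`independent`: a fresh subset for every (replicate, k). Identical marginals,
but successive means are independent; their spread at the scales of interest
(≈ 1-2 pp at k ≈ 30-40 with n = 50) exceeds z = 1 until k approaches N, so
stability is only declared near the census and the method's sample-size
recommendations lose their meaning. The mode is retained because it is the
natural null reading of "random sampling without replacement at each k" and
because the contrast is instructive; it is not used by any default.

Randomness: every (group, species) pair gets its own `numpy` child stream,
derived from the base seed and a SHA-256 hash of the pair label, so results
for one pair are invariant to the presence of others. Simulation grids derive
one child stream per cell index the same way.

## Simulation design (the validation harness)

* **Default grid**: population sizes N ∈ {100, 1000, 10000} × true
  prevalences p ∈ {10%..90%, step 10%} × replicate counts
  n ∈ {10..100 step 10, 200, 500}, detector defaults — 324 cells, one run
  each, equal weight in all averages. The synthetic population (exactly
  round(N·p) presences) is handed to the estimator as the dataset, so
  k_MAX = N; there is no separate observation layer. Runs in a few seconds.
* **Parameter sweep**: x ∈ {2, 10, 50} × y ∈ {1, 2, 5, 10} ×
  z ∈ {0.5, 1, 2} on the focal case N = 1000, p = 50%, n = 50 (36 cells).
* **Repeat runs**: the focal case rerun 10 times with independent seeds;
  the mean ± sd of k* quantifies the intrinsic stochasticity (sd ≈ 25% of
  the mean), which is why the CLI defaults to 5 runs and reports a
  rounded-up mean as the conservative recommendation.

Mid-range prevalences need roughly twice the samples of extreme ones because
the variance p(1-p) of the binomial-like draw peaks at p = 0.5; the stability
point distribution is symmetric under p ↔ 1-p.

A handful of grid cells (N = 100, mid prevalence, n ≤ 20 replicates —
typically 1-4 of 324, seed-dependent) legitimately return "na": with that
little averaging the curve never beats Δ < 1 within 100 points. Grid
summaries therefore average over the non-na cells and report the na count.

## Demonstration data

`prevstab.datasets.coral_demo()` is a **synthetic** stand-in for a coral /
coral-dwelling-fauna survey (586 colonies, 6 host groups, 6 symbiont
species, 9 scored pairs). Per-pair sample sizes and presence totals are fixed
by construction; only the row placement of presences and missing cells is
randomised. Sizes and the three *Millepora complanata* prevalences
(21.1%, 19.2%, 23.8%, with unequal scored counts 95/104/101 exercising the
missing-data path) mirror the published survey this layout emulates; the
remaining pairs are plausible inventions. The *Spirobranchus polycerus* /
*Acropora palmata* pair is deliberately mid-prevalence (17/35 ≈ 49%) with
only 35 colonies: since mid prevalences need ≈ 40 samples, its verdict is
"na" in a substantial fraction of runs — the textbook insufficient-effort
case. Because the stand-in is generated, passing tests demonstrate the
machinery, not properties of the real survey; real data additionally carry
spatial structure, observer effects and imperfect detection, none of which
are modelled (presence/absence is taken at face value).

## Numerical choices and edge cases

* Prevalence is always in percent (0-100); y and z are in percentage
  points — the defaults are only sensible on that scale.
* m(k_MAX) equals the observed proportion bit-exactly: mean presence counts
  are accumulated in integers, and the final division reproduces the same
  float expression as the observed proportion.
* Missing cells are dropped per column before resampling, shrinking that
  pair's k_MAX; a pair with no scored entries is skipped (or flagged "no
  data" with `include_empty=True`).
* Display rounding is 1 decimal place, half away from zero; internal values
  are never rounded.
* A single repeat run reports sd = 0 by convention, flagged in the summary.
* Monotonicity guarantees: lengthening the window or tightening y or z can
  only delay (or remove) the stability point, because a qualifying window's
  leading sub-window also qualifies and strict-threshold sets are nested.

## Known limitations

* Perfect detection is assumed; an absent record means absent, not missed.
* No confidence intervals on the prevalence estimate — the method bounds
  sampling effort, not estimator uncertainty.
* The stability point is itself stochastic (sd ≈ 25% of its mean at the
  focal case); single runs should not be trusted, hence the multi-run
  default in the CLI.
* Sample sizes are advisory for the sampled population and moment; prevalence
  varies across sites, depths and seasons, and a verdict does not transfer.
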