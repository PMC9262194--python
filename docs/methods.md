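# Methods

## The background model

A Hi-C library at a fixed bin size is reduced to the sparse set of bin
pairs with at least one supporting read pair (self pairs removed, fragment
ends assigned to the bin containing their midpoint). The observed count of
pair *(i, j)* is modelled as negative binomial with a mean built from three
multiplicative pieces and a shared dispersion:

```
x_ij ~ NB(mu_ij, r)                         Var = mu + mu^2 / r
mu_ij = softmax(v_i * v_j * f(d_ij), base_e)
v_i   = maximum(s_i^b * e^{b_m}, v_base)
f(d)  = softmax(exp(a3 ln(d)^3 + a2 ln(d)^2 + a1 ln(d) + a0), f_c)   (cis)
f     = f_c                                                          (trans)
```

Assumptions worth spelling out:

* **Bin bias is separable and one-dimensional.** Everything that makes a
  bin more or less visible (GC, mappability, restriction-site density,
  capture efficiency) is summarised by one multiplier `v_i`, itself a
  power law in the bin's effective total read count `s_i`. An exponent
  `b < 1` expresses saturation: duplicate removal means a bin's totals grow
  sublinearly in its underlying visibility.
* **Distance decay is smooth in log distance and bottoms out.** The cubic
  in `ln d` can bend twice across the 1 kb–500 kb…10 Mb range; the constant
  `f_c` represents random background ligation, which does not vanish at
  large distance, and is also the trans expectation (distant cis and trans
  pairs show the same background level).
* **Over-dispersion is shared.** One `r` for all pairs of a library (per
  interaction class in capture mode).

The two-argument soft maximum `softmax(a, b) = w a + (1-w) b` with
`w = 1/(1 + e^{-k(a-b)})` replaces the hard maximum wherever the
expectation must stay differentiable. The bias floor (`v_base`) is kept
hard: it enters only through `s_i`, which is fixed within one fitting
round, so no gradient needs to cross it.

### Zero truncation

The triplet store never contains zero-count pairs, so the data presented
to the fitter are draws from the NB *conditioned on* `x >= 1`. At realistic
depths half of all cis pairs are dropped this way, and fitting the
unconditional NB to the survivors is badly inconsistent — the distant-pair
background, the dispersion and the bias exponent all absorb the truncation
(in simulations the fitted dispersion was ~4.5x truth and the fitted
background-ligation level ~20x truth). The likelihood therefore subtracts
`log(1 - P0)` per pair (`P0 = (r/(r+mu))^r`), and P-values are tails of
the same conditional distribution. `TrainingConfig(zero_truncation=False)`
restores the plain unconditional form.

## Fitting

All free parameters — `b, b_m, ln v_base, a0..a3, ln f_c, ln r` — are
fitted jointly by full-batch ADAM (learning rate 1e-2, moments 0.9/0.999,
eps 1e-8) with analytic gradients; positive parameters live on the log
scale. A round stops when every parameter moves less than `tol = 1e-4` in
one iteration, or at 1000 iterations to cap oscillation. An optional
mini-batch mode (`batch_size`) exists for very large maps; the default is
deterministic.

Two reparameterisations matter for a diagonal optimiser and are purely
internal (public parameters are in the plain basis):

* the decay cubic is optimised on the centred/scaled log distance
  `t = (ln d - mean)/sd` — raw powers of `ln d` are nearly collinear over a
  genomic range and stall first-order methods;
* `ln s_i` is centred, decorrelating the bias exponent from its offset.

Initialisation is data-driven: `b = 1`; `b_m` centres the median bias at
1; `v_base` at the 1st percentile of the unfloored biases; the cubic from
an OLS fit of log distance-stratified mean normalised counts; `f_c` from
the trans mean (or the farthest cis decile); `r` by method of moments on
distance strata.

### Rounds and masking

Real loops sit in the data and would inflate any background fitted to all
pairs. Training therefore runs in rounds (default 4): fit on unmasked
pairs; score everything; mask pairs with `p < 0.001` (the mask is rebuilt
from scratch each round, not accumulated); recompute effective bin totals
with masked pairs contributing their model expectation instead of their
observed count. The final model is the last round's parameters together
with the totals it was fitted on.

### P-value convention

The discrete tail can be taken inclusive, `P(X >= x)` (conservative), or
exclusive, `P(X > x)`. The package default is the inclusive tail;
`inclusive_pvalue=False` switches. This choice is visible in null
calibration (below).

## Capture mode

Bait-enriched libraries have three pair classes (TT/TO/OO) with their own
full parameter sets, fitted class-by-class each round against shared bin
totals; `k` and `base_e` stay global. Because a bin's raw total mixes
classes with very different depths, totals are formed from target-target
equivalent counts `x * mu_TT / mu_own` (masked pairs contribute `mu_TT`).
A class with fewer than 1000 pairs is not fitted; it borrows the nearest
fitted class's parameters (TT <-> TO <-> OO), with a warning. With baits
covering every bin the whole construction reduces, exactly and bit for
bit, to the general model.

## The simulator

`simulate_background` draws every cis pair (and all trans pairs when more
than one chromosome is requested) from the model itself: gamma-Poisson
draws of `NB(mu_ij, r)`, zero draws dropped and the dropped fraction
reported, spiked loops redrawn at `fold x mu`, optional bait enrichment
multiplying the expectation per target end.

The one non-obvious design point is the bias field. The bias exponent `b`
relates bias to the map's own marginal totals, so it is only a recoverable
quantity if the generated map satisfies that relation about itself:
`v_i = s_i^b e^{b_m}` with `s_i ≈ Σ_j mu_ij`. The simulator solves this
nonlinear system for the totals (Levenberg–Marquardt on `ln s`; the naive
fixed-point iteration is unstable because bias growth feeds totals feeds
bias). Heterogeneity of the solved totals comes from geometry alone — bins
near chromosome ends reach fewer close neighbours — amplified by the
`1/(1-b)` feedback; at the default fixture this spans roughly a factor of
20 in totals. The residual self-inconsistency is below ~2% in log scale,
concentrated near chromosome ends.

Default truth constants (arbitrary but fixed): `b = 0.8`, `r = 4`,
`f_c = 0.2` reads, `v_base = 0.05`, `k = 10`, `base_e = 0.5` reads, and a
decay cubic interpolated through (10 kb, 60), (20 kb, 30), (200 kb, 3),
(10 Mb, 0.2) reads; `b_m` is calibrated so the median bias is ~1. The
default geometry is one chromosome of 500 x 10 kb bins (~1.25e5 pairs,
~50% dropped as zeros).

What the simulator does *not* emulate: TADs, compartments and other
correlated structure; restriction-fragment granularity; mappability holes;
inter-library variation. Passing the validation suite therefore shows the
estimator is correct *for the model's own data*, not that the model is
adequate for any particular real library.

## Validation experiments

The suite in `hicbg.experiments` (run by both `tests/test_acceptance.py`
and `scripts/acceptance.py`):

* **Closed-form oracles.** NB tail P-values against brute-force pmf
  summation (counts to 200; mu in 0.1/1/10, r in 0.5/2/50); the soft
  maximum against the bound `|softmax - max| <= |a-b| e^{-k|a-b|}`;
  Fisher's exact P against full hypergeometric enumeration for every 2x2
  table with total <= 50.
* **Null calibration.** Background-only map at the default fixture, full
  4-round training, fraction of pairs called at `p < 0.001`. Because the
  counts are small integers the attainable significance levels are a
  coarse grid: with the inclusive tail the called fraction sits at roughly
  0.5–0.7x nominal (conservative); with the exclusive tail at roughly 2x.
  Discreteness, not misestimation: the same fractions computed under the
  generative truth behave identically. Users thresholding raw P-values
  should expect the inclusive default to under-call slightly rather than
  over-call.
* **Parameter recovery.** Ten simulations of 625 x 16 kb bins (195,000
  pairs each, distances 16 kb–10 Mb), single-round fit from default
  initialisation. Median errors across seeds: bias exponent ~0.02–0.03
  absolute, log dispersion ~0.06, decay curve within ~3% (worst point,
  expected-count scale at the median bias — the floor regions and the
  overall scale split between bias and decay are not separately
  identifiable, so curves are compared at the identifiable level). Two
  small biases are intrinsic rather than bugs: masking rounds clip the
  extreme upper tail (raising fitted `r` a few percent on null data), and
  bin totals are sums of the modelled counts themselves, so bias factors
  co-adapt to sampling noise (another few percent on `r`).
* **Spiked-loop detection.** Fifty loops at 10x background on pairs with
  background mean >= 10 reads, full training: ~95% are called at
  `p < 0.001` while non-loop calls stay at the null rate. At weaker sites
  power is counting-limited: a 10x spike on a 1-read background is missed
  ~30% of the time by any method reading the same counts.
* **Capture degeneracy.** All-covering baits reproduce the general model's
  P-values exactly (float-identical), and the TT conversion is the
  identity on TT pairs and linear in the count.

Problem sizes were chosen so the full suite replays in a few minutes on a
single core while keeping every experiment at the scale stated above.

## Known limitations

* Bin totals are response-derived covariates; the resulting co-adaptation
  slightly understates dispersion at small bin counts (see above).
* Discrete tails make threshold calibration convention-dependent; there is
  no mid-P option at present.
* The trans background is a single constant per library (per class in
  capture mode); chromosome-pair-specific trans levels are not modelled.
* No multiple-testing correction is applied to the primary calls (raw
  P-value thresholding); a Benjamini–Hochberg q-value column is emitted
  for users who want it.
* Matrix balancing (ICE/KR) is deliberately not consumed: the model wants
  raw counts, and absorbs visibility through the bias factors.
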