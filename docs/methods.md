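# Methods

## Problem setting

The package addresses sequential experimental design for lead optimisation
of a two-reagent combinatorial library. The search space `S` is a grid of
`N = l_A × l_B` compounds, each identified by a pair of categorical reagent
levels `x = (x₁, x₂)` (50 levels per reagent in the reference setting,
`N = 2500`). Each compound has a scalar activity `y = f(x)` (a pIC50-like
response on roughly [3.40, 8.00]); some cells may have no available
response. The goal is to locate the compound maximising `f` while testing
only a small fraction of the space — 140 unique evaluations by default,
5.6% of the 2500-cell grid.

## The model-guided evolutionary design (EDO)

One "experiment" is a ground-truth lookup on a landscape object standing in
for the laboratory. The design evolves as follows.

**Initial design (generation 1).** Every level of reagent A is paired with
a uniformly random level of B, then every level of B with a random level of
A, redrawing collisions, giving `l_A + l_B` distinct compounds (100 on the
50×50 grid) that cover every level of both reagents at least once. The
two-way coverage matters: the one-hot surrogate has at least one
observation of every level from the first fit onward.

**Surrogate.** A random-forest regressor (500 trees, otherwise the
implementation defaults of scikit-learn) fitted to all scored compounds
tested so far. Both factors are one-hot encoded (100 binary columns at
50+50 levels) — the standard faithful encoding for purely nominal factors;
no ordinal structure is imposed. The forest is seeded, so fit + predict are
deterministic. The surrogate sits behind a minimal `predict(compounds)`
contract, so a ground-truth oracle (or any other model) can be substituted;
the oracle predicts missing cells as `-inf` so they never win an argmax.

**Selection.** Parents are drawn from the *whole* tested pool with
probability proportional to the square of the response,
`πᵢ = yᵢ² / Σⱼ yⱼ²`. The squared law assumes non-negative activities;
negative responses are rejected as an error. The law gives marginal
probabilities, not a sampling scheme; we use sequential weighted draws
without replacement (weights renormalised after each removal) so the 10
parents per generation are distinct.

**Crossover (model-guided).** For each parent, one reagent is fixed
(chosen with probability ½) at the parent's level and all `l` compounds
varying the other reagent are enumerated; already-tested compounds and
candidates already chosen this generation are removed; the surrogate scores
the survivors and the argmax is kept, with prediction ties broken by the
lowest level index (a deterministic tie-break, needed for bit-identical
reruns). If the chosen side is exhausted the other side is tried; if both
are, a uniformly random untested compound is used — this fallback preserves
the never-retest invariant instead of aborting.

**Mutation.** With probability `P = 0.05` one reagent (uniform) has its
level replaced by a uniformly drawn *different* level — a mutation must
change the compound. A mutant colliding with a tested or pending compound
is replaced by a uniform untested compound.

**Loop and stopping.** Each generation adds `min(10, remaining budget,
remaining untested cells)` new compounds (a short generation is flagged as
truncated). The run stops at the known global maximum (benchmark mode,
`stop_at_known_optimum`), at `max_generations` evolution steps (default 5),
or at the unique-evaluation budget (default 140 = 100 + 4×10). In
prospective use the optimum is unknown and the flag is turned off; only the
generation cap and budget stop the run.

**Missing cells.** A designed compound whose response turns out to be
unavailable still consumes budget (a synthesised-but-unmeasurable compound
still costs an experiment), is recorded with a missing response, and is
excluded from surrogate training and from the selection pool.

## The simple-GA benchmark (GAO)

The same evolutionary loop without the surrogate: a 40-compound uniform
random initial population, then 10 generations of 10 offspring, each
produced by recombining two parents (reagent A from one, B from the other,
side uniform), the same squared-response selection, the same mutation
operator, the same no-retest/budget bookkeeping — 40 + 10×10 = 140
evaluations, identical budget accounting to EDO so comparisons are
like-for-like. The 40/10×10 split and textbook operators are this package's
sizing of the "simple GA" foil; they are config-exposed, not claims about
any historical implementation.

## Goodness criteria

* `DGO = 1 − |ŷ_max − y_max| / |y_min − y_max|` — affine in the best found
  response `ŷ_max`; 1 iff the optimum was found. Requires the space's true
  extremes, so it is a benchmark criterion.
* `DGO_α` — the fraction of the top-α *optimal region* tested. The region
  is every non-missing compound with `y ≥ y_α`, `y_α` the `(1−α)` quantile
  of the non-missing response distribution. Quantiles use linear
  interpolation between order statistics (the common statistical default;
  fixed and documented so `DGO_α` is reproducible); region membership is
  `≥` with ties at the threshold all included. Cumulative per-generation
  `DGO_α` values form the enrichment curve (non-decreasing by
  construction).
* Two designs' region coverage is compared with a one-tailed pooled
  two-proportion z-test without continuity correction (the textbook
  default; at equal observed proportions the p-value is exactly 0.5, and
  without continuity correction the test is antisymmetric).
* Frequency tables of responses above a threshold (default 6.0) use fixed,
  half-open bins `[lo, lo + w)`.

## Synthetic benchmark landscapes

The generator emulates the reference library's summary structure, not its
cells:

* latent surface `z(a,b) = w_A·α_a + w_B·β_b + w_AB·γ_ab`, with `α, β`
  i.i.d. standard normal and `γ` non-zero on a 5% random subset of cells;
  defaults `(w_A, w_B, w_AB) = (1, 1, 0.5)` give learnable row/column
  main effects with mild rough interactions, mirroring the banded heatmap
  structure of the empirical set;
* a monotone rank map onto a scaled Beta(2, 2.89) marginal over
  [3.40, 8.00]: mean `2/(2+2.89) ≈ 0.409` of the range, i.e. ≈ 5.28, and
  right skew. Mid-ranks `(r + ½)/N` keep quantiles strictly inside (0, 1);
  monotonicity preserves the latent argmax set;
* the top-ranked `n_global_optima` cells (default 2) are raised to exactly
  `y_max = 8.00`, so the benchmark property "global optimum known exactly"
  holds by construction;
* an exact `round(missing_fraction · N)` count of cells is deleted at
  random, never a global optimum.

What the generator does **not** emulate: the real library's actual SAR
(which reagents are good, the shape of its interactions), assay noise, or
any chemistry. Tests passing on synthetic landscapes show the algorithmic
machinery behaves as specified under landscapes with learnable main-effect
structure; they do not certify performance on any particular real library.
A structureless negative control (`random_landscape`, i.i.d. uniform) is
provided for contrast.

## Numerical and design choices

* All randomness flows from `numpy.random.default_rng(seed)`; a run is a
  pure function of (landscape, config, seed), and reruns are bit-identical.
* Activities are stored at full precision; no rounding on input.
* Optimum detection uses exact float equality with the known maximum —
  sound here because planted optima (and tabulated activities) are exact
  values, not computed quantities.
* The generation cap defaults to 5 evolution steps while the 140-point
  budget already binds after 4 full generations; the cap therefore never
  truncates the default schedule but governs runs with larger budgets.
* `DGO` with `ŷ_max = 7.60` on [3.40, 8.00] evaluates to 0.913; the
  formula is applied literally (no truncation to 0.90).
* Degenerate inputs: an all-equal landscape has an undefined `DGO`
  (rejected) and a full optimal region (returned, not an error); a 1×n grid
  cannot host the two-way-coverage initial design and is rejected.

## Study sizes used by the test suite

The packaged studies run at the reference scale where that is cheap
(50×50 grids, 140-evaluation budgets, 100-replicate sweeps, 10⁵ selection
draws) and on smaller grids for pure bookkeeping properties (200 seeded
runs on 4–9 level grids), sizes chosen to keep the full suite comfortably
reproducible on a laptop. Operator-level properties are scale-free, so
small grids lose no generality.

## Known limitations

* Exactly two categorical factors; no constraints, no multiple objectives.
* The surrogate is fixed to a random forest behind a pluggable contract;
  no model selection or tuning is performed.
* The two-proportion z-test is a normal approximation; with the small
  region sizes at α = 0.01 (25 cells of 2500) it is indicative rather than
  exact, which is also why replicated property checks — not single-run
  p-values — are the package's acceptance basis.
* `DGO` and `DGO_α` require ground truth and are therefore benchmark-only
  diagnostics; prospective runs report only the design record and best
  found compound.
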