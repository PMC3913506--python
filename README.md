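# edopt

Evolutionary model-based design for optimisation of two-reagent
combinatorial chemistry libraries.

## The problem

In lead optimisation a library compound is defined by the choice of one
level for each of two reagents — a categorical grid `S` of
`N = l_A × l_B` molecules (50 × 50 = 2500 in the reference setting), each
with an activity `y = f(x₁, x₂)` (pIC50-like). Synthesising and assaying
the whole grid is wasteful; the design problem is to find the compound
`x* = argmax f` testing as few points as possible.

`edopt` implements a sequential, model-guided evolutionary design (**EDO**)
that locates the optimum within ~140 unique experiments (5.6% of the grid):

1. an initial design of `l_A + l_B` compounds covering every level of both
   reagents;
2. per generation: fit a 500-tree random forest to all tested compounds;
   select 10 parents with probability `πᵢ = yᵢ²/Σⱼyⱼ²`; for each parent fix
   one reagent at random and take the forest-predicted best *untested*
   level of the other; mutate with probability `P = 0.05`; assay the new
   batch;
3. stop at the known optimum (benchmark mode), the generation cap, or the
   140-evaluation budget.

A simple genetic algorithm without the surrogate (**GAO**, 40 + 10×10 = 140
evaluations) is included as the benchmark, plus the design-goodness
criteria used to compare them:

* `DGO = 1 − |ŷ_max − y_max| / |y_min − y_max|` (1 iff the optimum was found),
* `DGO_α` = fraction of the top-α region of the space tested (α = 0.01, 0.05),

with per-generation enrichment curves, one-tailed two-proportion z-tests,
and a seeded synthetic-landscape generator that emulates the reference
MMP-12 library's structure (right-skewed marginal on [3.40, 8.00], mean
≈ 5.28, two cells at the exact maximum 8.00) so every study is fully
reproducible without external data.

## Worked example

```python
import edopt

# a 50x50 benchmark landscape with a known double optimum at 8.00
landscape = edopt.generate_landscape(edopt.SyntheticLandscapeSpec(seed=1))
print(landscape.describe())

result = edopt.EDO(landscape, edopt.EDOConfig(seed=1)).fit()
print(result.summary())
```

prints

```
DescriptiveStats(n_available=2500, y_min=3.4275426191682636, y_max=8.0,
                 mean=5.281537347956633, median=5.2201838435603705,
                 q1=4.550403643362525, q3=5.955514737449174)
EDO run summary
============================================
landscape            synthetic(seed=1)
space size N         2500
unique evaluations   110
generations          2
best compound        (A31, B21)
best response        8.0000  (found at generation 2)
known space maximum  8.0000
DGO                  1.0000
--------------------------------------------
generation sizes     m1=100, m2=10
per-generation best  7.647, 8.000
```

The generated landscape reproduces the reference profile (mean 5.28,
median 5.22, right-skewed, max exactly 8.00). The design tested 110 of
2500 compounds — the 100-point initial design plus one 10-point generation
— and its second generation already contained a global optimum, giving
`DGO = 1.00`. `result.dgo_alpha(0.05)` reports that those 110 compounds
cover 10.4% of the top-5% region; `result.enrichment_curve(0.05)` gives
the per-generation build-up `[0.072, 0.104]`.

The same study from the shell:

```sh
edopt generate --seed 1 --out runs/land
edopt describe --landscape runs/land/landscape.csv
edopt run-edo  --landscape runs/land/landscape.csv --seed 1 --out runs/edo
edopt compare  --landscape runs/land/landscape.csv --seed 1 --out runs/cmp
edopt robustness --landscape runs/land/landscape.csv --replicates 100 \
    --threshold 7.60 --out runs/rob
```

Real data drop in the same way: a long-format CSV with columns
`reagent_a,reagent_b,activity` (empty or `NA` = missing response) loaded
via `edopt.load_landscape(path, l_a=50, l_b=50)`.

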