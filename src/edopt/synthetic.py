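"""Synthetic combinatorial landscapes.

Generates two-reagent response surfaces with the statistical signature of
the MMP-12 inhibitor test library: a 50x50 grid, a right-skewed activity
marginal on [3.40, 8.00] with mean ~5.28, a handful of cells sharing the
exact global maximum, visible row/column (main-effect) structure with
sparse interactions, and optionally missing responses.

The construction is latent-surface + rank map:

1. draw a latent surface ``z(a, b) = w_A a_a + w_B b_b + w_AB g_ab`` with
   i.i.d. standard-normal main effects and a sparse normal interaction;
2. monotonically map the ranks of ``z`` onto a scaled Beta target marginal
   over ``[y_min, y_max]`` (rank transform preserves the argmax set);
3. raise the top-ranked ``n_global_optima`` cells to exactly ``y_max``;
4. delete a fixed fraction of cells at random, never a global optimum.

Because the map is monotone the main-effect structure survives, so a
surrogate model has something real to learn — mirroring the row/column
banding of the empirical heatmap — while the marginal matches the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .landscape import CombinatorialLandscape, CompoundKey

__all__ = ["SyntheticLandscapeSpec", "generate_landscape", "random_landscape", "latent_surface"]

# Beta(2, 2.89): mean 2/(2+2.89) = 0.409 so the scaled mean is
# 3.40 + 4.60 * 0.409 = 5.28, and a < b gives the right skew.
_DEFAULT_SHAPE = (2.0, 2.89)


@dataclass(frozen=True)
class SyntheticLandscapeSpec:
    """Parameters of the synthetic landscape generator.

    ``effect_weights = (w_A, w_B, w_AB)`` weight the reagent-A main
    effects, reagent-B main effects and sparse pairwise interactions in the
    latent surface; ``interaction_density`` is the fraction of cells with a
    non-zero interaction term.
    """

    l_a: int = 50
    l_b: int = 50
    y_min: float = 3.40
    y_max: float = 8.00
    marginal_shape: tuple[float, float] = _DEFAULT_SHAPE
    effect_weights: tuple[float, float, float] = (1.0, 1.0, 0.5)
    interaction_density: float = 0.05
    n_global_optima: int = 2
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l_a < 2 or self.l_b < 2:
            raise ValueError("level counts must be >= 2")
        if not self.y_min < self.y_max:
            raise ValueError("y_min must be < y_max")
        if any(s <= 0 for s in self.marginal_shape):
            raise ValueError("Beta shape parameters must be positive")
        if any(w < 0 for w in self.effect_weights) or not any(self.effect_weights):
            raise ValueError("effect weights must be non-negative and not all zero")
        if not 0.0 <= self.interaction_density <= 1.0:
            raise ValueError("interaction_density must lie in [0, 1]")
        if self.n_global_optima < 1:
            raise ValueError("n_global_optima must be >= 1")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.n_global_optima > self.l_a * self.l_b:
            raise ValueError("more forced optima than grid cells")


def latent_surface(spec: SyntheticLandscapeSpec) -> np.ndarray:
    """The latent ``(l_a, l_b)`` surface before the rank transform.

    Exposed so the additive structure (with ``w_AB = 0`` the difference
    between any two A-rows is constant across B) is directly testable.
    """
    rng = np.random.default_rng(spec.seed)
    w_a, w_b, w_ab = spec.effect_weights
    alpha = rng.standard_normal(spec.l_a)
    beta = rng.standard_normal(spec.l_b)
    mask = rng.random((spec.l_a, spec.l_b)) < spec.interaction_density
    gamma = np.where(mask, rng.standard_normal((spec.l_a, spec.l_b)), 0.0)
    return w_a * alpha[:, None] + w_b * beta[None, :] + w_ab * gamma


def generate_landscape(spec: SyntheticLandscapeSpec) -> CombinatorialLandscape:
    """Generate a landscape from ``spec``; fully reproducible from its seed."""
    z = latent_surface(spec)
    n = z.size
    a_shape, b_shape = spec.marginal_shape

    flat = z.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    # mid-rank plotting positions keep the quantiles strictly inside (0, 1)
    u = (ranks + 0.5) / n
    y = spec.y_min + (spec.y_max - spec.y_min) * stats.beta.ppf(u, a_shape, b_shape)
    y = y.reshape(z.shape)

    # plant the optima: the top-ranked cells share the exact maximum
    top = order[-spec.n_global_optima:]
    optima = {CompoundKey(i // spec.l_b + 1, i % spec.l_b + 1) for i in top}
    for idx in top:
        y[idx // spec.l_b, idx % spec.l_b] = spec.y_max

    responses = {
        CompoundKey(a + 1, b + 1): float(y[a, b])
        for a in range(spec.l_a)
        for b in range(spec.l_b)
    }

    n_missing = int(round(spec.missing_fraction * n))
    if n_missing:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
        candidates = sorted(set(responses) - optima)
        if n_missing > len(candidates):
            raise ValueError("missing_fraction would delete a global optimum")
        drop = rng.choice(len(candidates), size=n_missing, replace=False)
        for i in drop:
            del responses[candidates[i]]

    return CombinatorialLandscape(
        spec.l_a, spec.l_b, responses, name=f"synthetic(seed={spec.seed})"
    )


def random_landscape(l_a: int, l_b: int, seed: int) -> CombinatorialLandscape:
    """Null landscape: i.i.d. uniform responses on [0, 1], no structure.

    A negative control — no surrogate can learn anything exploitable here.
    """
    if l_a < 2 or l_b < 2:
        raise ValueError("level counts must be >= 2")
    rng = np.random.default_rng(seed)
    y = rng.random((l_a, l_b))
    responses = {
        CompoundKey(a + 1, b + 1): float(y[a, b]) for a in range(l_a) for b in range(l_b)
    }
    return CombinatorialLandscape(l_a, l_b, responses, name=f"uniform(seed={seed})")
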