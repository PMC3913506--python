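"""Design-goodness criteria for sequential optimisation designs.

Two complementary criteria judge how well a small experimental design
located the best compounds of a combinatorial space whose ground truth is
known:

* ``DGO = 1 - |yhat_max - y_max| / |y_min - y_max|`` — one minus the
  normalised gap between the best response found and the global best;
  1 exactly when the design hit the optimum, 0 when it only found the
  worst compound.
* ``DGO_alpha`` — the fraction of the top-``alpha`` optimal region of the
  whole space that the design has tested (an enrichment measure at, e.g.,
  alpha = 0.01 and 0.05).

Also provided: per-generation enrichment curves, the one-tailed pooled
two-proportion z-test used to compare two designs' region coverage, and
fixed-width frequency tables of the high responses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .design import EvaluatedDesign, RunResult
from .landscape import CombinatorialLandscape

__all__ = [
    "GoodnessReport",
    "dgo",
    "dgo_alpha",
    "enrichment_curve",
    "one_tailed_two_proportion_test",
    "response_frequency_table",
    "build_goodness_report",
]


def dgo(y_hat_max: float, y_max: float, y_min: float) -> float:
    """Design goodness for optimisation: 1 - |yhat_max - y_max| / |y_min - y_max|.

    Affine and strictly increasing in ``y_hat_max`` over [y_min, y_max];
    equals 1 iff the design found the global maximum.
    """
    if y_max == y_min:
        raise ValueError("degenerate response range: y_max == y_min")
    if not (min(y_min, y_max) <= y_hat_max <= max(y_min, y_max)):
        raise ValueError("y_hat_max must lie between y_min and y_max")
    return 1.0 - abs(y_hat_max - y_max) / abs(y_min - y_max)


def dgo_alpha(
    tested: EvaluatedDesign | Sequence, landscape: CombinatorialLandscape, alpha: float
) -> float:
    """Fraction of the top-``alpha`` optimal region covered by the design.

    Counts tested compounds with response >= y_alpha over the number of
    compounds of the whole space with response >= y_alpha; membership uses
    the landscape's own region, so missing cells can never qualify.
    """
    region = landscape.optimal_region(alpha)
    if not region:
        raise ValueError("empty optimal region")
    if isinstance(tested, EvaluatedDesign):
        keys = tested.keys
    else:
        keys = set(tested)
    return len(keys & region) / len(region)


def enrichment_curve(
    result: RunResult, landscape: CombinatorialLandscape, alpha: float
) -> list[float]:
    """Cumulative DGO_alpha after each generation; non-decreasing."""
    region = landscape.optimal_region(alpha)
    covered: set = set()
    curve: list[float] = []
    records = result.design.records
    for k in range(1, result.design.last_generation + 1):
        covered |= {r.key for r in records if r.generation == k and r.key in region}
        curve.append(len(covered) / len(region))
    return curve


def one_tailed_two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Upper-tail p-value of the pooled two-proportion z-test.

    H0: p1 = p2 against H1: p1 > p2, normal approximation with pooled
    variance and no continuity correction.  With equal observed proportions
    the p-value is exactly 0.5.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:  # both proportions 0 or both 1 -> identical, no evidence
        return 0.5
    z = (p1 - p2) / se
    return float(sps.norm.sf(z))


def response_frequency_table(
    result: RunResult, threshold: float, bin_width: float
) -> dict[tuple[float, float], int]:
    """Counts of evaluated responses above ``threshold`` in fixed-width bins.

    Bins are half-open ``[lo, hi)`` starting at the threshold; the counts
    sum to the number of qualifying evaluations.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = [
        r.activity
        for r in result.design.records
        if r.activity is not None and r.activity > threshold
    ]
    if not values:
        return {}
    n_bins = int(np.floor((max(values) - threshold) / bin_width)) + 1
    table: dict[tuple[float, float], int] = {}
    for i in range(n_bins):
        lo = threshold + i * bin_width
        table[(lo, lo + bin_width)] = 0
    for v in values:
        i = int(np.floor((v - threshold) / bin_width))
        lo = threshold + i * bin_width
        table[(lo, lo + bin_width)] += 1
    return table


@dataclass
class GoodnessReport:
    """Bundle of all goodness criteria for one completed run."""

    method: str
    dgo: float
    dgo_alpha: dict[float, float]
    y_alpha: dict[float, float]
    y_hat_max: float
    y_max: float
    y_min: float
    m: int
    n_space: int
    enrichment_curves: dict[float, list[float]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.dgo <= 1.0:
            raise ValueError("DGO must lie in [0, 1]")
        for a, v in self.dgo_alpha.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"DGO_alpha at alpha={a} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "dgo": self.dgo,
            "dgo_alpha": {str(a): v for a, v in self.dgo_alpha.items()},
            "y_alpha": {str(a): v for a, v in self.y_alpha.items()},
            "y_hat_max": self.y_hat_max,
            "y_max": self.y_max,
            "y_min": self.y_min,
            "m": self.m,
            "n_space": self.n_space,
            "enrichment_curves": {str(a): v for a, v in self.enrichment_curves.items()},
        }

    def to_json(self, path_or_buf=None) -> str | None:
        text = json.dumps(self.to_dict(), indent=2)
        if path_or_buf is None:
            return text
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)
        return None


def build_goodness_report(
    result: RunResult,
    landscape: CombinatorialLandscape,
    alphas: Sequence[float] = (0.01, 0.05),
) -> GoodnessReport:
    """Compute DGO, DGO_alpha and enrichment curves for a completed run."""
    stats = landscape.describe()
    return GoodnessReport(
        method=result.method,
        dgo=dgo(result.best_value, stats.y_max, stats.y_min),
        dgo_alpha={a: dgo_alpha(result.design, landscape, a) for a in alphas},
        y_alpha={a: landscape.y_alpha(a) for a in alphas},
        y_hat_max=result.best_value,
        y_max=stats.y_max,
        y_min=stats.y_min,
        m=result.design.n_unique,
        n_space=landscape.n_cells,
        enrichment_curves={a: enrichment_curve(result, landscape, a) for a in alphas},
    )
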