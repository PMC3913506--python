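"""Surrogate models over two categorical reagent factors.

At each generation of the evolutionary design a regression model is fitted
to every compound tested so far and used to score untested candidates.
The default is a random forest with 500 trees over a one-hot encoding of
both reagent factors (no ordinal structure is imposed on the levels; a
level unseen in training simply contributes an all-zero column block and
still receives a finite prediction).  The contract is a minimal
fit/predict pair so alternative models — including the ground-truth oracle
used in equivalence tests — can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .landscape import CombinatorialLandscape, CompoundKey

__all__ = [
    "SurrogateConfig",
    "Surrogate",
    "RandomForestSurrogate",
    "OracleSurrogate",
    "fit_surrogate",
    "predict_surrogate",
    "oracle_surrogate",
]


@dataclass(frozen=True)
class SurrogateConfig:
    """Random-forest settings: 500 trees with the library's standard
    parameterisation otherwise; ``encoding`` names the categorical scheme
    (only one-hot is implemented)."""

    n_trees: int = 500
    encoding: str = "one-hot"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.encoding != "one-hot":
            raise ValueError(f"unknown encoding {self.encoding!r}")


@runtime_checkable
class Surrogate(Protocol):
    """Fitted-predictor contract used by the design algorithms."""

    def predict(self, compounds: Sequence[CompoundKey]) -> np.ndarray: ...


class RandomForestSurrogate:
    """Random-forest regressor over one-hot encoded reagent levels."""

    def __init__(self, l_a: int, l_b: int, config: SurrogateConfig | None = None) -> None:
        self.l_a = int(l_a)
        self.l_b = int(l_b)
        self.config = config or SurrogateConfig()
        self._forest: RandomForestRegressor | None = None
        self.n_training = 0
        self.levels_seen_a: set[int] = set()
        self.levels_seen_b: set[int] = set()

    def _encode(self, compounds: Sequence[CompoundKey]) -> np.ndarray:
        X = np.zeros((len(compounds), self.l_a + self.l_b))
        for i, key in enumerate(compounds):
            a, b = key
            if not (1 <= a <= self.l_a and 1 <= b <= self.l_b):
                raise ValueError(f"compound {tuple(key)} outside the grid")
            X[i, a - 1] = 1.0
            X[i, self.l_a + b - 1] = 1.0
        return X

    def fit(self, design: Sequence[CompoundKey], responses: Sequence[float]) -> "RandomForestSurrogate":
        if len(design) != len(responses):
            raise ValueError("design and responses must have equal length")
        if len(design) < 2:
            raise ValueError("need at least 2 training points")
        y = np.asarray(responses, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("training responses must be finite (no missing values)")
        X = self._encode(list(design))
        self._forest = RandomForestRegressor(
            n_estimators=self.config.n_trees, random_state=self.config.seed
        ).fit(X, y)
        self.n_training = len(design)
        self.levels_seen_a = {k.reagent_a for k in map(CompoundKey._make, design)}
        self.levels_seen_b = {k.reagent_b for k in map(CompoundKey._make, design)}
        return self

    def predict(self, compounds: Sequence[CompoundKey]) -> np.ndarray:
        if self._forest is None:
            raise ValueError("surrogate is not fitted")
        compounds = list(compounds)
        if not compounds:
            return np.empty(0)
        return self._forest.predict(self._encode(compounds))


class OracleSurrogate:
    """Test double that predicts the ground truth.

    Missing cells get ``-inf`` so they can never win an argmax; everything
    else is the landscape's true response.
    """

    def __init__(self, landscape: CombinatorialLandscape) -> None:
        self.landscape = landscape

    def predict(self, compounds: Sequence[CompoundKey]) -> np.ndarray:
        out = np.empty(len(compounds))
        for i, key in enumerate(compounds):
            value = self.landscape.evaluate(key)
            out[i] = -np.inf if value is None else value
        return out


def fit_surrogate(
    design: Sequence[CompoundKey],
    responses: Sequence[float],
    config: SurrogateConfig,
    l_a: int,
    l_b: int,
) -> RandomForestSurrogate:
    """Fit the default random-forest surrogate; deterministic given the
    config seed."""
    return RandomForestSurrogate(l_a, l_b, config).fit(design, responses)


def predict_surrogate(model: Surrogate, compounds: Sequence[CompoundKey]) -> np.ndarray:
    """One finite prediction per compound, order-preserving."""
    return model.predict(list(compounds))


def oracle_surrogate(landscape: CombinatorialLandscape) -> OracleSurrogate:
    return OracleSurrogate(landscape)
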