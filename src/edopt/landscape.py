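"""Two-reagent combinatorial landscapes.

A landscape is the full experimental space of a two-reagent combinatorial
library: every compound is identified by a pair of categorical reagent
levels ``(a, b)`` with ``1 <= a <= l_A`` and ``1 <= b <= l_B``, and carries a
scalar activity (a pIC50-like response) that may be missing for compounds
that were never successfully assayed.  The landscape plays the role of the
laboratory for benchmark runs: evaluating a compound is a deterministic
lookup of its ground-truth response.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundKey",
    "DescriptiveStats",
    "CombinatorialLandscape",
    "load_landscape",
]


class CompoundKey(NamedTuple):
    """One experimental point: a pair of 1-based categorical reagent levels."""

    reagent_a: int
    reagent_b: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"(A{self.reagent_a}, B{self.reagent_b})"


@dataclass(frozen=True)
class DescriptiveStats:
    """Summary of the non-missing response distribution of a landscape."""

    n_available: int
    y_min: float
    y_max: float
    mean: float
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.y_min <= self.q1 <= self.median <= self.q3 <= self.y_max):
            raise ValueError("quartiles must be ordered: min <= q1 <= median <= q3 <= max")


class CombinatorialLandscape:
    """The search space ``S`` with its response surface ``f``.

    Parameters
    ----------
    l_a, l_b
        Number of categorical levels of reagent A and reagent B; the space
        holds ``N = l_a * l_b`` cells.
    responses
        Mapping from :class:`CompoundKey` to finite activity values.  Cells
        absent from the mapping are *missing*: they exist in the grid but
        have no available response (never encoded as a sentinel number).
    name
        Free-text label carried through exports.
    a_labels, b_labels
        Optional external level labels (e.g. ``"A21"``); position ``i``
        labels level ``i + 1``.  Defaults to ``A1..A{l_a}`` / ``B1..B{l_b}``.
    """

    def __init__(
        self,
        l_a: int,
        l_b: int,
        responses: Mapping[CompoundKey, float],
        name: str = "",
        a_labels: Sequence[str] | None = None,
        b_labels: Sequence[str] | None = None,
    ) -> None:
        if l_a < 1 or l_b < 1:
            raise ValueError("level counts must be >= 1")
        self.l_a = int(l_a)
        self.l_b = int(l_b)
        self.name = name
        self._responses: dict[CompoundKey, float] = {}
        for key, value in responses.items():
            key = CompoundKey(*key)
            self._check_key(key)
            if key in self._responses:
                raise ValueError(f"duplicate cell {key}")
            value = float(value)
            if not np.isfinite(value):
                raise ValueError(f"non-finite response {value!r} at cell {key}")
            self._responses[key] = value
        if len(self._responses) > self.n_cells:
            raise ValueError("more responses than grid cells")
        self.a_labels = list(a_labels) if a_labels is not None else [f"A{i}" for i in range(1, l_a + 1)]
        self.b_labels = list(b_labels) if b_labels is not None else [f"B{i}" for i in range(1, l_b + 1)]
        if len(self.a_labels) != self.l_a or len(self.b_labels) != self.l_b:
            raise ValueError("label lists must match the declared level counts")

    # -- basic queries ----------------------------------------------------

    @property
    def n_cells(self) -> int:
        """Size ``N`` of the whole experimental space."""
        return self.l_a * self.l_b

    @property
    def n_available(self) -> int:
        """Number of cells with a non-missing response."""
        return len(self._responses)

    @property
    def responses(self) -> Mapping[CompoundKey, float]:
        return dict(self._responses)

    def _check_key(self, key: CompoundKey) -> None:
        if not (1 <= key.reagent_a <= self.l_a and 1 <= key.reagent_b <= self.l_b):
            raise ValueError(
                f"compound {tuple(key)} outside the {self.l_a}x{self.l_b} grid"
            )

    def all_keys(self) -> Iterator[CompoundKey]:
        """Every cell of the grid, missing or not, in row-major order."""
        for a in range(1, self.l_a + 1):
            for b in range(1, self.l_b + 1):
                yield CompoundKey(a, b)

    def available_keys(self) -> list[CompoundKey]:
        return list(self._responses)

    def evaluate(self, compound: CompoundKey) -> float | None:
        """Ground-truth response of ``compound``; ``None`` when missing."""
        compound = CompoundKey(*compound)
        self._check_key(compound)
        return self._responses.get(compound)

    def is_missing(self, compound: CompoundKey) -> bool:
        compound = CompoundKey(*compound)
        self._check_key(compound)
        return compound not in self._responses

    def response_values(self) -> np.ndarray:
        """Non-missing responses as an array (insertion order)."""
        return np.fromiter(self._responses.values(), dtype=float, count=len(self._responses))

    # -- statistics -------------------------------------------------------

    def describe(self) -> DescriptiveStats:
        """Descriptive statistics over the non-missing responses."""
        y = self.response_values()
        if y.size == 0:
            raise ValueError("all responses are missing")
        q1, med, q3 = np.quantile(y, [0.25, 0.5, 0.75])
        return DescriptiveStats(
            n_available=int(y.size),
            y_min=float(y.min()),
            y_max=float(y.max()),
            mean=float(y.mean()),
            median=float(med),
            q1=float(q1),
            q3=float(q3),
        )

    def y_alpha(self, alpha: float) -> float:
        """Activity threshold at the upper ``alpha`` tail: the (1 - alpha)
        quantile of the non-missing response distribution (linear
        interpolation between order statistics)."""
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        y = self.response_values()
        if y.size == 0:
            raise ValueError("all responses are missing")
        return float(np.quantile(y, 1.0 - alpha))

    def optimal_region(self, alpha: float) -> set[CompoundKey]:
        """All non-missing compounds with response >= the alpha threshold.

        Ties at the threshold are all included; with all responses equal the
        region is the whole available space.
        """
        threshold = self.y_alpha(alpha)
        return {k for k, v in self._responses.items() if v >= threshold}

    def global_optimum(self) -> tuple[set[CompoundKey], float]:
        """Every argmax cell together with the maximum response."""
        if not self._responses:
            raise ValueError("all responses are missing")
        y_max = max(self._responses.values())
        return {k for k, v in self._responses.items() if v == y_max}, y_max

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per grid cell (missing cells get
        NA activity), using the external level labels."""
        rows = []
        for key in self.all_keys():
            rows.append(
                (
                    self.a_labels[key.reagent_a - 1],
                    self.b_labels[key.reagent_b - 1],
                    self._responses.get(key, np.nan),
                )
            )
        return pd.DataFrame(rows, columns=["reagent_a", "reagent_b", "activity"])

    def to_csv(self, path_or_buf) -> None:
        """Write the long-format CSV (`reagent_a,reagent_b,activity`)."""
        self.to_frame().to_csv(path_or_buf, index=False)

    def to_matrix(self) -> pd.DataFrame:
        """Wide-format ``l_a x l_b`` matrix (rows = A levels, columns = B
        levels, NaN = missing) for heatmap-style inspection."""
        mat = np.full((self.l_a, self.l_b), np.nan)
        for key, value in self._responses.items():
            mat[key.reagent_a - 1, key.reagent_b - 1] = value
        return pd.DataFrame(mat, index=self.a_labels, columns=self.b_labels)

    def to_matrix_csv(self, path_or_buf) -> None:
        self.to_matrix().to_csv(path_or_buf)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CombinatorialLandscape(l_a={self.l_a}, l_b={self.l_b}, "
            f"available={self.n_available}/{self.n_cells}, name={self.name!r})"
        )


def load_landscape(
    source,
    l_a: int,
    l_b: int,
    name: str = "",
) -> CombinatorialLandscape:
    """Read a landscape from long-format CSV.

    The stream must carry columns ``reagent_a, reagent_b, activity``; an
    empty field or ``NA`` marks a missing response.  Level labels are mapped
    to 1-based indices in sorted label order, and the mapping is retained on
    the returned landscape (``a_labels`` / ``b_labels``).

    Raises
    ------
    ValueError
        On duplicate cells, more distinct labels than the declared counts,
        or a non-numeric activity other than the missing marker.
    """
    if isinstance(source, (str, bytes)) and "\n" in str(source):
        source = io.StringIO(str(source))
    df = pd.read_csv(source, na_values=["NA"], keep_default_na=True)
    required = {"reagent_a", "reagent_b", "activity"}
    if not required.issubset(df.columns):
        raise ValueError(f"input must have columns {sorted(required)}")
    try:
        activity = pd.to_numeric(df["activity"])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric activity value: {exc}") from exc

    a_labels = sorted(df["reagent_a"].astype(str).unique())
    b_labels = sorted(df["reagent_b"].astype(str).unique())
    if len(a_labels) > l_a:
        raise ValueError(f"{len(a_labels)} reagent-A labels exceed declared l_a={l_a}")
    if len(b_labels) > l_b:
        raise ValueError(f"{len(b_labels)} reagent-B labels exceed declared l_b={l_b}")
    # pad to the declared counts so the grid shape is what the caller stated
    a_labels += [f"A_unused{i}" for i in range(len(a_labels) + 1, l_a + 1)]
    b_labels += [f"B_unused{i}" for i in range(len(b_labels) + 1, l_b + 1)]
    a_index = {lab: i + 1 for i, lab in enumerate(a_labels)}
    b_index = {lab: i + 1 for i, lab in enumerate(b_labels)}

    responses: dict[CompoundKey, float] = {}
    seen: set[CompoundKey] = set()
    for (a_raw, b_raw), y in zip(
        zip(df["reagent_a"].astype(str), df["reagent_b"].astype(str)), activity
    ):
        key = CompoundKey(a_index[a_raw], b_index[b_raw])
        if key in seen:
            raise ValueError(f"duplicate cell ({a_raw}, {b_raw})")
        seen.add(key)
        if pd.notna(y):
            responses[key] = float(y)
    return CombinatorialLandscape(
        l_a, l_b, responses, name=name, a_labels=a_labels, b_labels=b_labels
    )
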