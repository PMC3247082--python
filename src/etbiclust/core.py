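"""Domain types and the range-coherence engine.

A *bicluster* here is the constant-row kind: a set of genes whose expression
values are nearly equal within each supporting experimental condition
(transaction).  Coherence of one transaction is judged by the relative
*range* of the values, ``(max - min) / min``, computed on absolute values of
a strictly same-sign retained set.  Robustness to noise comes from an error
budget: up to ``max_errors`` extreme values may be discarded before the
range test is applied.  The strength of a pattern is its *RangeSupport*:
the sum over supporting transactions of the minimum absolute retained value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InvalidInputError",
    "MiningParams",
    "SupportDecision",
    "ExpressionMatrix",
    "Bicluster",
    "error_budget",
    "error_splits",
    "check_transaction",
    "count_errors",
]

#: absolute slack used in floating-point threshold comparisons
_FLOAT_TOL = 1e-9


class InvalidInputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


def error_budget(k: int, epsilon: float) -> int:
    """Number of permissible errors per transaction for a k-gene bicluster.

    The budget is ``floor(k * epsilon)``; a tiny additive slack absorbs
    binary floating-point representation of epsilon (e.g. k=3, eps=0.1).
    """
    if k < 1:
        raise InvalidInputError(f"bicluster level must be >= 1, got {k}")
    return int(math.floor(k * epsilon + _FLOAT_TOL))


def error_splits(e: int) -> list[tuple[int, int]]:
    """All ways to spend ``e`` discards on the two extremes of a sorted list.

    Returns (i, j) pairs: discard the i smallest and j largest values,
    i + j = e.  For e=2 these are the three cases: two minima, one of each,
    two maxima.
    """
    if e < 0:
        raise InvalidInputError(f"error count must be >= 0, got {e}")
    return [(e - j, j) for j in range(e + 1)]


@dataclass(frozen=True)
class MiningParams:
    """User-facing mining thresholds.

    Parameters
    ----------
    alpha : float
        Relative-range threshold; a transaction's retained values must
        satisfy ``(max|v| - min|v|) / min|v| <= alpha``.  Non-negative,
        dimensionless.
    epsilon : float
        Error tolerance in ``[0, 1)``: the maximum fraction of a
        transaction's values that may be discarded as errors.  ``0`` is the
        exact (RAP) mode.
    rs_threshold : float
        Minimum RangeSupport a pattern must accumulate to be reported.
        Positive, on the scale of the expression values.
    """

    alpha: float
    epsilon: float = 0.0
    rs_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha >= 0):
            raise InvalidInputError(f"alpha must be >= 0, got {self.alpha}")
        if not (0 <= self.epsilon < 1):
            raise InvalidInputError(
                f"epsilon must lie in [0, 1), got {self.epsilon}"
            )
        if not (self.rs_threshold > 0):
            raise InvalidInputError(
                f"rs_threshold must be > 0, got {self.rs_threshold}"
            )

    def error_budget(self, k: int) -> int:
        return error_budget(k, self.epsilon)


@dataclass(frozen=True)
class SupportDecision:
    """Outcome of checking one transaction against one gene set.

    ``retained`` and ``discarded`` partition the evaluated positions
    (indices into the value list handed to :func:`check_transaction`).
    ``contribution`` is the minimum absolute retained value when
    ``supports`` is true, else 0.
    """

    supports: bool
    retained: tuple[int, ...]
    discarded: tuple[int, ...]
    contribution: float

    def __post_init__(self) -> None:
        if set(self.retained) & set(self.discarded):
            raise InvalidInputError("retained and discarded overlap")
        if self.supports and not self.retained:
            raise InvalidInputError("a supporting decision must retain values")


def _coherent(vals: Sequence[float], alpha: float) -> float | None:
    """Return min |v| if ``vals`` is same-sign and range-coherent, else None.

    Zeros have no strict sign and therefore can never be retained.
    """
    if all(v > 0 for v in vals) or all(v < 0 for v in vals):
        avs = [abs(v) for v in vals]
        mn, mx = min(avs), max(avs)
        if (mx - mn) / mn <= alpha * (1 + _FLOAT_TOL) + _FLOAT_TOL:
            return mn
    return None


def check_transaction(
    values: Sequence[float], alpha: float, max_errors: int
) -> SupportDecision:
    """Decide whether one transaction supports a gene set under an error budget.

    The values are sorted (by signed value); for e = 0 .. ``max_errors`` and
    every split e = i + j, the i smallest and j largest values are discarded
    and the retained set must (a) be strictly same-sign and (b) have relative
    range of absolute values at most ``alpha``.  Errors live only at the
    extremes of the sorted order — interior values are never discardable.

    The first passing configuration at the smallest e wins; among passing
    splits at that e, the one maximizing the contribution (ties: fewer
    discards from the maximum end).
    """
    vals = [float(v) for v in values]
    n = len(vals)
    if n == 0:
        raise InvalidInputError("cannot check an empty value list")
    if not (0 <= max_errors < n):
        raise InvalidInputError(
            f"max_errors must lie in [0, {n - 1}] for {n} values, "
            f"got {max_errors}"
        )
    order = sorted(range(n), key=lambda i: (vals[i], i))
    for e in range(max_errors + 1):
        best: tuple[float, tuple[int, int]] | None = None
        for j in range(e + 1):  # j discards from the max end
            i = e - j
            kept = order[i: n - j]
            contrib = _coherent([vals[p] for p in kept], alpha)
            if contrib is not None and (best is None or contrib > best[0]):
                best = (contrib, (i, j))
        if best is not None:
            contrib, (i, j) = best
            kept = tuple(sorted(order[i: n - j]))
            dropped = tuple(sorted(order[:i] + order[n - j: n]))
            return SupportDecision(True, kept, dropped, contrib)
    return SupportDecision(False, (), tuple(range(n)), 0.0)


def count_errors(values: Sequence[float], alpha: float) -> int:
    """Minimum number of extreme discards making the rest coherent.

    Returns ``len(values)`` when no non-empty retained set passes (e.g. an
    all-zero transaction).
    """
    vals = [float(v) for v in values]
    n = len(vals)
    if n == 0:
        raise InvalidInputError("cannot count errors of an empty value list")
    decision = check_transaction(vals, alpha, n - 1)
    return len(decision.discarded) if decision.supports else n


@dataclass(frozen=True)
class ExpressionMatrix:
    """A real-valued genes x conditions expression matrix.

    Gene and condition identifiers are unique labels; every cell holds a
    finite real number.
    """

    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(
            self, "condition_ids", tuple(str(c) for c in self.condition_ids)
        )
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2:
            raise InvalidInputError("values must be a 2-D array")
        if vals.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise InvalidInputError(
                f"shape {vals.shape} does not match {len(self.gene_ids)} genes "
                f"x {len(self.condition_ids)} conditions"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidInputError("duplicate gene identifiers")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise InvalidInputError("duplicate condition identifiers")
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise InvalidInputError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"condition {self.condition_ids[bad[1]]!r}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def condition_index(self) -> dict[str, int]:
        return {c: j for j, c in enumerate(self.condition_ids)}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(str(g) for g in df.index),
            condition_ids=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=list(self.gene_ids),
            columns=list(self.condition_ids),
        )


@dataclass(frozen=True)
class Bicluster:
    """A mined error-tolerant bicluster.

    ``genes`` follow the matrix row order; ``transactions`` the matrix column
    order.  ``per_transaction`` maps each supporting condition label to the
    :class:`SupportDecision` whose positions index into ``genes``.
    ``range_support`` equals the sum of the per-transaction contributions.
    """

    genes: tuple[str, ...]
    transactions: tuple[str, ...]
    range_support: float
    per_transaction: Mapping[str, SupportDecision] = field(repr=False)
    level: int = 0

    def __post_init__(self) -> None:
        if self.level == 0:
            object.__setattr__(self, "level", len(self.genes))
        if set(self.transactions) != set(self.per_transaction):
            raise InvalidInputError(
                "transactions and per_transaction keys disagree"
            )

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def errors_of(self, transaction: str) -> tuple[str, ...]:
        """Gene identifiers of the discarded (error) values in a transaction."""
        d = self.per_transaction[transaction]
        return tuple(self.genes[i] for i in d.discarded)

    def sort_key(self) -> tuple[int, tuple[str, ...]]:
        return (self.level, tuple(sorted(self.genes)))
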