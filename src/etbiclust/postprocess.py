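"""Redundancy-aware selection of top biclusters.

Association-style miners emit many overlapping patterns; downstream
evaluation uses a greedy, size-ordered selection with an overlap cap, the
common practice for comparing bicluster collections.  Size is the number of
genes only (error-tolerant patterns tend to carry large condition sets, so
|genes| x |conditions| would let near-duplicates through).  Ties in size are
broken by the Cheng–Church mean squared residue, computed on retained
(non-error) cells only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Bicluster, ExpressionMatrix, InvalidInputError

__all__ = ["SelectionParams", "mean_squared_residue", "select_top"]


@dataclass(frozen=True)
class SelectionParams:
    """Greedy-selection knobs: at most ``max_selected`` biclusters, pairwise
    gene overlap at most ``max_overlap`` (fraction of the smaller set)."""

    max_selected: int = 500
    max_overlap: float = 0.25

    def __post_init__(self) -> None:
        if self.max_selected < 1:
            raise InvalidInputError("max_selected must be positive")
        if not (0 <= self.max_overlap <= 1):
            raise InvalidInputError("max_overlap must lie in [0, 1]")


def mean_squared_residue(
    bicluster: Bicluster, matrix: ExpressionMatrix
) -> float:
    """Cheng–Church mean squared residue over the retained cells.

    H = mean over retained (i, j) of (a_ij - a_iJ - a_Ij + a_IJ)^2, with the
    row, column and overall means taken over retained cells only; discarded
    (error) cells are excluded throughout.  A single-cell bicluster scores 0.
    """
    gi = matrix.gene_index()
    ci = matrix.condition_index()
    g_idx = [gi[g] for g in bicluster.genes]
    c_idx = [ci[c] for c in bicluster.transactions]
    sub = matrix.values[np.ix_(g_idx, c_idx)]
    mask = np.zeros(sub.shape, dtype=bool)
    for j, cond in enumerate(bicluster.transactions):
        for i in bicluster.per_transaction[cond].retained:
            mask[i, j] = True
    n_ret = int(mask.sum())
    if n_ret == 0:
        raise InvalidInputError("bicluster has no retained cells")
    if n_ret == 1:
        return 0.0
    am = np.ma.array(sub, mask=~mask)
    residue = (
        am
        - am.mean(axis=1, keepdims=True)
        - am.mean(axis=0, keepdims=True)
        + am.mean()
    )
    return float((residue ** 2).mean())


def _overlap(a: frozenset[str], b: frozenset[str]) -> float:
    """|A ∩ B| / min(|A|, |B|): symmetric, strictest common overlap measure;
    stops a large pattern from absorbing a smaller near-subset."""
    return len(a & b) / min(len(a), len(b))


def select_top(
    biclusters: Sequence[Bicluster],
    matrix: ExpressionMatrix,
    params: SelectionParams = SelectionParams(),
    include_singletons: bool = False,
) -> list[Bicluster]:
    """Greedy top-bicluster selection.

    Candidates are sorted by gene count (descending), then mean squared
    residue (ascending), then lexicographic gene set for determinism; a
    candidate is accepted when its gene overlap with every already-selected
    bicluster is at most ``params.max_overlap``.  Single-gene patterns are
    skipped unless ``include_singletons``.
    """
    pool = [
        b for b in biclusters if include_singletons or b.level >= 2
    ]
    mse_cache: dict[tuple, float] = {}

    def mse(b: Bicluster) -> float:
        # key on genes+transactions: merged runs may share gene sets
        k = (b.gene_set, frozenset(b.transactions))
        if k not in mse_cache:
            mse_cache[k] = mean_squared_residue(b, matrix)
        return mse_cache[k]

    pool.sort(key=lambda b: (-len(b.genes), mse(b), tuple(sorted(b.genes))))
    selected: list[Bicluster] = []
    for b in pool:
        if len(selected) >= params.max_selected:
            break
        if all(
            _overlap(b.gene_set, s.gene_set) <= params.max_overlap
            for s in selected
        ):
            selected.append(b)
    return selected
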