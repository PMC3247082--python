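"""Level-wise bottom-up mining of error-tolerant biclusters.

Starting from singleton genes, (k+1)-gene candidates are generated from
k-gene patterns by prefix joins under the matrix row order, pruned
Apriori-style (every k-subset must itself be a valid pattern).  The
per-transaction error budget at level k is ``floor(k * epsilon)``.  When the
budget grows from level k to k+1 (an *error step*), candidate transactions
are the union of the subsets' supporting-transaction sets; when it stays
constant (a *non-error step*), their intersection.  Each candidate
transaction is re-checked from scratch with the new budget, and a candidate
is kept when its RangeSupport reaches the threshold.

With ``epsilon = 0`` both the range and RangeSupport measures are
anti-monotone, so the search is exhaustive (the RAP mode).  For
``epsilon > 0`` the range measure loses anti-monotonicity and the level-wise
procedure is a heuristic: it subsumes the exact output but does not
enumerate every error-tolerant pattern.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .core import (
    Bicluster,
    ExpressionMatrix,
    InvalidInputError,
    MiningParams,
    SupportDecision,
    check_transaction,
)

__all__ = ["mine", "merge_runs", "ETBiclusterMiner"]

logger = logging.getLogger(__name__)

_RS_TOL = 1e-9  # slack on the RangeSupport threshold comparison


def _level_one(matrix: ExpressionMatrix, params: MiningParams
               ) -> dict[tuple[int, ...], Bicluster]:
    """Valid singletons: RangeSupport = sum of absolute values over all
    transactions; zero cells never support (a zero has no sign)."""
    out: dict[tuple[int, ...], Bicluster] = {}
    for gi, gene in enumerate(matrix.gene_ids):
        decisions: dict[str, SupportDecision] = {}
        rs = 0.0
        for cj, cond in enumerate(matrix.condition_ids):
            v = float(matrix.values[gi, cj])
            if v != 0.0:
                decisions[cond] = SupportDecision(True, (0,), (), abs(v))
                rs += abs(v)
        if rs >= params.rs_threshold - _RS_TOL and decisions:
            out[(gi,)] = Bicluster(
                genes=(gene,),
                transactions=tuple(
                    c for c in matrix.condition_ids if c in decisions
                ),
                range_support=rs,
                per_transaction=decisions,
                level=1,
            )
    return out


def _join_candidates(keys: Sequence[tuple[int, ...]]) -> Iterable[tuple[int, ...]]:
    """Prefix join: two sorted k-tuples sharing their first k-1 entries."""
    keys = sorted(keys)
    for a_idx, a in enumerate(keys):
        for b in keys[a_idx + 1:]:
            if a[:-1] != b[:-1]:
                break  # sorted order: once prefixes diverge they stay diverged
            yield a + (b[-1],)


def mine(
    matrix: ExpressionMatrix,
    params: MiningParams,
    max_candidates_per_level: int | None = None,
) -> list[Bicluster]:
    """Run the level-wise miner and return all valid biclusters, all levels.

    Output is ordered by level, then lexicographically by gene set.  No
    closed/maximal filtering is applied; redundancy is handled downstream by
    top-bicluster selection.

    ``max_candidates_per_level`` is an optional guardrail: when set, levels
    with more joined candidates are truncated (with a logged warning) to
    keep desk-scale runs bounded.  Off by default.
    """
    if not isinstance(matrix, ExpressionMatrix):
        raise InvalidInputError("matrix must be an ExpressionMatrix")
    if not isinstance(params, MiningParams):
        raise InvalidInputError("params must be a MiningParams")

    cond_order = matrix.condition_index()
    levels: list[dict[tuple[int, ...], Bicluster]] = []
    current = _level_one(matrix, params)
    levels.append(current)
    logger.info("level 1: %d valid singletons", len(current))

    k = 1
    while current:
        k += 1
        budget = params.error_budget(k)
        error_step = budget > params.error_budget(k - 1)
        candidates = list(_join_candidates(list(current)))
        if max_candidates_per_level is not None and \
                len(candidates) > max_candidates_per_level:
            logger.warning(
                "level %d: truncating %d candidates to %d",
                k, len(candidates), max_candidates_per_level,
            )
            candidates = candidates[:max_candidates_per_level]
        nxt: dict[tuple[int, ...], Bicluster] = {}
        n_checked = 0
        for cand in candidates:
            subs = list(combinations(cand, k - 1))
            if any(s not in current for s in subs):
                continue  # Apriori pruning
            n_checked += 1
            tsets = [set(current[s].transactions) for s in subs]
            cand_ts = set.union(*tsets) if error_step else set.intersection(*tsets)
            decisions: dict[str, SupportDecision] = {}
            rs = 0.0
            for cond in cand_ts:
                cj = cond_order[cond]
                vals = [float(matrix.values[gi, cj]) for gi in cand]
                d = check_transaction(vals, params.alpha, budget)
                if d.supports:
                    decisions[cond] = d
                    rs += d.contribution
            if rs >= params.rs_threshold - _RS_TOL and decisions:
                nxt[cand] = Bicluster(
                    genes=tuple(matrix.gene_ids[gi] for gi in cand),
                    transactions=tuple(
                        sorted(decisions, key=cond_order.__getitem__)
                    ),
                    range_support=rs,
                    per_transaction=decisions,
                    level=k,
                )
        logger.info(
            "level %d (%s step, budget %d): %d candidates, %d survived pruning,"
            " %d valid",
            k, "error" if error_step else "non-error", budget,
            len(candidates), n_checked, len(nxt),
        )
        levels.append(nxt)
        current = nxt

    out = [b for lvl in levels for b in lvl.values()]
    out.sort(key=Bicluster.sort_key)
    return out


def merge_runs(
    exact: Sequence[Bicluster], tolerant: Sequence[Bicluster]
) -> list[Bicluster]:
    """Union of an exact (epsilon=0) and an error-tolerant run.

    Keyed by gene set; when the same gene set appears in both, the variant
    with the larger supporting-transaction set wins (tie: larger
    RangeSupport).  Both runs must come from the same matrix.
    """
    merged: dict[frozenset[str], Bicluster] = {}
    for b in list(exact) + list(tolerant):
        key = b.gene_set
        old = merged.get(key)
        if old is None:
            merged[key] = b
        elif (len(b.transactions), b.range_support) > (
            len(old.transactions), old.range_support
        ):
            merged[key] = b
    out = list(merged.values())
    out.sort(key=Bicluster.sort_key)
    return out


class ETBiclusterMiner(BaseEstimator):
    """Error-tolerant constant-row bicluster miner.

    scikit-learn-style estimator: construct with the mining thresholds, call
    :meth:`fit` on a genes x conditions matrix, then read the fitted
    attributes.

    Parameters
    ----------
    alpha : float, default 0.5
        Relative-range coherence threshold per transaction.
    epsilon : float, default 0.25
        Error tolerance in [0, 1); fraction of a transaction's values that
        may be discarded as errors.  0 gives the exact (RAP) miner.
    rs_threshold : float, default 5.0
        Minimum RangeSupport of a reported pattern.
    max_candidates_per_level : int or None, default None
        Optional cap on joined candidates per level (guardrail for large
        inputs); off by default.

    Attributes
    ----------
    biclusters_ : list of Bicluster
        All valid patterns, every level, ordered by level then gene set.
    rows_ : ndarray of bool, shape (n_biclusters, n_genes)
        Gene membership of each bicluster (matrix row order).
    columns_ : ndarray of bool, shape (n_biclusters, n_conditions)
        Supporting-transaction membership of each bicluster.
    n_biclusters_ : int
    matrix_ : ExpressionMatrix
        The validated input the patterns refer to.

    Examples
    --------
    >>> from etbiclust import ETBiclusterMiner, worked_example_fixture
    >>> m = ETBiclusterMiner(alpha=0.5, epsilon=0.25, rs_threshold=5.0)
    >>> m.fit(worked_example_fixture())
    ETBiclusterMiner()
    >>> sorted(b.genes for b in m.biclusters_ if b.level == 5)
    [('a', 'b', 'c', 'd', 'e')]
    """

    def __init__(
        self,
        alpha: float = 0.5,
        epsilon: float = 0.25,
        rs_threshold: float = 5.0,
        max_candidates_per_level: int | None = None,
    ):
        self.alpha = alpha
        self.epsilon = epsilon
        self.rs_threshold = rs_threshold
        self.max_candidates_per_level = max_candidates_per_level

    # -- helpers -----------------------------------------------------------
    def _as_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        try:
            import pandas as pd
            if isinstance(X, pd.DataFrame):
                return ExpressionMatrix.from_dataframe(X)
        except ImportError:  # pragma: no cover
            pass
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise InvalidInputError("X must be a 2-D genes x conditions array")
        return ExpressionMatrix(
            gene_ids=tuple(f"g{i}" for i in range(arr.shape[0])),
            condition_ids=tuple(f"c{j}" for j in range(arr.shape[1])),
            values=arr,
        )

    def _params(self) -> MiningParams:
        return MiningParams(
            alpha=self.alpha,
            epsilon=self.epsilon,
            rs_threshold=self.rs_threshold,
        )

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None) -> "ETBiclusterMiner":
        """Mine all error-tolerant biclusters from X (genes x conditions)."""
        matrix = self._as_matrix(X)
        params = self._params()  # validates thresholds
        found = mine(matrix, params, self.max_candidates_per_level)

        gi = matrix.gene_index()
        ci = matrix.condition_index()
        rows = np.zeros((len(found), matrix.n_genes), dtype=bool)
        cols = np.zeros((len(found), matrix.n_conditions), dtype=bool)
        for b_idx, b in enumerate(found):
            rows[b_idx, [gi[g] for g in b.genes]] = True
            cols[b_idx, [ci[c] for c in b.transactions]] = True

        self.matrix_ = matrix
        self.biclusters_ = found
        self.rows_ = rows
        self.columns_ = cols
        self.n_biclusters_ = len(found)
        return self

    def get_bicluster(self, genes: Iterable[str]) -> Bicluster | None:
        """Fitted pattern with exactly this gene set, or None."""
        if not hasattr(self, "biclusters_"):
            raise InvalidInputError("call fit before get_bicluster")
        want = frozenset(genes)
        for b in self.biclusters_:
            if b.gene_set == want:
                return b
        return None
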