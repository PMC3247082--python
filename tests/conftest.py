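"""Shared fixtures: the walk-through matrix, random matrices, an
independent brute-force miner used as the exact-mode oracle, and a small
gene-set collection."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from etbiclust import (
    ExpressionMatrix,
    GeneSetCollection,
    worked_example_fixture,
)


@pytest.fixture(scope="session")
def fixture_matrix() -> ExpressionMatrix:
    return worked_example_fixture()


def random_matrix(rng: np.random.Generator, n_genes: int,
                  n_conditions: int) -> ExpressionMatrix:
    """Uniform [-2, 2] values with a sprinkling of exact zeros."""
    vals = rng.uniform(-2, 2, size=(n_genes, n_conditions))
    vals[rng.random(vals.shape) < 0.05] = 0.0
    return ExpressionMatrix(
        gene_ids=tuple(f"g{i}" for i in range(n_genes)),
        condition_ids=tuple(f"c{j}" for j in range(n_conditions)),
        values=vals,
    )


def brute_force_exact(matrix: ExpressionMatrix, alpha: float,
                      rs_threshold: float) -> dict[frozenset, tuple]:
    """Independent exact-mode oracle: every gene subset, checked directly
    against the definition (no discards, strict same sign, relative range of
    absolute values <= alpha; RangeSupport = sum of per-transaction minimum
    absolute values).  Returns gene set -> (support set, RangeSupport)."""
    out: dict[frozenset, tuple] = {}
    n = matrix.n_genes
    for r in range(1, n + 1):
        for subset in combinations(range(n), r):
            rs = 0.0
            supp = []
            for j, cond in enumerate(matrix.condition_ids):
                vals = matrix.values[list(subset), j]
                if not ((vals > 0).all() or (vals < 0).all()):
                    continue
                avs = np.abs(vals)
                if (avs.max() - avs.min()) / avs.min() <= alpha:
                    supp.append(cond)
                    rs += float(avs.min())
            if supp and rs >= rs_threshold - 1e-9:
                key = frozenset(matrix.gene_ids[i] for i in subset)
                out[key] = (frozenset(supp), rs)
    return out


@pytest.fixture()
def toy_collection() -> GeneSetCollection:
    return GeneSetCollection.from_sets(
        {
            "setA": ["g1", "g2", "g3"],
            "setB": ["g3", "g4", "g5", "g6"],
            "setC": ["g7", "g8"],
        },
        universe=[f"g{i}" for i in range(1, 11)],
    )
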