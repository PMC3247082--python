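"""Evaluation of mined biclusters.

Four pieces, mirroring how bicluster collections are judged in practice:

* hypergeometric gene-set enrichment of each bicluster against a GMT-style
  collection (upper-tail p, no multiple-testing correction — the p-values
  serve only to *compare* collections, not to call individual hits);
* summary fractions over a p-value threshold sweep;
* discriminative (case/control) biomarker filtering by odds ratio and a
  two-sided Fisher exact test;
* two randomization significance tests: size-matched random gene sets with
  an empirical exceedance p-value, and per-gene shuffling of the expression
  matrix (preserves every gene's value distribution, destroys inter-gene
  correlation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact, hypergeom

from .core import Bicluster, ExpressionMatrix, InvalidInputError

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "PhenotypeLabels",
    "BiomarkerRecord",
    "hypergeom_pvalue",
    "enrich",
    "enrichment_summary",
    "discriminative_filter",
    "randomization_gene_sets",
    "RandomizationResult",
    "randomization_shuffle_data",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the annotation universe.

    The universe defaults to the union of all sets; when supplied
    explicitly, member sets are restricted to it.
    """

    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, Iterable[str]],
        universe: Iterable[str] | None = None,
    ) -> "GeneSetCollection":
        frozen = {name: frozenset(g) for name, g in sets.items()}
        if universe is None:
            uni = frozenset().union(*frozen.values()) if frozen else frozenset()
        else:
            uni = frozenset(universe)
            frozen = {name: g & uni for name, g in frozen.items()}
        return cls(sets=frozen, universe=uni)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes <= self.universe:
                raise InvalidInputError(
                    f"gene set {name!r} is not contained in the universe"
                )


@dataclass(frozen=True)
class EnrichmentRecord:
    """One (bicluster, term) enrichment test.

    ``score`` is the per-bicluster enrichment score, -log10 of the minimum
    p-value over all terms for that bicluster (identical on every record of
    a bicluster).
    """

    bicluster_id: str
    term_name: str
    overlap_count: int
    p_value: float
    score: float


@dataclass(frozen=True)
class PhenotypeLabels:
    """condition -> 'case' | 'control' map for biomarker mode."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {"case", "control"}
        if bad:
            raise InvalidInputError(f"labels must be case/control, got {bad}")

    @property
    def cases(self) -> frozenset[str]:
        return frozenset(c for c, v in self.labels.items() if v == "case")

    @property
    def controls(self) -> frozenset[str]:
        return frozenset(c for c, v in self.labels.items() if v == "control")


@dataclass(frozen=True)
class BiomarkerRecord:
    """Discriminative-bicluster statistics on the 2x2 case/control table
    (a = cases supporting, b = cases not, c = controls supporting,
    d = controls not)."""

    bicluster_id: str
    table: tuple[int, int, int, int]
    odds_ratio: float
    p_value: float


def hypergeom_pvalue(
    bicluster_genes: Iterable[str],
    term_genes: Iterable[str],
    universe: Iterable[str],
) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Drawing n = |bicluster ∩ universe| genes without replacement from N
    universe genes of which K = |term| are annotated, the p-value is the
    probability of seeing at least the observed overlap k.  A bicluster with
    no gene in the universe scores p = 1 (logged).
    """
    uni = frozenset(universe)
    term = frozenset(term_genes) & uni
    bic = frozenset(bicluster_genes) & uni
    N, K, n = len(uni), len(term), len(bic)
    if n == 0:
        logger.info("bicluster has no genes in the universe; p = 1")
        return 1.0
    k = len(bic & term)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def _bicluster_id(b: Bicluster) -> str:
    return "|".join(sorted(b.genes))


def enrich(
    biclusters: Sequence[Bicluster],
    collection: GeneSetCollection,
) -> list[EnrichmentRecord]:
    """Hypergeometric test of every (bicluster, term) pair.

    No multiple-testing correction is applied.
    """
    records: list[EnrichmentRecord] = []
    for b in biclusters:
        bid = _bicluster_id(b)
        bic = b.gene_set & collection.universe
        pairs = []
        for name, term in sorted(collection.sets.items()):
            p = hypergeom_pvalue(bic, term, collection.universe)
            pairs.append((name, len(bic & term), p))
        pmin = min((p for _, _, p in pairs), default=1.0)
        score = -math.log10(pmin) if pmin > 0 else math.inf
        records.extend(
            EnrichmentRecord(bid, name, k, p, score)
            for name, k, p in pairs
        )
    return records


def enrichment_summary(
    records: Sequence[EnrichmentRecord],
    thresholds: Sequence[float],
) -> dict[float, dict[str, float]]:
    """Per-threshold fractions: biclusters enriched by >= 1 term, and terms
    enriching >= 1 bicluster."""
    by_bic: dict[str, float] = {}
    by_term: dict[str, float] = {}
    for r in records:
        by_bic[r.bicluster_id] = min(
            by_bic.get(r.bicluster_id, 1.0), r.p_value
        )
        by_term[r.term_name] = min(by_term.get(r.term_name, 1.0), r.p_value)
    out: dict[float, dict[str, float]] = {}
    for tau in thresholds:
        out[tau] = {
            "fraction_biclusters_enriched": (
                sum(p <= tau for p in by_bic.values()) / len(by_bic)
                if by_bic else 0.0
            ),
            "fraction_terms_enriching": (
                sum(p <= tau for p in by_term.values()) / len(by_term)
                if by_term else 0.0
            ),
        }
    return out


def discriminative_filter(
    biclusters: Sequence[Bicluster],
    labels: PhenotypeLabels,
    p_threshold: float = 0.05,
    or_low: float = 0.5,
    or_high: float = 2.0,
) -> list[BiomarkerRecord]:
    """Keep biclusters discriminating cases from controls.

    A condition "supports" a bicluster when it is one of its supporting
    transactions.  The 2x2 table is tested with a two-sided Fisher exact
    test; the odds ratio uses the Haldane–Anscombe +0.5 correction on all
    cells whenever any cell is zero.  Retained: p < ``p_threshold`` and
    OR > ``or_high`` or OR < ``or_low``.
    """
    cases, controls = labels.cases, labels.controls
    out: list[BiomarkerRecord] = []
    for b in biclusters:
        supp = set(b.transactions)
        missing = supp - set(labels.labels)
        if missing:
            raise InvalidInputError(
                f"supporting transactions without labels: {sorted(missing)}"
            )
        a = len(supp & cases)
        bb = len(cases) - a
        c = len(supp & controls)
        d = len(controls) - c
        if min(a, bb, c, d) == 0:
            a_, b_, c_, d_ = (x + 0.5 for x in (a, bb, c, d))
        else:
            a_, b_, c_, d_ = float(a), float(bb), float(c), float(d)
        odds = (a_ * d_) / (b_ * c_)
        p = float(fisher_exact([[a, bb], [c, d]], alternative="two-sided")[1])
        if p < p_threshold and (odds > or_high or odds < or_low):
            out.append(
                BiomarkerRecord(_bicluster_id(b), (a, bb, c, d), odds, p)
            )
    return out


@dataclass(frozen=True)
class RandomizationResult:
    """Outcome of the size-matched random-gene-set test.

    ``per_bicluster`` rows: (bicluster_id, actual_score, exceed_count,
    empirical_p); an exceed_count of 0 means the empirical p is below
    1/reps and is reported as such by :meth:`format_empirical_p`.
    ``summary`` maps each p-value threshold to (actual_fraction,
    n_random_runs_exceeding_actual_fraction).
    """

    reps: int
    per_bicluster: tuple[tuple[str, float, int, float], ...]
    summary: Mapping[float, tuple[float, int]] = field(default_factory=dict)

    def format_empirical_p(self, exceed_count: int) -> str:
        if exceed_count == 0:
            return f"< {1 / self.reps:g}"
        return f"{exceed_count / self.reps:g}"


def randomization_gene_sets(
    selected: Sequence[Bicluster],
    gene_sets: GeneSetCollection,
    reps: int = 1000,
    seed: int = 0,
    thresholds: Sequence[float] = (0.05, 0.01, 0.005, 0.001, 0.00001),
) -> RandomizationResult:
    """Size-matched random-gene-set significance test.

    For each selected bicluster of gene size s, ``reps`` uniform random
    s-subsets of the universe are drawn; the empirical p-value is the
    fraction of random sets whose enrichment score strictly exceeds the
    actual one (ties favour the actual bicluster).  The summary additionally
    reports, per threshold, how many of the ``reps`` random bicluster
    collections have a larger enriched fraction than the actual collection.
    Bit-for-bit reproducible given the seed.
    """
    if reps < 1:
        raise InvalidInputError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    universe = sorted(gene_sets.universe)
    N = len(universe)
    gene_pos = {g: i for i, g in enumerate(universe)}
    names = sorted(gene_sets.sets)
    # term membership matrix over the universe (terms x genes)
    M = np.zeros((len(names), N), dtype=bool)
    for t, name in enumerate(names):
        M[t, [gene_pos[g] for g in gene_sets.sets[name]]] = True
    K = M.sum(axis=1)

    def min_p(idx: np.ndarray) -> float:
        n = len(idx)
        if n == 0 or len(names) == 0:
            return 1.0
        k = M[:, idx].sum(axis=1)
        p = hypergeom.sf(k - 1, N, K, n)
        return float(np.min(p))

    def score(pmin: float) -> float:
        return -math.log10(pmin) if pmin > 0 else math.inf

    per: list[tuple[str, float, int, float]] = []
    # random-run p-value matrix: reps x biclusters (min p per random set)
    rand_p = np.ones((reps, len(selected)))
    actual_p = np.ones(len(selected))
    for b_idx, b in enumerate(selected):
        bic = sorted(b.gene_set & gene_sets.universe)
        s = len(b.gene_set)
        if s > N:
            raise InvalidInputError(
                f"bicluster size {s} exceeds universe size {N}"
            )
        actual = min_p(np.array([gene_pos[g] for g in bic], dtype=int))
        actual_p[b_idx] = actual
        actual_score = score(actual)
        exceed = 0
        for r in range(reps):
            pr = min_p(rng.choice(N, size=s, replace=False))
            rand_p[r, b_idx] = pr
            if score(pr) > actual_score:
                exceed += 1
        per.append((_bicluster_id(b), actual_score, exceed, exceed / reps))

    summary: dict[float, tuple[float, int]] = {}
    n_b = max(len(selected), 1)
    for tau in thresholds:
        actual_frac = float((actual_p <= tau).sum()) / n_b
        rand_frac = (rand_p <= tau).sum(axis=1) / n_b
        summary[tau] = (actual_frac, int((rand_frac > actual_frac).sum()))
    return RandomizationResult(
        reps=reps, per_bicluster=tuple(per), summary=summary
    )


def randomization_shuffle_data(
    matrix: ExpressionMatrix, seed: int = 0
) -> ExpressionMatrix:
    """Shuffle each gene's values independently across conditions.

    Preserves every gene's value multiset exactly while destroying the
    correlation structure between genes; mining the result estimates the
    background pattern yield of the data.
    """
    rng = np.random.default_rng(seed)
    shuffled = matrix.values.copy()
    for i in range(shuffled.shape[0]):
        rng.shuffle(shuffled[i])
    return ExpressionMatrix(
        gene_ids=matrix.gene_ids,
        condition_ids=matrix.condition_ids,
        values=shuffled,
    )
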