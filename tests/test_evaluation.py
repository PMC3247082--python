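"""Enrichment statistics, biomarker filtering and randomization tests."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import fisher_exact

from etbiclust import (
    Bicluster,
    ExpressionMatrix,
    GeneSetCollection,
    InvalidInputError,
    PhenotypeLabels,
    SupportDecision,
    discriminative_filter,
    enrich,
    enrichment_summary,
    hypergeom_pvalue,
    randomization_gene_sets,
    randomization_shuffle_data,
)


def make_bicluster(genes, transactions=("c1",)):
    per = {t: SupportDecision(True, (0,), (), 1.0) for t in transactions}
    return Bicluster(tuple(genes), tuple(transactions), 1.0, per, len(genes))


class TestHypergeomPvalue:
    def test_all_draws_annotated_closed_form(self):
        # N=20, K=5, n=5, k=5 -> p = 1 / C(20,5) = 1/15504
        universe = [f"g{i}" for i in range(20)]
        term = universe[:5]
        p = hypergeom_pvalue(term, term, universe)
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_term_equal_to_universe_gives_one(self):
        universe = [f"g{i}" for i in range(10)]
        assert hypergeom_pvalue(universe[:3], universe, universe) == \
            pytest.approx(1.0)

    def test_zero_overlap_gives_one(self):
        universe = [f"g{i}" for i in range(10)]
        p = hypergeom_pvalue(universe[:3], universe[5:8], universe)
        assert p == pytest.approx(1.0)

    def test_empty_intersection_with_universe_gives_one(self):
        assert hypergeom_pvalue(["x"], ["g1"], ["g1", "g2"]) == 1.0

    def test_upper_tail_matches_enumeration(self):
        # independent oracle: sum point probabilities of the hypergeometric
        # support directly
        N, K, n = 12, 4, 5
        universe = [f"g{i}" for i in range(N)]
        term = universe[:K]
        for k in range(0, min(K, n) + 1):
            bic = universe[:k] + universe[K:K + (n - k)]
            total = sum(
                math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
                for x in range(k, min(K, n) + 1)
            )
            assert hypergeom_pvalue(bic, term, universe) == \
                pytest.approx(total, rel=1e-9)

    def test_monotone_in_overlap(self):
        N, K, n = 15, 6, 6
        universe = [f"g{i}" for i in range(N)]
        term = universe[:K]
        ps = []
        for k in range(0, n + 1):
            bic = universe[:k] + universe[K:K + (n - k)]
            ps.append(hypergeom_pvalue(bic, term, universe))
        assert ps == sorted(ps, reverse=True)

    def test_point_masses_sum_to_one(self):
        N, K, n = 10, 3, 4
        total = sum(
            math.comb(K, x) * math.comb(N - K, n - x)
            for x in range(0, min(K, n) + 1)
        )
        assert total == math.comb(N, n)


class TestEnrichmentSummary:
    def test_single_pair_fractions(self, toy_collection):
        b = make_bicluster(("g1", "g2", "g3"))
        records = enrich([b], toy_collection)
        pmin = min(r.p_value for r in records)
        # exact match of setA in a 10-gene universe: p = 1/C(10,3)
        assert pmin == pytest.approx(1 / math.comb(10, 3))
        summary = enrichment_summary(records, [0.01, 0.001])
        assert summary[0.01]["fraction_biclusters_enriched"] == 1.0
        assert summary[0.001]["fraction_biclusters_enriched"] == 0.0

    def test_fractions_match_direct_counting(self, toy_collection):
        rng = np.random.default_rng(4)
        universe = sorted(toy_collection.universe)
        bics = [
            make_bicluster(rng.choice(universe, size=3, replace=False))
            for _ in range(10)
        ]
        records = enrich(bics, toy_collection)
        taus = [0.05, 0.2, 0.5, 1.0]
        summary = enrichment_summary(records, taus)
        pmin_by_bic = {}
        pmin_by_term = {}
        for r in records:
            pmin_by_bic[r.bicluster_id] = min(
                pmin_by_bic.get(r.bicluster_id, 1.0), r.p_value)
            pmin_by_term[r.term_name] = min(
                pmin_by_term.get(r.term_name, 1.0), r.p_value)
        for tau in taus:
            assert summary[tau]["fraction_biclusters_enriched"] == \
                pytest.approx(np.mean([p <= tau
                                       for p in pmin_by_bic.values()]))
            assert summary[tau]["fraction_terms_enriching"] == \
                pytest.approx(np.mean([p <= tau
                                       for p in pmin_by_term.values()]))

    def test_score_is_minus_log10_of_min_p(self, toy_collection):
        b = make_bicluster(("g1", "g2", "g3"))
        records = enrich([b], toy_collection)
        pmin = min(r.p_value for r in records)
        assert records[0].score == pytest.approx(-math.log10(pmin))


class TestDiscriminativeFilter:
    def _labels(self, n_case, n_control):
        labels = {f"case{i}": "case" for i in range(n_case)}
        labels.update({f"ctrl{i}": "control" for i in range(n_control)})
        return PhenotypeLabels(labels)

    def test_odds_ratio_formula(self):
        # a=30, b=128, c=20, d=413 -> OR = (30*413)/(128*20) ~ 4.84
        labels = self._labels(158, 433)
        supp = tuple(f"case{i}" for i in range(30)) + tuple(
            f"ctrl{i}" for i in range(20))
        b = make_bicluster(("gA", "gB"), supp)
        records = discriminative_filter([b], labels)
        assert len(records) == 1
        rec = records[0]
        assert rec.table == (30, 128, 20, 413)
        assert rec.odds_ratio == pytest.approx(30 * 413 / (128 * 20))
        assert rec.p_value == pytest.approx(
            fisher_exact([[30, 128], [20, 413]])[1])
        assert rec.p_value < 0.05

    def test_equal_proportions_never_retained(self):
        labels = self._labels(10, 10)
        supp = tuple(f"case{i}" for i in range(5)) + tuple(
            f"ctrl{i}" for i in range(5))
        assert discriminative_filter([make_bicluster("XY", supp)],
                                     labels) == []

    def test_zero_cell_correction_keeps_or_finite(self):
        labels = self._labels(10, 10)
        supp = tuple(f"ctrl{i}" for i in range(8))  # a = 0
        b = make_bicluster("XY", supp)
        records = discriminative_filter([b], labels, p_threshold=0.05)
        if records:  # retained only if Fisher p permits
            assert math.isfinite(records[0].odds_ratio)
            assert records[0].odds_ratio == pytest.approx(
                (0.5 * 2.5) / (10.5 * 8.5))

    def test_thresholds_enforced_on_output(self):
        rng = np.random.default_rng(9)
        labels = self._labels(50, 50)
        conds = sorted(labels.labels)
        bics = []
        for _ in range(30):
            supp = tuple(rng.choice(conds, size=rng.integers(5, 40),
                                    replace=False))
            bics.append(make_bicluster(("gA", "gB"), supp))
        for rec in discriminative_filter(bics, labels):
            assert rec.p_value < 0.05
            assert rec.odds_ratio > 2.0 or rec.odds_ratio < 0.5

    def test_missing_label_rejected(self):
        labels = self._labels(2, 2)
        b = make_bicluster("XY", ("case0", "mystery"))
        with pytest.raises(InvalidInputError):
            discriminative_filter([b], labels)

    def test_label_values_validated(self):
        with pytest.raises(InvalidInputError):
            PhenotypeLabels({"c1": "patient"})


class TestRandomizationGeneSets:
    def test_empirical_p_is_exceedance_fraction(self, toy_collection):
        b = make_bicluster(("g1", "g2", "g3"))  # exactly setA: near-minimal p
        result = randomization_gene_sets([b], toy_collection, reps=200,
                                         seed=42)
        (_, score, exceed, emp_p), = result.per_bicluster
        assert emp_p == exceed / 200
        assert exceed == 0  # no random triple beats the exact match
        assert result.format_empirical_p(exceed) == "< 0.005"
        assert result.format_empirical_p(1) == "0.005"

    def test_reproducible_given_seed(self, toy_collection):
        b = make_bicluster(("g1", "g4", "g7"))
        r1 = randomization_gene_sets([b], toy_collection, reps=100, seed=7)
        r2 = randomization_gene_sets([b], toy_collection, reps=100, seed=7)
        assert r1 == r2

    def test_summary_counts_runs_exceeding_actual_fraction(self,
                                                           toy_collection):
        bics = [make_bicluster(("g1", "g2", "g3")),
                make_bicluster(("g7", "g8"))]
        result = randomization_gene_sets(bics, toy_collection, reps=50,
                                         seed=1, thresholds=(0.05, 1.0))
        frac_1, n_1 = result.summary[1.0]
        assert frac_1 == 1.0  # every p-value is <= 1
        assert n_1 == 0       # no random fraction can strictly exceed 1
        frac, n = result.summary[0.05]
        assert 0 <= frac <= 1 and 0 <= n <= 50

    def test_random_actual_set_has_roughly_uniform_empirical_p(
            self, toy_collection):
        # an unremarkable "actual" set should not look significant
        rng = np.random.default_rng(3)
        universe = sorted(toy_collection.universe)
        ps = []
        for s in range(30):
            genes = rng.choice(universe, size=3, replace=False)
            r = randomization_gene_sets([make_bicluster(genes)],
                                        toy_collection, reps=40, seed=s)
            ps.append(r.per_bicluster[0][3])
        assert np.mean(ps) > 0.15  # far from uniformly significant

    def test_oversized_bicluster_rejected(self, toy_collection):
        big = make_bicluster(tuple(f"x{i}" for i in range(50)))
        with pytest.raises(InvalidInputError):
            randomization_gene_sets([big], toy_collection, reps=10, seed=0)


class TestShuffleData:
    def _matrix(self, seed=0, shape=(6, 20)):
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(
            tuple(f"g{i}" for i in range(shape[0])),
            tuple(f"c{j}" for j in range(shape[1])),
            rng.uniform(-2, 2, size=shape),
        )

    def test_row_multisets_preserved(self):
        m = self._matrix()
        sh = randomization_shuffle_data(m, seed=5)
        assert np.allclose(np.sort(sh.values, axis=1),
                           np.sort(m.values, axis=1))
        assert sh.gene_ids == m.gene_ids

    def test_reproducible_and_seed_sensitive(self):
        m = self._matrix()
        a = randomization_shuffle_data(m, seed=5)
        b = randomization_shuffle_data(m, seed=5)
        c = randomization_shuffle_data(m, seed=6)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_breaks_correlation_between_identical_rows(self):
        rng = np.random.default_rng(2)
        row = rng.uniform(1, 2, size=200)
        m = ExpressionMatrix(("a", "b"), tuple(f"c{j}" for j in range(200)),
                             np.vstack([row, row]))
        corrs = []
        for s in range(30):
            sh = randomization_shuffle_data(m, seed=s)
            corrs.append(np.corrcoef(sh.values)[0, 1])
        assert abs(np.mean(corrs)) < 0.1
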