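"""Query construction, KS running-sum ES and connectivity scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemoconnect import (
    ConnectivityRecord,
    DegRecord,
    GeneUniverse,
    PrototypeRankedList,
    QuerySignature,
    Ranking,
    ValidationError,
    build_query,
    connectivity_score,
    ks_running_sum,
    rank_compounds,
)
from chemoconnect.connectivity import ks_running_sum_from_positions

from .conftest import es_prefix_oracle


def universe_of(n):
    return GeneUniverse(tuple(f"g{i:03d}" for i in range(n)))


class TestBuildQuery:
    @pytest.fixture
    def universe(self):
        return universe_of(40)

    def deg(self, gene, log2fc, padj):
        return DegRecord(gene_id=gene, log2fc=log2fc, pvalue=padj / 2, padj=padj)

    def table(self, universe):
        genes = universe.genes
        rows = [self.deg(genes[i], +2.0, 0.04) for i in range(6)]
        rows += [self.deg(genes[i], -1.0, 0.01) for i in range(6, 12)]
        rows += [self.deg(genes[i], +2.0, 0.06) for i in range(12, 16)]  # above FDR
        rows += [self.deg(genes[i], 0.0, 0.001) for i in range(16, 18)]  # zero lfc
        return rows

    def test_threshold_and_sign_rules(self, universe):
        q = build_query(self.table(universe), universe, 0.05)
        assert q.up == frozenset(universe.genes[:6])
        assert q.down == frozenset(universe.genes[6:12])
        assert q.n_dropped_unmapped == 0

    def test_unmapped_genes_counted(self, universe):
        rows = self.table(universe) + [self.deg("not_a_gene", 3.0, 0.001)]
        q = build_query(rows, universe, 0.05)
        assert q.n_dropped_unmapped == 1
        assert "not_a_gene" not in q.up

    def test_sparse_direction_fails_with_counts(self, universe):
        rows = [self.deg(universe.genes[i], +2.0, 0.01) for i in range(8)]
        rows += [self.deg(universe.genes[8], -2.0, 0.01)]
        with pytest.raises(ValidationError, match="'down' has 1 mapped genes"):
            build_query(rows, universe, 0.05)

    def test_duplicate_gene_rows_rejected(self, universe):
        rows = self.table(universe) + [self.deg(universe.genes[0], 1.0, 0.2)]
        with pytest.raises(ValidationError, match="duplicate gene_id"):
            build_query(rows, universe, 0.05)

    def test_up_down_disjointness_enforced(self):
        with pytest.raises(ValidationError, match="overlap"):
            QuerySignature(up=frozenset({"a", "b"}), down=frozenset({"b", "c"}))


class TestKsRunningSum:
    def test_perfect_head_and_tail(self):
        ranking = [f"x{i}" for i in range(10)]
        assert ks_running_sum({"x0", "x1"}, ranking) == pytest.approx(1.0)
        assert ks_running_sum({"x8", "x9"}, ranking) == pytest.approx(-1.0)

    def test_earliest_extreme_wins_ties(self):
        # hits at positions 1 and 4 of 4: running sums +.5, 0, -.5, 0
        assert ks_running_sum({"a", "d"}, ["a", "b", "c", "d"]) == pytest.approx(0.5)

    def test_empty_and_full_hit_sets_rejected(self):
        with pytest.raises(ValidationError):
            ks_running_sum(set(), ["a", "b"])
        with pytest.raises(ValidationError):
            ks_running_sum({"a", "b"}, ["a", "b"])

    def test_matches_prefix_oracle_on_random_instances(self):
        rng = np.random.default_rng(101)
        for _ in range(1000):
            n = int(rng.integers(2, 51))
            k = int(rng.integers(1, n))
            ranking = [f"e{i}" for i in rng.permutation(n)]
            hits = set(rng.choice(ranking, size=k, replace=False).tolist())
            assert ks_running_sum(hits, ranking) == es_prefix_oracle(hits, ranking)

    def test_unit_magnitude_iff_contiguous_extreme_block(self):
        """|ES| = 1 exactly when the hits fill the head (ES=+1) or tail (-1)."""
        for n in range(2, 9):
            ranking = [f"e{i}" for i in range(n)]
            for k in range(1, n):
                for subset in itertools.combinations(range(n), k):
                    es = ks_running_sum({ranking[i] for i in subset}, ranking)
                    head = subset == tuple(range(k))
                    tail = subset == tuple(range(n - k, n))
                    if head:
                        assert es == pytest.approx(1.0)
                    elif tail:
                        assert es == pytest.approx(-1.0)
                    else:
                        assert abs(es) < 1.0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.data())
    def test_oracle_property_on_arbitrary_instances(self, data):
        """Hypothesis-drawn (set, ranking) instances agree with the oracle."""
        n = data.draw(st.integers(2, 30))
        perm = data.draw(st.permutations(range(n)))
        k = data.draw(st.integers(1, n - 1))
        hit_idx = data.draw(
            st.sets(st.integers(0, n - 1), min_size=k, max_size=k)
        )
        ranking = [f"e{i}" for i in perm]
        hits = {f"e{i}" for i in hit_idx}
        assert ks_running_sum(hits, ranking) == es_prefix_oracle(hits, ranking)

    def test_label_invariance(self):
        rng = np.random.default_rng(5)
        n, k = 30, 7
        pos = np.sort(rng.choice(n, size=k, replace=False))
        base = ks_running_sum_from_positions(pos, n)
        for labels in (
            [f"a{i}" for i in range(n)],
            [f"zz{i:04d}" for i in range(n)],
        ):
            hits = {labels[i] for i in pos}
            assert ks_running_sum(hits, labels) == base


def prl_from_order(universe, ordered_genes, cid="c1"):
    return PrototypeRankedList(
        compound_id=cid,
        ranking=Ranking.from_ordered_genes(universe, ordered_genes),
        n_replicates_merged=1,
    )


class TestConnectivityScore:
    @pytest.fixture
    def setting(self):
        u = universe_of(20)
        genes = list(u.genes)
        query = QuerySignature(up=frozenset(genes[:5]), down=frozenset(genes[5:10]))
        return u, genes, query

    def test_perfect_concordance_attains_plus_one(self, setting):
        u, genes, query = setting
        ordered = genes[:5] + genes[10:] + genes[5:10]  # up head, down tail
        rec = connectivity_score(query, prl_from_order(u, ordered))
        assert rec.es_up == pytest.approx(1.0)
        assert rec.es_down == pytest.approx(-1.0)
        assert rec.score == pytest.approx(1.0)

    def test_same_sign_es_nulled(self, setting):
        u, genes, query = setting
        # both query directions at the head -> both ES positive -> score 0
        ordered = genes[:10] + genes[10:]
        rec = connectivity_score(query, prl_from_order(u, ordered))
        assert rec.es_up > 0 and rec.es_down > 0
        assert rec.score == 0.0
        rec2 = connectivity_score(
            query, prl_from_order(u, ordered), null_same_sign=False
        )
        assert rec2.score == pytest.approx((rec2.es_up - rec2.es_down) / 2)

    def test_antisymmetric_under_query_swap(self, setting):
        u, genes, query = setting
        rng = np.random.default_rng(3)
        swapped = QuerySignature(up=query.down, down=query.up)
        for _ in range(20):
            order = [genes[i] for i in rng.permutation(len(genes))]
            prl = prl_from_order(u, order)
            a = connectivity_score(query, prl)
            b = connectivity_score(swapped, prl)
            assert b.score == pytest.approx(-a.score)
            assert -1.0 <= a.score <= 1.0


class TestRankCompounds:
    def rec(self, cid, score):
        return ConnectivityRecord(cid, es_up=score, es_down=-score, score=score)

    def test_descending_with_lexicographic_ties(self):
        recs = [self.rec("b", 0.5), self.rec("a", 0.5), self.rec("c", 0.9)]
        ranking = rank_compounds(recs)
        assert ranking.compound_ids == ("c", "a", "b")

    def test_negation_reverses_order(self):
        recs = [self.rec("a", 0.9), self.rec("b", 0.5), self.rec("c", 0.1)]
        fwd = rank_compounds(recs).compound_ids
        rev = rank_compounds([self.rec(r.compound_id, -r.score) for r in recs])
        assert rev.compound_ids == fwd[::-1]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate compound"):
            rank_compounds([self.rec("a", 0.1), self.rec("a", 0.2)])
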