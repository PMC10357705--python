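"""Enrichment engine: exact tail probabilities, BH-FDR, contrast wiring."""

import math
from math import comb

import numpy as np
import pytest

from darkcov.enrich import bh_fdr, enrich, hypergeom_upper_tail, run_contrasts
from darkcov.models import DarkCoverageReport, TermMap


def upper_tail_by_enumeration(k, K, n, N):
    """P(X >= k) as an exact ratio of binomial-coefficient sums."""
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1)
              if n - i <= N - K)
    return num / comb(N, n)


def bh_step_up_reference(p):
    """Direct transcription of the BH step-up definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


class TestHypergeomUpperTail:
    def test_enumeration_example(self):
        # all 5 of the study's 3 draws hit the 5 annotated of 10:
        # C(5,3)/C(10,3) = 10/120
        assert hypergeom_upper_tail(3, 5, 3, 10) == pytest.approx(10 / 120, rel=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 5, 3, 10) == 1.0

    @pytest.mark.parametrize(
        "k,K,n,N", [(4, 3, 5, 10), (4, 5, 3, 10), (3, 5, 11, 10), (0, 11, 3, 10)]
    )
    def test_inconsistent_counts_rejected(self, k, K, n, N):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(k, K, n, N)

    def test_random_small_draws_match_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            N = int(rng.integers(1, 31))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                upper_tail_by_enumeration(k, K, n, N), rel=1e-10, abs=1e-300
            )


class TestBhFdr:
    def test_hand_worked_example(self):
        # step-up: q3 = 0.03, q2 = min(0.03, 3*0.02/2)=0.03, q1 = min(0.03, 0.03)
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_empty(self):
        assert bh_fdr([]).size == 0

    def test_matches_step_up_reference_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = int(rng.integers(1, 120))
            p = rng.random(m)
            assert bh_fdr(p) == pytest.approx(bh_step_up_reference(list(p)), rel=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        p = rng.random(40)
        perm = rng.permutation(40)
        assert bh_fdr(p[perm]) == pytest.approx(bh_fdr(p)[perm], rel=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(7)
        p = np.sort(rng.random(50))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def simple_terms():
    return TermMap(
        terms={
            "T1": frozenset({"A", "B", "C"}),
            "T2": frozenset({"D", "E", "F"}),
        }
    )


class TestEnrich:
    def test_full_term_ranks_first(self):
        universe = list("ABCDEFGH")
        res = enrich(["A", "B", "C"], universe, simple_terms())
        assert res[0].term_id == "T1"
        assert res[0].k == 3 and res[0].K == 3 and res[0].n == 3 and res[0].N == 8
        assert res[0].p_value < res[1].p_value

    def test_study_equals_universe_all_p_one(self):
        universe = list("ABCDEF")
        res = enrich(universe, universe, simple_terms())
        assert all(r.p_value == 1.0 for r in res)

    def test_empty_study_after_intersection_errors(self):
        with pytest.raises(ValueError, match="empty"):
            enrich(["Z"], list("ABC"), simple_terms())

    def test_outside_genes_dropped(self, caplog):
        universe = list("ABCDEFGH")
        with caplog.at_level("WARNING"):
            res = enrich(["A", "B", "ZZZ"], universe, simple_terms())
        assert res[0].n == 2

    def test_min_term_size_filter(self):
        universe = list("ABCDEFGH")
        tm = TermMap(terms={"BIG": frozenset("ABCD"), "TINY": frozenset("A")})
        res = enrich(["A"], universe, tm, min_term_size=3)
        assert [r.term_id for r in res] == ["BIG"]


def _report(gene_id, body_dark, cds_dark):
    return DarkCoverageReport(
        gene_id=gene_id, symbol=gene_id, body_len=100,
        body_dark_bp=body_dark, cds_len=50, cds_dark_bp=cds_dark,
    )


class TestRunContrasts:
    def test_no_dark_genes_yields_explicit_empty_outcome(self):
        reports = {g: _report(g, 0, 0) for g in "ABCD"}
        out = run_contrasts(reports, list("AB"), list("ABCD"), simple_terms())
        assert out["dark_vs_genome"].message == "no study genes"
        assert out["dark_vs_genome"].results == []

    def test_all_mapped_dark_cds_degenerate(self):
        reports = {g: _report(g, 10, 5) for g in "ABCDEF"}
        tm = TermMap(terms={"T1": frozenset("ABC")})
        out = run_contrasts(reports, list("ABCDEF"), list("ABCDEF"), tm)
        b = out["dark_cds_vs_grl"]
        assert all(r.p_value == 1.0 for r in b.results)

    def test_planted_term_recovered_in_cohort(self, default_cohort):
        """The generator's planted term is FDR-significant in dark-vs-genome."""
        from darkcov.annotate import annotate_genes
        from darkcov.intervals import normalize

        reports = annotate_genes(
            default_cohort.genes, normalize(default_cohort.dark_records)
        )
        grl_ids = default_cohort.truth["cohort"]
        mapped = [
            gid
            for locus in default_cohort.loci
            for gid in locus.mapped_gene_ids
        ]
        out = run_contrasts(
            reports,
            mapped,
            [g.gene_id for g in default_cohort.genes],
            default_cohort.term_map,
        )
        a = out["dark_vs_genome"]
        planted = default_cohort.config.planted_term
        assert a.results[0].term_id == planted
        assert a.results[0].q_value < 0.05
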