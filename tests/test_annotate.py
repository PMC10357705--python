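"""Dark scoring: CDS unions, per-gene reports, locus and cohort summaries."""

import math

import numpy as np
import pytest

from darkcov.annotate import (
    cds_union,
    gene_dark_report,
    summarize_cohort,
    summarize_loci,
)
from darkcov.intervals import GenomicInterval, normalize
from darkcov.models import GeneModel, RiskLocus

from conftest import per_base_cover


def make_gene(gene_id="G1", chrom="chr1", body=(0, 1000), transcripts=None):
    return GeneModel(
        gene_id=gene_id,
        symbol=gene_id,
        chrom=chrom,
        strand="+",
        body=GenomicInterval(chrom, *body),
        transcripts=transcripts or {},
    )


class TestCdsUnion:
    def test_union_across_transcripts(self):
        g = make_gene(
            transcripts={
                "t1": [GenomicInterval("chr1", 100, 200)],
                "t2": [GenomicInterval("chr1", 150, 250)],
            }
        )
        u = cds_union(g)
        assert u.to_intervals() == [GenomicInterval("chr1", 100, 250)]
        assert u.total_length == 150

    def test_single_transcript(self):
        exons = [GenomicInterval("chr1", 10, 60), GenomicInterval("chr1", 100, 150)]
        g = make_gene(transcripts={"t1": exons})
        assert cds_union(g).total_length == 100

    def test_longest_transcript_mode(self):
        g = make_gene(
            transcripts={
                "t1": [GenomicInterval("chr1", 100, 400)],
                "t2": [GenomicInterval("chr1", 100, 200)],
            }
        )
        assert cds_union(g, mode="longest").total_length == 300

    def test_random_multi_transcript_matches_per_base_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            transcripts = {}
            raw = []
            for t in range(int(rng.integers(1, 4))):
                exons = []
                for _ in range(int(rng.integers(1, 5))):
                    s = int(rng.integers(0, 900))
                    e = s + int(rng.integers(1, 100))
                    exons.append(GenomicInterval("chr1", s, min(e, 1000)))
                transcripts[f"t{t}"] = exons
                raw.extend(exons)
            g = make_gene(transcripts=transcripts)
            cover = per_base_cover(raw, {"chr1": 1000})
            assert cds_union(g).total_length == int(cover["chr1"].sum())


class TestGeneDarkReport:
    def test_fully_dark(self):
        g = make_gene(transcripts={"t1": [GenomicInterval("chr1", 100, 300)]})
        dark = normalize([GenomicInterval("chr1", 0, 1000)])
        r = gene_dark_report(g, dark)
        assert r.body_dark_frac == 1.0 and r.cds_dark_frac == 1.0
        assert r.any_dark_body and r.any_dark_cds and r.dark_cds_gt5 and r.dark_cds_gt20

    def test_disjoint_dark(self):
        g = make_gene(transcripts={"t1": [GenomicInterval("chr1", 100, 300)]})
        dark = normalize([GenomicInterval("chr2", 0, 1000)])
        r = gene_dark_report(g, dark)
        assert r.body_dark_bp == 0 and r.cds_dark_bp == 0
        assert not (r.any_dark_body or r.any_dark_cds or r.dark_cds_gt5)

    def test_noncoding_gene_cds_frac_is_nan(self):
        g = make_gene()
        r = gene_dark_report(g, normalize([GenomicInterval("chr1", 0, 10)]))
        assert r.cds_len == 0 and math.isnan(r.cds_dark_frac)
        assert not r.any_dark_cds and not r.dark_cds_gt5

    def test_planted_fraction_reproduced_exactly(self, default_cohort):
        """A gene planted at 7.7% dark-CDS reads back 0.077, gt5 but not gt20."""
        cfg = default_cohort.config
        dark = normalize(default_cohort.dark_records)
        by_idx = {i: g for i, g in enumerate(default_cohort.genes)}
        for idx, frac in cfg.cds_dark_targets.items():
            r = gene_dark_report(by_idx[idx], dark)
            assert r.cds_dark_frac == pytest.approx(frac, abs=0)
        shank_like = next(i for i, f in cfg.cds_dark_targets.items() if f == 0.077)
        r = gene_dark_report(by_idx[shank_like], dark)
        assert r.cds_dark_frac == 0.077 and r.dark_cds_gt5 and not r.dark_cds_gt20

    def test_flag_monotonicity(self, default_cohort):
        dark = normalize(default_cohort.dark_records)
        for g in default_cohort.genes:
            r = gene_dark_report(g, dark)
            assert (not r.dark_cds_gt20) or r.dark_cds_gt5
            assert (not r.dark_cds_gt5) or r.any_dark_cds

    def test_fraction_invariant_under_coordinate_scaling(self):
        """Scaling every coordinate by a constant leaves fractions unchanged."""
        def build(scale):
            g = make_gene(
                body=(0, 1000 * scale),
                transcripts={
                    "t1": [GenomicInterval("chr1", 100 * scale, 300 * scale)]
                },
            )
            dark = normalize([GenomicInterval("chr1", 150 * scale, 500 * scale)])
            return gene_dark_report(g, dark)

        r1, r7 = build(1), build(7)
        assert r1.body_dark_frac == r7.body_dark_frac
        assert r1.cds_dark_frac == r7.cds_dark_frac


class TestSummarizeLoci:
    def test_percentage_arithmetic(self):
        loci = [
            RiskLocus("L1", GenomicInterval("chr1", 0, 100)),
            RiskLocus("L2", GenomicInterval("chr1", 200, 300)),
            RiskLocus("L3", GenomicInterval("chr1", 400, 500)),
        ]
        dark = [GenomicInterval("chr1", 50, 60)]
        s = summarize_loci(loci, dark)
        assert s.n_loci_dark == 1
        assert s.pct_loci_dark == pytest.approx(100 / 3)
        assert s.total_locus_dark_bp == 10

    def test_no_dark_records(self):
        loci = [RiskLocus("L1", GenomicInterval("chr1", 0, 100))]
        s = summarize_loci(loci, [])
        assert s.n_dark_records == [0] and s.dark_bp == [0] and s.n_loci_dark == 0

    def test_duplicate_locus_id_errors(self):
        loci = [
            RiskLocus("L1", GenomicInterval("chr1", 0, 100)),
            RiskLocus("L1", GenomicInterval("chr1", 200, 300)),
        ]
        with pytest.raises(ValueError, match="L1"):
            summarize_loci(loci, [])

    def test_record_counts_on_unmerged_records(self):
        loci = [RiskLocus("L1", GenomicInterval("chr1", 0, 1000))]
        dark = [GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 20, 30)]
        s = summarize_loci(loci, dark)
        assert s.n_dark_records == [2] and s.dark_bp == [20]

    def test_planted_locus_truth(self, default_cohort):
        s = summarize_loci(default_cohort.loci, default_cohort.dark_records)
        for lid, n, bp in zip(s.locus_ids, s.n_dark_records, s.dark_bp):
            t = default_cohort.truth["loci"][lid]
            assert (n, bp) == (t["n_dark_records"], t["dark_bp"])


class TestSummarizeCohort:
    def test_shared_gene_counted_once(self):
        g1 = make_gene("G1", body=(0, 100), transcripts={})
        loci = [
            RiskLocus("L1", GenomicInterval("chr1", 0, 50), ["G1"]),
            RiskLocus("L2", GenomicInterval("chr1", 60, 120), ["G1"]),
        ]
        summary, reports = summarize_cohort(loci, [g1], [])
        assert summary.n_genes == 1 and set(reports) == {"G1"}

    def test_all_genes_fully_dark(self):
        genes = [
            make_gene("G1", body=(0, 100),
                      transcripts={"t": [GenomicInterval("chr1", 10, 90)]}),
            make_gene("G2", body=(200, 300),
                      transcripts={"t": [GenomicInterval("chr1", 210, 290)]}),
        ]
        loci = [RiskLocus("L1", GenomicInterval("chr1", 0, 400), ["G1", "G2"])]
        dark = [GenomicInterval("chr1", 0, 400)]
        summary, _ = summarize_cohort(loci, genes, dark)
        assert summary.n_genes_dark_body == summary.n_genes == 2
        assert summary.n_dark_cds_gt20 == 2

    def test_unresolved_ids_counted_not_fatal(self, caplog):
        g1 = make_gene("G1", body=(0, 100))
        loci = [RiskLocus("L1", GenomicInterval("chr1", 0, 50), ["G1", "MISSING"])]
        with caplog.at_level("WARNING"):
            summary, _ = summarize_cohort(loci, [g1], [])
        assert summary.n_genes == 1 and summary.n_unresolved_gene_ids == 1

    def test_planted_class_counts(self, default_cohort):
        summary, reports = summarize_cohort(
            default_cohort.loci, default_cohort.genes, default_cohort.dark_records
        )
        t = default_cohort.truth["cohort"]
        assert summary.n_any_dark_cds == t["n_any_dark_cds"]
        assert summary.n_dark_cds_gt5 == t["n_dark_cds_gt5"]
        assert summary.n_dark_cds_gt20 == t["n_dark_cds_gt20"]
        # totals equal the sum over per-gene reports: no double counting
        assert summary.gene_dark_bp_total == sum(
            r.body_dark_bp for r in reports.values()
        )
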