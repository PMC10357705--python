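"""Dark-coverage scoring of genes and risk loci.

The central quantities: for each gene, the base pairs of its body and of its
CDS union covered by dark regions (and the resulting fractions and
threshold classes, strict > 5% and > 20%); for each risk locus, how many
dark records touch it and how many of its bases are dark; and the
cohort-level aggregate row combining both.

Gene statistics are gene-level, not locus-clipped: a mapped gene partially
outside its locus still contributes its full body and CDS. Locus bp columns
are locus-clipped by construction. Both a gene-level and a locus-clipped
dark-bp total are reported at the cohort level.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .intervals import (
    GenomicInterval,
    IntervalSet,
    count_source_overlaps,
    normalize,
)
from .models import (
    CohortSummary,
    DarkCoverageReport,
    GeneModel,
    LocusOverlapSummary,
    RiskLocus,
)

logger = logging.getLogger(__name__)

__all__ = [
    "cds_union",
    "gene_dark_report",
    "annotate_genes",
    "reports_to_frame",
    "summarize_loci",
    "locus_summary_frame",
    "summarize_cohort",
    "cohort_summary_frame",
]


def cds_union(gene: GeneModel, mode: str = "union") -> IntervalSet:
    """Merged CDS intervals of a gene.

    ``union`` (default) merges CDS exons across every transcript — the most
    inclusive reading of a gene's protein-coding footprint. ``longest``
    instead uses the single transcript with the largest merged CDS length.
    """
    if mode == "union":
        exons: List[GenomicInterval] = [
            ex for tx in gene.transcripts.values() for ex in tx
        ]
        return normalize(exons)
    if mode == "longest":
        best = IntervalSet()
        for tx in gene.transcripts.values():
            cand = normalize(tx)
            if cand.total_length > best.total_length:
                best = cand
        return best
    raise ValueError(f"cds mode must be 'union' or 'longest', got {mode!r}")


def gene_dark_report(
    gene: GeneModel, dark: IntervalSet, cds_mode: str = "union"
) -> DarkCoverageReport:
    """Dark coverage of one gene's body and CDS union."""
    body_set = normalize([gene.body])
    cds = cds_union(gene, mode=cds_mode)
    return DarkCoverageReport(
        gene_id=gene.gene_id,
        symbol=gene.symbol,
        body_len=gene.body.length,
        body_dark_bp=body_set.intersect_length(dark),
        cds_len=cds.total_length,
        cds_dark_bp=cds.intersect_length(dark),
    )


def annotate_genes(
    genes: Iterable[GeneModel], dark: IntervalSet, cds_mode: str = "union"
) -> Dict[str, DarkCoverageReport]:
    """Per-gene dark-coverage reports, keyed by gene_id."""
    return {
        g.gene_id: gene_dark_report(g, dark, cds_mode=cds_mode) for g in genes
    }


def reports_to_frame(reports: Dict[str, DarkCoverageReport]) -> pd.DataFrame:
    """Tabular form of the per-gene reports (one row per gene, sorted)."""
    rows = []
    for gid in sorted(reports):
        r = reports[gid]
        rows.append(
            {
                "gene_id": r.gene_id,
                "symbol": r.symbol,
                "body_len": r.body_len,
                "body_dark_bp": r.body_dark_bp,
                "body_dark_frac": r.body_dark_frac,
                "cds_len": r.cds_len,
                "cds_dark_bp": r.cds_dark_bp,
                "cds_dark_frac": r.cds_dark_frac,
                "any_dark_body": r.any_dark_body,
                "any_dark_cds": r.any_dark_cds,
                "dark_cds_gt5": r.dark_cds_gt5,
                "dark_cds_gt20": r.dark_cds_gt20,
            }
        )
    return pd.DataFrame(rows)


def summarize_loci(
    loci: Sequence[RiskLocus], dark_records: Sequence[GenomicInterval]
) -> LocusOverlapSummary:
    """Per-locus dark overlap: record counts on the unmerged catalog,
    base-pair overlap on the merged one."""
    ids = [l.locus_id for l in loci]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate locus ids: {', '.join(dupes)}")
    dark = normalize(dark_records)
    n_records: List[int] = []
    dark_bp: List[int] = []
    for locus in loci:
        n_records.append(count_source_overlaps(dark_records, locus.span))
        dark_bp.append(normalize([locus.span]).intersect_length(dark))
    return LocusOverlapSummary(
        locus_ids=ids, n_dark_records=n_records, dark_bp=dark_bp
    )


def locus_summary_frame(summary: LocusOverlapSummary) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": summary.locus_ids,
            "n_dark_records": summary.n_dark_records,
            "dark_bp": summary.dark_bp,
            "is_dark": summary.is_dark,
        }
    )


def summarize_cohort(
    loci: Sequence[RiskLocus],
    genes: Sequence[GeneModel],
    dark_records: Sequence[GenomicInterval],
    cds_mode: str = "union",
    reports: Optional[Dict[str, DarkCoverageReport]] = None,
) -> Tuple[CohortSummary, Dict[str, DarkCoverageReport]]:
    """Cohort aggregate over the deduplicated union of mapped genes.

    A gene mapped by two loci counts once. Mapped gene ids that resolve to
    no gene model are logged and counted, not fatal. Returns the summary and
    the per-mapped-gene reports it was built from.
    """
    locus_summary = summarize_loci(loci, dark_records)
    gene_index = {g.gene_id: g for g in genes}
    mapped_ids: List[str] = []
    seen = set()
    for locus in loci:
        for gid in locus.mapped_gene_ids:
            if gid not in seen:
                seen.add(gid)
                mapped_ids.append(gid)
    unresolved = [gid for gid in mapped_ids if gid not in gene_index]
    if unresolved:
        logger.warning(
            "%d mapped gene ids not found in the annotation (e.g. %s)",
            len(unresolved),
            ", ".join(unresolved[:5]),
        )
    resolved = [gid for gid in mapped_ids if gid in gene_index]

    dark = normalize(dark_records)
    if reports is None:
        reports = annotate_genes(
            (gene_index[gid] for gid in resolved), dark, cds_mode=cds_mode
        )
    mapped_reports = {gid: reports[gid] for gid in resolved}

    # gene dark bp, both gene-level and clipped to the locus union
    gene_bodies = normalize([gene_index[gid].body for gid in resolved])
    gene_dark = gene_bodies.intersect(dark)
    locus_union = normalize([l.span for l in loci])

    summary = CohortSummary(
        n_loci=locus_summary.n_loci,
        n_loci_dark=locus_summary.n_loci_dark,
        total_locus_dark_bp=locus_summary.total_locus_dark_bp,
        n_genes=len(resolved),
        n_genes_dark_body=sum(
            1 for r in mapped_reports.values() if r.any_dark_body
        ),
        gene_dark_bp_total=gene_dark.total_length,
        gene_dark_bp_in_loci=gene_dark.intersect_length(locus_union),
        n_any_dark_cds=sum(1 for r in mapped_reports.values() if r.any_dark_cds),
        n_dark_cds_gt5=sum(1 for r in mapped_reports.values() if r.dark_cds_gt5),
        n_dark_cds_gt20=sum(
            1 for r in mapped_reports.values() if r.dark_cds_gt20
        ),
        n_unresolved_gene_ids=len(unresolved),
    )
    return summary, mapped_reports


def cohort_summary_frame(summary: CohortSummary) -> pd.DataFrame:
    """One-row table shaped like a per-cohort summary row."""
    return pd.DataFrame(
        [
            {
                "n_loci": summary.n_loci,
                "n_loci_dark": summary.n_loci_dark,
                "pct_loci_dark": summary.pct_loci_dark,
                "total_locus_dark_bp": summary.total_locus_dark_bp,
                "n_genes": summary.n_genes,
                "n_genes_dark_body": summary.n_genes_dark_body,
                "pct_genes_dark_body": summary.pct_genes_dark_body,
                "gene_dark_bp_total": summary.gene_dark_bp_total,
                "gene_dark_bp_in_loci": summary.gene_dark_bp_in_loci,
                "n_any_dark_cds": summary.n_any_dark_cds,
                "n_dark_cds_gt5": summary.n_dark_cds_gt5,
                "n_dark_cds_gt20": summary.n_dark_cds_gt20,
                "n_unresolved_gene_ids": summary.n_unresolved_gene_ids,
            }
        ]
    )
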