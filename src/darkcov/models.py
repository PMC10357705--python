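"""Domain types shared across the pipeline.

All coordinates are internal 0-based half-open; readers in :mod:`darkcov.io`
convert from the 1-based closed conventions of GFF/GTF and locus tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

from .intervals import GenomicInterval, IntervalSet, normalize

__all__ = [
    "GeneModel",
    "RiskLocus",
    "GeneRecord",
    "TermMap",
    "DarkCoverageReport",
    "LocusOverlapSummary",
    "CohortSummary",
]


@dataclass
class GeneModel:
    """A gene with its body span and per-transcript CDS exons.

    ``transcripts`` maps transcript_id -> list of CDS-exon intervals. Genes
    without any CDS are legal (non-coding); they contribute to gene-body
    statistics and report an undefined (NA) CDS dark fraction.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    body: GenomicInterval
    transcripts: Dict[str, List[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.body.chrom != self.chrom:
            raise ValueError(f"gene {self.gene_id}: body chrom != gene chrom")
        for tx_id, exons in self.transcripts.items():
            for ex in exons:
                if ex.chrom != self.chrom:
                    raise ValueError(
                        f"gene {self.gene_id}: CDS exon of {tx_id} on {ex.chrom}, "
                        f"gene on {self.chrom}"
                    )
                if ex.start < self.body.start or ex.end > self.body.end:
                    raise ValueError(
                        f"gene {self.gene_id}: CDS exon {ex.start}-{ex.end} "
                        f"outside body {self.body.start}-{self.body.end}"
                    )

    @property
    def has_cds(self) -> bool:
        return any(self.transcripts.values())


@dataclass
class RiskLocus:
    """A genomic risk locus (GRL) with its precomputed mapped genes."""

    locus_id: str
    span: GenomicInterval
    mapped_gene_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.mapped_gene_ids)) != len(self.mapped_gene_ids):
            raise ValueError(f"locus {self.locus_id}: duplicate mapped gene ids")


@dataclass
class GeneRecord:
    """One row of a candidate-gene table (SCHEMA/ASC/SFARI style)."""

    gene_id: str
    p_value: Optional[float] = None
    q_value: Optional[float] = None
    category: Optional[str] = None

    def __post_init__(self) -> None:
        for label, v in (("p_value", self.p_value), ("q_value", self.q_value)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{label} outside [0,1] for {self.gene_id}: {v}")


@dataclass
class TermMap:
    """Mapping term_id -> set of gene ids, with optional descriptions."""

    terms: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    descriptions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, FrozenSet[str]] = {}
        for term, genes in self.terms.items():
            gs = frozenset(genes)
            if not gs:
                raise ValueError(f"term {term} has no genes")
            clean[term] = gs
        self.terms = clean

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class DarkCoverageReport:
    """Per-gene dark coverage of the gene body and of the CDS union.

    ``cds_dark_frac`` is NaN for genes without CDS. Threshold flags use
    strict inequalities (> 5%, > 20%), so a gene at exactly 5% dark-CDS is
    not ``dark_cds_gt5``.
    """

    gene_id: str
    symbol: str
    body_len: int
    body_dark_bp: int
    cds_len: int
    cds_dark_bp: int

    @property
    def body_dark_frac(self) -> float:
        return self.body_dark_bp / self.body_len

    @property
    def cds_dark_frac(self) -> float:
        if self.cds_len == 0:
            return math.nan
        return self.cds_dark_bp / self.cds_len

    @property
    def any_dark_body(self) -> bool:
        return self.body_dark_bp > 0

    @property
    def any_dark_cds(self) -> bool:
        return self.cds_dark_bp > 0

    @property
    def dark_cds_gt5(self) -> bool:
        return self.cds_len > 0 and self.cds_dark_bp / self.cds_len > 0.05

    @property
    def dark_cds_gt20(self) -> bool:
        return self.cds_len > 0 and self.cds_dark_bp / self.cds_len > 0.20

    def __post_init__(self) -> None:
        if not (0 <= self.body_dark_bp <= self.body_len):
            raise ValueError(f"{self.gene_id}: body_dark_bp out of range")
        if not (0 <= self.cds_dark_bp <= self.cds_len):
            raise ValueError(f"{self.gene_id}: cds_dark_bp out of range")


@dataclass
class LocusOverlapSummary:
    """Per-locus dark overlap plus the cohort-level aggregate."""

    locus_ids: List[str]
    n_dark_records: List[int]
    dark_bp: List[int]

    @property
    def is_dark(self) -> List[bool]:
        return [bp > 0 for bp in self.dark_bp]

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_loci_dark(self) -> int:
        return sum(self.is_dark)

    @property
    def pct_loci_dark(self) -> float:
        if self.n_loci == 0:
            return math.nan
        return 100.0 * self.n_loci_dark / self.n_loci

    @property
    def total_locus_dark_bp(self) -> int:
        return sum(self.dark_bp)


@dataclass
class CohortSummary:
    """One Table-shaped cohort row: locus aggregate + gene-level counts."""

    n_loci: int
    n_loci_dark: int
    total_locus_dark_bp: int
    n_genes: int
    n_genes_dark_body: int
    gene_dark_bp_total: int
    gene_dark_bp_in_loci: int
    n_any_dark_cds: int
    n_dark_cds_gt5: int
    n_dark_cds_gt20: int
    n_unresolved_gene_ids: int = 0

    @property
    def pct_loci_dark(self) -> float:
        return math.nan if self.n_loci == 0 else 100.0 * self.n_loci_dark / self.n_loci

    @property
    def pct_genes_dark_body(self) -> float:
        if self.n_genes == 0:
            return math.nan
        return 100.0 * self.n_genes_dark_body / self.n_genes

    def __post_init__(self) -> None:
        if not (
            self.n_any_dark_cds >= self.n_dark_cds_gt5 >= self.n_dark_cds_gt20
        ):
            raise ValueError("dark-CDS class counts must be non-increasing")
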