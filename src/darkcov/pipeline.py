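"""End-to-end pipeline: read inputs, score, summarize, enrich, stratify.

The CLI and the analysis drivers are thin wrappers over
:func:`run_pipeline`, which returns every output table in memory;
:func:`write_outputs` serializes them plus a run manifest (input hashes,
config hash, chromosome-name overlap diagnostics, warning counts) so a
rerun with identical inputs is byte-identical and silent chromosome-name
mismatches are impossible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from . import io as dio
from .annotate import (
    annotate_genes,
    cohort_summary_frame,
    locus_summary_frame,
    reports_to_frame,
    summarize_cohort,
    summarize_loci,
)
from .enrich import ContrastOutcome, run_contrasts
from .intervals import normalize
from .io import GrlTableSpec
from .stratify import stratification_chi2, stratify

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass
class RunConfig:
    """All pipeline inputs and knobs; loadable from YAML, overridable by flags."""

    dark_bed: str = "dark.bed"
    gene_models: str = "genes.gff3"
    gene_models_dialect: str = "gff3"
    grl_table: str = "grl.tsv"
    gene_table: Optional[str] = "genes_table.tsv"
    term_map: Optional[str] = "terms.gmt"
    term_map_format: str = "gmt"
    grl_columns: GrlTableSpec = field(default_factory=GrlTableSpec)
    strip_chr_prefix: bool = False
    cds_mode: str = "union"
    thresholds: Tuple[float, float] = (0.05, 0.20)
    bins: Tuple[float, float] = (0.1, 0.3)
    dark_definition: str = "body"
    min_term_size: int = 3
    stratify_chi2: bool = False
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        lo, hi = self.thresholds
        if not (0 < lo < hi < 1):
            raise ValueError("thresholds must be strictly increasing in (0,1)")
        for label, p in (
            ("dark_bed", self.dark_bed),
            ("gene_models", self.gene_models),
            ("grl_table", self.grl_table),
        ):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label}: no such file {p!r}")
        for label, p in (("gene_table", self.gene_table), ("term_map", self.term_map)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label}: no such file {p!r}")

    @staticmethod
    def from_yaml(path: PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        grl_cols = raw.pop("grl_columns", None)
        cfg = RunConfig(**{k: v for k, v in raw.items() if k in _CONFIG_FIELDS})
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        if grl_cols:
            cfg.grl_columns = GrlTableSpec(**grl_cols)
        if isinstance(cfg.thresholds, list):
            cfg.thresholds = tuple(cfg.thresholds)
        if isinstance(cfg.bins, list):
            cfg.bins = tuple(cfg.bins)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["bins"] = list(self.bins)
        return d


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


@dataclass
class PipelineResult:
    gene_report: pd.DataFrame
    locus_summary: pd.DataFrame
    cohort_summary: pd.DataFrame
    contrasts: Dict[str, ContrastOutcome]
    stratification: Optional[pd.DataFrame]
    chrom_diagnostics: pd.DataFrame
    n_unresolved_gene_ids: int


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage on the configured inputs."""
    config.validate()
    dark_records = dio.read_bed(config.dark_bed)
    genes = dio.read_gene_models(config.gene_models, dialect=config.gene_models_dialect)
    loci = dio.read_grl_table(config.grl_table, spec=config.grl_columns)
    if config.strip_chr_prefix:
        # applied symmetrically to every input so overlap arithmetic cannot
        # silently see disjoint chromosome namespaces
        from .models import GeneModel, RiskLocus

        dark_records = [dio.strip_chr_prefix_interval(iv) for iv in dark_records]
        genes = [
            GeneModel(
                gene_id=g.gene_id,
                symbol=g.symbol,
                chrom=dio.strip_chr_prefix_interval(g.body).chrom,
                strand=g.strand,
                body=dio.strip_chr_prefix_interval(g.body),
                transcripts={
                    tid: [dio.strip_chr_prefix_interval(e) for e in exons]
                    for tid, exons in g.transcripts.items()
                },
            )
            for g in genes
        ]
        loci = [
            RiskLocus(
                locus_id=l.locus_id,
                span=dio.strip_chr_prefix_interval(l.span),
                mapped_gene_ids=list(l.mapped_gene_ids),
            )
            for l in loci
        ]

    chrom_diag = dio.chromosome_overlap_report(
        {
            "dark_bed": {iv.chrom for iv in dark_records},
            "gene_models": {g.chrom for g in genes},
            "grl_table": {l.span.chrom for l in loci},
        }
    )
    for _, row in chrom_diag.iterrows():
        if row["n_a"] and row["n_b"] and row["shared"] == 0:
            logger.warning(
                "no shared chromosome names between %s and %s — "
                "overlaps will be zero",
                row["input_a"],
                row["input_b"],
            )

    dark = normalize(dark_records)
    reports = annotate_genes(genes, dark, cds_mode=config.cds_mode)
    gene_report = reports_to_frame(reports)

    locus_sum = summarize_loci(loci, dark_records)
    cohort, mapped_reports = summarize_cohort(
        loci, genes, dark_records, cds_mode=config.cds_mode, reports=reports
    )

    contrasts: Dict[str, ContrastOutcome] = {}
    if config.term_map is not None:
        terms = dio.read_term_map(config.term_map, format=config.term_map_format)
        grl_gene_ids = list(mapped_reports)
        contrasts = run_contrasts(
            reports,
            grl_gene_ids,
            [g.gene_id for g in genes],
            terms,
            min_term_size=config.min_term_size,
        )

    strat_df: Optional[pd.DataFrame] = None
    if config.gene_table is not None:
        records = dio.read_gene_table(config.gene_table)
        strat_df = stratify(
            records,
            reports,
            bins=config.bins,
            dark_definition=config.dark_definition,
        )
        if config.stratify_chi2 and not strat_df.empty:
            stat, p = stratification_chi2(strat_df)
            logger.info("stratification chi2=%.4g p=%.4g", stat, p)

    return PipelineResult(
        gene_report=gene_report,
        locus_summary=locus_summary_frame(locus_sum),
        cohort_summary=cohort_summary_frame(cohort),
        contrasts=contrasts,
        stratification=strat_df,
        chrom_diagnostics=chrom_diag,
        n_unresolved_gene_ids=cohort.n_unresolved_gene_ids,
    )


def contrast_frame(outcome: ContrastOutcome) -> pd.DataFrame:
    rows = [
        {
            "term_id": r.term_id,
            "k": r.k,
            "n": r.n,
            "K": r.K,
            "N": r.N,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "study_genes": ",".join(sorted(r.study_genes)),
        }
        for r in outcome.results
    ]
    return pd.DataFrame(
        rows, columns=["term_id", "k", "n", "K", "N", "p_value", "q_value", "study_genes"]
    )


def _sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(result: PipelineResult, config: RunConfig) -> Dict[str, Path]:
    """Serialize all tables and the run manifest under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["gene_dark_report"] = out / "gene_dark_report.tsv"
    dio.write_tsv(result.gene_report, paths["gene_dark_report"], sort_by=["gene_id"])
    paths["locus_summary"] = out / "locus_summary.tsv"
    dio.write_tsv(result.locus_summary, paths["locus_summary"], sort_by=["locus_id"])
    paths["cohort_summary"] = out / "cohort_summary.tsv"
    dio.write_tsv(result.cohort_summary, paths["cohort_summary"])
    for name, outcome in result.contrasts.items():
        p = out / f"enrichment_{name}.tsv"
        dio.write_tsv(contrast_frame(outcome), p)
        paths[f"enrichment_{name}"] = p
    if result.stratification is not None:
        paths["stratification"] = out / "stratification.tsv"
        dio.write_tsv(result.stratification, paths["stratification"])

    inputs = {
        k: p
        for k, p in {
            "dark_bed": config.dark_bed,
            "gene_models": config.gene_models,
            "grl_table": config.grl_table,
            "gene_table": config.gene_table,
            "term_map": config.term_map,
        }.items()
        if p is not None
    }
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "input_sha256": {k: _sha256(p) for k, p in inputs.items()},
        "chromosome_overlap": result.chrom_diagnostics.to_dict(orient="records"),
        "n_unresolved_gene_ids": result.n_unresolved_gene_ids,
        "contrast_messages": {
            name: o.message for name, o in result.contrasts.items() if o.message
        },
    }
    paths["manifest"] = out / "run_manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
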