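"""Readers and writers for every external format the pipeline touches.

All readers convert to the internal convention (0-based half-open):

* BED is already 0-based half-open and passes through verbatim.
* GFF3/GTF are 1-based closed; ``start`` becomes ``start - 1``.
* Locus (GRL) tables declare their convention; 1-based closed is the default.

Writers emit deterministic column and row order so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Union

import gffutils
import pandas as pd

from .intervals import GenomicInterval
from .models import GeneModel, GeneRecord, RiskLocus, TermMap

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_BED_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path: PathLike) -> List[GenomicInterval]:
    """Read BED3/BED4 into intervals, preserving input order (no merging).

    Track/browser/comment lines are skipped; column 4, when present, becomes
    the interval name. Malformed lines raise with their line number.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] else None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3 / GTF)
# ---------------------------------------------------------------------------

def read_gene_models(path: PathLike, dialect: str = "gff3") -> List[GeneModel]:
    """Parse gene models from GFF3 or GTF via gffutils.

    CDS features must resolve to a gene through a transcript (GFF3
    ``Parent`` chain, or GTF ``gene_id``/``transcript_id`` attributes).
    Genes without CDS are retained with empty transcripts. The gene body is
    the ``gene`` feature span, or the min/max over the gene's transcripts
    when no gene feature exists.
    """
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"dialect must be 'gff3' or 'gtf', got {dialect!r}")
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    # gene features ------------------------------------------------------
    gene_info: Dict[str, dict] = {}
    for g in db.features_of_type("gene"):
        orig_id = g.attributes.get("ID", g.attributes.get("gene_id", [g.id]))[0]
        symbol = g.attributes.get(
            "Name", g.attributes.get("gene_name", [orig_id])
        )[0]
        if orig_id in gene_info:
            prev = gene_info[orig_id]
            if prev["chrom"] != g.seqid:
                raise ValueError(
                    f"gene {orig_id} appears on {prev['chrom']} and {g.seqid}"
                )
            prev["start"] = min(prev["start"], g.start - 1)
            prev["end"] = max(prev["end"], g.end)
        else:
            gene_info[orig_id] = {
                "chrom": g.seqid,
                "start": g.start - 1,
                "end": g.end,
                "strand": g.strand if g.strand in ("+", "-") else ".",
                "symbol": symbol,
            }

    # transcript -> gene -------------------------------------------------
    tx2gene: Dict[str, str] = {}
    tx_span: Dict[str, dict] = {}
    for t in db.features_of_type(("mRNA", "transcript")):
        tid = t.attributes.get(
            "ID", t.attributes.get("transcript_id", [t.id])
        )[0]
        gid: Optional[str] = None
        parents = t.attributes.get("Parent", [])
        if parents:
            gid = parents[0]
        elif "gene_id" in t.attributes:
            gid = t.attributes["gene_id"][0]
        if gid is None:
            raise ValueError(f"transcript {tid} has no parent gene")
        tx2gene[tid] = gid
        tx_span[tid] = {"chrom": t.seqid, "start": t.start - 1, "end": t.end}

    # CDS features -------------------------------------------------------
    cds_by_tx: Dict[str, List[GenomicInterval]] = {}
    for c in db.features_of_type("CDS"):
        if "transcript_id" in c.attributes:  # GTF
            tids = [c.attributes["transcript_id"][0]]
        else:  # GFF3
            tids = list(c.attributes.get("Parent", []))
        if not tids:
            raise ValueError(f"CDS at {c.seqid}:{c.start}-{c.end} has no parent")
        for tid in tids:
            if tid not in tx2gene:
                if "gene_id" in c.attributes:
                    tx2gene[tid] = c.attributes["gene_id"][0]
                elif tid in gene_info:
                    # CDS attached directly to a gene: single implicit transcript
                    tx2gene[tid] = tid
                else:
                    raise ValueError(
                        f"CDS at {c.seqid}:{c.start}-{c.end}: "
                        f"parent {tid} resolves to no gene"
                    )
            cds_by_tx.setdefault(tid, []).append(
                GenomicInterval(c.seqid, c.start - 1, c.end)
            )

    # assemble -----------------------------------------------------------
    gene_tx: Dict[str, Dict[str, List[GenomicInterval]]] = {
        gid: {} for gid in gene_info
    }
    for tid, gid in tx2gene.items():
        if gid not in gene_info:
            span = tx_span.get(tid)
            if span is None:
                exons = cds_by_tx.get(tid, [])
                if not exons:
                    raise ValueError(f"CDS transcript {tid}: gene {gid} unresolvable")
                span = {
                    "chrom": exons[0].chrom,
                    "start": min(e.start for e in exons),
                    "end": max(e.end for e in exons),
                }
            gene_info[gid] = {
                "chrom": span["chrom"],
                "start": span["start"],
                "end": span["end"],
                "strand": ".",
                "symbol": gid,
            }
            gene_tx[gid] = {}
        else:
            info = gene_info[gid]
            span = tx_span.get(tid)
            if span is not None and span["chrom"] != info["chrom"]:
                raise ValueError(
                    f"transcript {tid} on {span['chrom']} but gene {gid} "
                    f"on {info['chrom']}"
                )
        if tid in cds_by_tx:
            gene_tx.setdefault(gid, {})[tid] = sorted(
                cds_by_tx[tid], key=lambda iv: iv.start
            )

    genes: List[GeneModel] = []
    for gid in sorted(gene_info):
        info = gene_info[gid]
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=info["symbol"],
                chrom=info["chrom"],
                strand=info["strand"],
                body=GenomicInterval(info["chrom"], info["start"], info["end"], gid),
                transcripts=gene_tx.get(gid, {}),
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: PathLike) -> None:
    """Emit gene/mRNA/CDS features in GFF3 (1-based closed on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(genes, key=lambda g: (g.chrom, g.body.start, g.gene_id)):
            attrs = f"ID={gene.gene_id};Name={gene.symbol}"
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        "darkcov",
                        "gene",
                        str(gene.body.start + 1),
                        str(gene.body.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for tx_id in sorted(gene.transcripts):
                exons = gene.transcripts[tx_id]
                tx_start = min(e.start for e in exons) if exons else gene.body.start
                tx_end = max(e.end for e in exons) if exons else gene.body.end
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            "darkcov",
                            "mRNA",
                            str(tx_start + 1),
                            str(tx_end),
                            ".",
                            gene.strand,
                            ".",
                            f"ID={tx_id};Parent={gene.gene_id}",
                        ]
                    )
                    + "\n"
                )
                for k, ex in enumerate(sorted(exons, key=lambda e: e.start)):
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom,
                                "darkcov",
                                "CDS",
                                str(ex.start + 1),
                                str(ex.end),
                                ".",
                                gene.strand,
                                "0",
                                f"ID={tx_id}.cds{k};Parent={tx_id}",
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Risk-locus (GRL) tables
# ---------------------------------------------------------------------------

@dataclass
class GrlTableSpec:
    """Column mapping and coordinate convention for a GRL TSV."""

    locus_id: str = "locus_id"
    chrom: str = "chrom"
    start: str = "start"
    end: str = "end"
    genes: str = "mapped_genes"
    gene_sep: str = ":"
    one_based_closed: bool = True


def read_grl_table(path: PathLike, spec: Optional[GrlTableSpec] = None) -> List[RiskLocus]:
    """Read a FUMA-style genomic-risk-locus table.

    One locus per row; the mapped-genes cell is split on ``spec.gene_sep``
    and deduplicated (a warning is logged when duplicates are dropped).
    """
    spec = spec or GrlTableSpec()
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [spec.locus_id, spec.chrom, spec.start, spec.end, spec.genes]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    loci: List[RiskLocus] = []
    offset = 1 if spec.one_based_closed else 0
    for _, row in df.iterrows():
        start = int(row[spec.start]) - offset
        end = int(row[spec.end])
        genes_cell = row[spec.genes]
        gene_ids: List[str] = []
        if isinstance(genes_cell, str) and genes_cell.strip():
            seen: Set[str] = set()
            for g in genes_cell.split(spec.gene_sep):
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    logger.warning(
                        "locus %s: duplicate mapped gene %s dropped",
                        row[spec.locus_id],
                        g,
                    )
                    continue
                seen.add(g)
                gene_ids.append(g)
        loci.append(
            RiskLocus(
                locus_id=str(row[spec.locus_id]),
                span=GenomicInterval(str(row[spec.chrom]), start, end,
                                     str(row[spec.locus_id])),
                mapped_gene_ids=gene_ids,
            )
        )
    return loci


def write_grl_table(loci: Sequence[RiskLocus], path: PathLike,
                    spec: Optional[GrlTableSpec] = None) -> None:
    spec = spec or GrlTableSpec()
    offset = 1 if spec.one_based_closed else 0
    rows = [
        {
            spec.locus_id: l.locus_id,
            spec.chrom: l.span.chrom,
            spec.start: l.span.start + offset,
            spec.end: l.span.end,
            spec.genes: spec.gene_sep.join(l.mapped_gene_ids),
        }
        for l in loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Candidate-gene tables
# ---------------------------------------------------------------------------

def read_gene_table(path: PathLike) -> List[GeneRecord]:
    """Read a headered TSV of per-gene statistics (gene_id required;
    p_value, q_value, category optional)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'gene_id'")
    records: List[GeneRecord] = []
    for _, row in df.iterrows():
        def _num(col: str) -> Optional[float]:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        category = None
        if "category" in df.columns and not pd.isna(row["category"]):
            category = str(row["category"])
        records.append(
            GeneRecord(
                gene_id=str(row["gene_id"]),
                p_value=_num("p_value"),
                q_value=_num("q_value"),
                category=category,
            )
        )
    return records


def write_gene_table(records: Sequence[GeneRecord], path: PathLike) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "category": r.category,
        }
        for r in sorted(records, key=lambda r: r.gene_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Term maps (GMT / two-column TSV)
# ---------------------------------------------------------------------------

def read_term_map(path: PathLike, format: str = "gmt") -> TermMap:
    """Read a term->genes map.

    ``gmt``: one term per line — term, description, gene, gene, ...
    ``tsv``: two columns per line — term_id, gene_id (no header).
    """
    terms: Dict[str, Set[str]] = {}
    descriptions: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "gmt":
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: GMT line needs term, description, >=1 gene"
                    )
                term, desc, genes = fields[0], fields[1], fields[2:]
                terms.setdefault(term, set()).update(g for g in genes if g)
                if desc:
                    descriptions[term] = desc
            elif format == "tsv":
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected term_id<TAB>gene_id")
                terms.setdefault(fields[0], set()).add(fields[1])
            else:
                raise ValueError(f"term-map format must be 'gmt' or 'tsv', got {format!r}")
    return TermMap(terms={t: frozenset(g) for t, g in terms.items()},
                   descriptions=descriptions)


def write_gmt(term_map: TermMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        for term in sorted(term_map.terms):
            desc = term_map.descriptions.get(term, "na")
            genes = sorted(term_map.terms[term])
            fh.write("\t".join([term, desc] + genes) + "\n")


# ---------------------------------------------------------------------------
# Generic TSV output
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: PathLike,
              sort_by: Optional[Sequence[str]] = None) -> None:
    """Write a DataFrame as TSV with deterministic row order."""
    if sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Chromosome-name handling
# ---------------------------------------------------------------------------

def strip_chr_prefix_interval(iv: GenomicInterval) -> GenomicInterval:
    chrom = iv.chrom[3:] if iv.chrom.startswith("chr") else iv.chrom
    return GenomicInterval(chrom, iv.start, iv.end, iv.name)


def chromosome_overlap_report(named_sets: Dict[str, Set[str]]) -> pd.DataFrame:
    """Pairwise shared-chromosome counts across inputs.

    A zero in the ``shared`` column flags a naming mismatch (e.g. ``chr1``
    vs ``1``) that would otherwise surface only as silent zero overlap.
    """
    names = sorted(named_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append(
                {
                    "input_a": a,
                    "input_b": b,
                    "n_a": len(named_sets[a]),
                    "n_b": len(named_sets[b]),
                    "shared": len(named_sets[a] & named_sets[b]),
                }
            )
    return pd.DataFrame(rows, columns=["input_a", "input_b", "n_a", "n_b", "shared"])
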