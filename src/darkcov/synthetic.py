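"""Synthetic cohort generator with exact, machine-readable ground truth.

The generator emulates the external inputs of a dark-region study — a dark
catalog (BED), gene models (GFF3), a risk-locus table with precomputed
mapped genes, a candidate-gene table with categories and q-values, and a
term map with one planted enriched term — on a toy multi-chromosome
genome, so every pipeline stage can be tested without any download.

Planted per-gene dark-CDS fractions are *exact*: every coding gene's CDS
union has a fixed integer length (default 1000 bp), targets are validated
to be realizable in whole base pairs (0.077 -> exactly 77 bp), and dark
intervals are placed deterministically inside the CDS to hit them. Noise
dark intervals are confined to intergenic gaps so gene truth is never
perturbed; locus-level truth is then computed by the generator itself with
the same interval engine the pipeline uses (an independent per-base oracle
cross-checks both in the test suite).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import io as dio
from .enrich import enrich
from .intervals import GenomicInterval, count_source_overlaps, normalize
from .models import GeneModel, GeneRecord, RiskLocus, TermMap

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "generate_null_study",
    "NullEnrichmentConfig",
    "simulate_null_type1",
    "simulate_term_recovery",
]

# Default planted dark-CDS fractions (gene index -> fraction of the CDS
# union). The 0.077 / 0.004 / 0.73 entries mirror the regimes reported for
# well-known partially dark disease genes (a mostly-callable gene with a
# handful of dark exons, a nearly clean gene, and a heavily duplicated one).
DEFAULT_CDS_DARK_TARGETS: Dict[int, float] = {
    0: 0.077,
    5: 0.004,
    10: 0.73,
    15: 0.05,
    20: 0.20,
    25: 0.25,
    30: 0.10,
    35: 0.50,
    40: 1.0,
    45: 0.006,
}

# Intron-only dark bp: genes dark in the body but with a clean CDS.
DEFAULT_INTRON_DARK_BP: Dict[int, int] = {2: 200, 12: 350, 22: 200, 42: 150, 52: 450}

DEFAULT_NONCODING_GENES: Tuple[int, ...] = (58, 59)

CATEGORY_CYCLE: Tuple[Optional[str], ...] = (
    "Score1",
    "Score3",
    "Syndromic",
    None,
    "Score2",
)


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    The defaults define a 3-chromosome toy genome with 60 genes and 12 risk
    loci; dark-CDS targets include the 7.7%, 0.4% and 73% regimes.
    """

    n_chromosomes: int = 3
    chrom_length: int = 1_000_000
    n_genes: int = 60
    n_loci: int = 12
    gene_body_len: int = 5_000
    cds_len: int = 1_000
    n_cds_exons: int = 5
    cds_dark_targets: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CDS_DARK_TARGETS)
    )
    intron_dark_bp: Dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_INTRON_DARK_BP)
    )
    noncoding_genes: Tuple[int, ...] = DEFAULT_NONCODING_GENES
    n_noise_dark: int = 30
    noise_dark_len: Tuple[int, int] = (50, 400)
    locus_pad: int = 500
    # term map
    n_null_terms: int = 25
    null_term_size: int = 8
    planted_term: str = "T_PLANTED"
    term_effect: float = 0.9  # P(membership) for dark mapped genes
    term_background: float = 0.05  # P(membership) for other genes
    min_planted_members: int = 3
    # stratification planting: (category, n_genes, n_dark) in the top q-bin
    planted_cell_category: str = "Score2"
    planted_cell_n: int = 5
    planted_cell_n_dark: int = 3
    strat_bins: Tuple[float, float] = (0.1, 0.3)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_chromosomes < 1 or self.n_loci < 1:
            raise ValueError("n_genes, n_chromosomes and n_loci must be positive")
        if self.cds_len % self.n_cds_exons:
            raise ValueError("cds_len must be divisible by n_cds_exons")
        exon_len = self.cds_len // self.n_cds_exons
        if 500 + (self.n_cds_exons - 1) * (exon_len + 700) + exon_len > self.gene_body_len:
            raise ValueError("gene_body_len too small for the CDS exon layout")
        for idx, frac in self.cds_dark_targets.items():
            if idx >= self.n_genes or idx in self.noncoding_genes:
                raise ValueError(f"dark-CDS target on invalid gene index {idx}")
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"dark-CDS target {frac} outside [0,1]")
            bp = frac * self.cds_len
            if abs(bp - round(bp)) > 1e-9:
                raise ValueError(
                    f"target {frac} is not realizable in whole bp on a "
                    f"{self.cds_len} bp CDS"
                )
        for idx, bp in self.intron_dark_bp.items():
            if idx >= self.n_genes:
                raise ValueError(f"intron-dark on invalid gene index {idx}")
            if idx in self.cds_dark_targets:
                raise ValueError(
                    f"gene {idx}: intron-only dark and a CDS target both set"
                )
            if not 0 < bp <= 450:
                raise ValueError("intron_dark_bp must be in (0, 450]")

    @property
    def dark_body_gene_indices(self) -> Set[int]:
        return {i for i, f in self.cds_dark_targets.items() if f > 0} | set(
            self.intron_dark_bp
        )


@dataclass
class SyntheticCohort:
    """In-memory cohort plus its ground truth (JSON-serializable dict)."""

    config: CohortConfig
    seed: int
    genes: List[GeneModel]
    dark_records: List[GenomicInterval]
    loci: List[RiskLocus]
    gene_records: List[GeneRecord]
    term_map: TermMap
    truth: dict


def _gene_layout(cfg: CohortConfig) -> List[Tuple[str, int]]:
    """(chrom, body_start) per gene index; genes evenly slotted."""
    per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)  # ceil
    slot = cfg.chrom_length // per_chrom
    if slot < cfg.gene_body_len + 2 * cfg.locus_pad + 100:
        raise ValueError("chrom_length too small for the requested gene count")
    layout = []
    for idx in range(cfg.n_genes):
        c, s = divmod(idx, per_chrom)
        chrom = f"chr{c + 1}"
        layout.append((chrom, s * slot + cfg.locus_pad + 100))
    return layout


def _build_gene(
    cfg: CohortConfig, idx: int, chrom: str, body_start: int
) -> GeneModel:
    gid = f"G{idx + 1:04d}"
    body = GenomicInterval(chrom, body_start, body_start + cfg.gene_body_len, gid)
    transcripts: Dict[str, List[GenomicInterval]] = {}
    if idx not in cfg.noncoding_genes:
        exon_len = cfg.cds_len // cfg.n_cds_exons
        exons = [
            GenomicInterval(
                chrom,
                body_start + 500 + j * (exon_len + 700),
                body_start + 500 + j * (exon_len + 700) + exon_len,
            )
            for j in range(cfg.n_cds_exons)
        ]
        transcripts[f"{gid}.t1"] = exons
        if idx % 2 == 0 and cfg.n_cds_exons >= 3:
            # second isoform: middle exons, first of them 5'-truncated;
            # the CDS union is unchanged (subset of the t1 exons)
            sub = exons[1 : min(4, cfg.n_cds_exons)]
            trunc = GenomicInterval(
                chrom, sub[0].start + exon_len // 4, sub[0].end
            )
            transcripts[f"{gid}.t2"] = [trunc] + list(sub[1:])
    strand = "+" if idx % 3 else "-"
    return GeneModel(
        gene_id=gid,
        symbol=f"GENE{idx + 1}",
        chrom=chrom,
        strand=strand,
        body=body,
        transcripts=transcripts,
    )


def _plant_gene_dark(
    cfg: CohortConfig, idx: int, gene: GeneModel
) -> List[GenomicInterval]:
    """Dark records inside one gene hitting its planted targets exactly."""
    records: List[GenomicInterval] = []
    target = cfg.cds_dark_targets.get(idx, 0.0)
    if target > 0:
        remaining = round(target * cfg.cds_len)
        exons = sorted(
            normalize(
                [ex for tx in gene.transcripts.values() for ex in tx]
            ).to_intervals(),
            key=lambda e: e.start,
        )
        for k, ex in enumerate(exons):
            if remaining <= 0:
                break
            take = min(remaining, ex.length)
            records.append(
                GenomicInterval(
                    gene.chrom, ex.start, ex.start + take, f"{gene.gene_id}_cds_dark{k}"
                )
            )
            remaining -= take
        assert remaining == 0
    intron_bp = cfg.intron_dark_bp.get(idx, 0)
    if intron_bp:
        # the first 500 bp of the body precede every CDS exon
        start = gene.body.start + 20
        records.append(
            GenomicInterval(
                gene.chrom, start, start + intron_bp, f"{gene.gene_id}_intron_dark"
            )
        )
    return records


def _build_loci(
    cfg: CohortConfig, genes: List[GeneModel]
) -> List[RiskLocus]:
    """Consecutive gene blocks per chromosome; the last gene of each block
    is left unmapped and outside the locus, and the locus right edge cuts
    into its last mapped gene (gene statistics stay gene-level)."""
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    chroms = sorted(by_chrom)
    base, extra = divmod(cfg.n_loci, len(chroms))
    loci: List[RiskLocus] = []
    locus_no = 0
    for ci, chrom in enumerate(chroms):
        n_loci_here = base + (1 if ci < extra else 0)
        gs = by_chrom[chrom]
        if n_loci_here == 0:
            continue
        block = max(1, len(gs) // n_loci_here)
        for j in range(n_loci_here):
            locus_no += 1
            members = gs[j * block : (j + 1) * block]
            if not members:
                continue
            mapped = members[:-1] if len(members) > 1 else members
            span_start = max(0, mapped[0].body.start - cfg.locus_pad)
            last = mapped[-1]
            if len(members) > 1:
                span_end = last.body.end - cfg.gene_body_len // 2
            else:
                span_end = last.body.end + cfg.locus_pad
            loci.append(
                RiskLocus(
                    locus_id=f"L{locus_no:03d}",
                    span=GenomicInterval(chrom, span_start, span_end, f"L{locus_no:03d}"),
                    mapped_gene_ids=[g.gene_id for g in mapped],
                )
            )
    return loci


def _place_noise_dark(
    cfg: CohortConfig,
    genes: List[GeneModel],
    rng: np.random.Generator,
) -> List[GenomicInterval]:
    """Intergenic dark records, never overlapping any gene body."""
    bodies = normalize([g.body for g in genes])
    per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)
    records: List[GenomicInterval] = []
    lo, hi = cfg.noise_dark_len
    n_chroms_used = -(-cfg.n_genes // per_chrom)
    attempts = 0
    while len(records) < cfg.n_noise_dark and attempts < cfg.n_noise_dark * 50:
        attempts += 1
        chrom = f"chr{int(rng.integers(1, n_chroms_used + 1))}"
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, cfg.chrom_length - length))
        cand = GenomicInterval(chrom, start, start + length)
        if normalize([cand]).intersect_length(bodies) == 0:
            records.append(
                GenomicInterval(
                    chrom, start, start + length, f"noise{len(records) + 1}"
                )
            )
    if len(records) < cfg.n_noise_dark:
        raise RuntimeError("could not place the requested intergenic dark records")
    return records


def _assign_gene_records(
    cfg: CohortConfig,
    genes: List[GeneModel],
    dark_idx: Set[int],
    rng: np.random.Generator,
) -> Tuple[List[GeneRecord], List[dict]]:
    """Categories and q-values with one exactly planted stratification cell.

    The planted cell is (planted_cell_category, top q-bin) with
    planted_cell_n genes of which planted_cell_n_dark are dark-body; no
    other gene of that category receives a q-value above the top breakpoint,
    so the cell proportion is exact by construction.
    """
    top = cfg.strat_bins[-1]
    dark_sorted = sorted(dark_idx)
    nondark_sorted = [i for i in range(cfg.n_genes) if i not in dark_idx]
    # clamp to what the dark plan makes realizable (a zero-dark cohort
    # simply gets an all-non-dark planted cell)
    n_cell_dark = min(cfg.planted_cell_n_dark, len(dark_sorted))
    if len(nondark_sorted) < cfg.planted_cell_n - n_cell_dark:
        raise ValueError("planted stratification cell is not realizable")
    planted = dark_sorted[:n_cell_dark] + nondark_sorted[
        : cfg.planted_cell_n - n_cell_dark
    ]
    planted_set = set(planted)
    records: List[GeneRecord] = []
    truth_rows: List[dict] = []
    cycle_pos = 0
    for i, gene in enumerate(genes):
        if i in planted_set:
            category: Optional[str] = cfg.planted_cell_category
            q: Optional[float] = round(
                float(top + (1 - top) * (0.2 + 0.6 * rng.random())), 6
            )
        else:
            category = CATEGORY_CYCLE[cycle_pos % len(CATEGORY_CYCLE)]
            cycle_pos += 1
            if i % 13 == 7:
                q = None  # unscored
            elif category == cfg.planted_cell_category:
                # keep the planted top-bin cell exact
                q = round(float(rng.uniform(0, cfg.strat_bins[-1] * 0.99)), 6)
            else:
                q = round(float(rng.random()), 6)
        records.append(GeneRecord(gene_id=gene.gene_id, q_value=q, category=category))
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "category": category,
                "q_value": q,
                "dark_body": i in dark_idx,
            }
        )
    return records, truth_rows


def _strat_bin_label(q: Optional[float], bins: Sequence[float]) -> str:
    if q is None:
        return "unscored"
    if q < bins[0]:
        return f"<{bins[0]:g}"
    if bins[0] <= q <= bins[1]:
        return f"{bins[0]:g}-{bins[1]:g}"
    return f">{bins[1]:g}"


def _build_term_map(
    cfg: CohortConfig,
    genes: List[GeneModel],
    dark_mapped: List[str],
    rng: np.random.Generator,
) -> TermMap:
    all_ids = [g.gene_id for g in genes]
    other = [g for g in all_ids if g not in set(dark_mapped)]
    members: Set[str] = {
        g for g in dark_mapped if rng.random() < cfg.term_effect
    }
    members |= {g for g in other if rng.random() < cfg.term_background}
    for g in list(dark_mapped) + all_ids:  # top up tiny planted terms
        if len(members) >= cfg.min_planted_members:
            break
        members.add(g)
    terms: Dict[str, frozenset] = {cfg.planted_term: frozenset(members)}
    descriptions = {cfg.planted_term: "planted enriched term"}
    for t in range(cfg.n_null_terms):
        tid = f"T{t + 1:03d}"
        size = min(cfg.null_term_size, len(all_ids))
        terms[tid] = frozenset(
            rng.choice(all_ids, size=size, replace=False).tolist()
        )
        descriptions[tid] = "background term"
    return TermMap(terms=terms, descriptions=descriptions)


def generate_cohort(config: Optional[CohortConfig] = None, seed: int = 0) -> SyntheticCohort:
    """Build a full synthetic cohort; deterministic for a fixed seed."""
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    layout = _gene_layout(cfg)
    genes = [
        _build_gene(cfg, i, chrom, start) for i, (chrom, start) in enumerate(layout)
    ]
    dark_records: List[GenomicInterval] = []
    for i, gene in enumerate(genes):
        dark_records.extend(_plant_gene_dark(cfg, i, gene))
    loci = _build_loci(cfg, genes)
    dark_records.extend(_place_noise_dark(cfg, genes, rng))

    dark_set = normalize(dark_records)
    # ----- gene truth (from planted integers; engine only for body overlap)
    gene_truth: Dict[str, dict] = {}
    for i, gene in enumerate(genes):
        coding = i not in cfg.noncoding_genes
        cds_dark = round(cfg.cds_dark_targets.get(i, 0.0) * cfg.cds_len) if coding else 0
        body_dark = cds_dark + cfg.intron_dark_bp.get(i, 0)
        cds_len = cfg.cds_len if coding else 0
        frac = cfg.cds_dark_targets.get(i, 0.0) if coding else None
        gene_truth[gene.gene_id] = {
            "body_len": cfg.gene_body_len,
            "body_dark_bp": body_dark,
            "body_dark_frac": body_dark / cfg.gene_body_len,
            "cds_len": cds_len,
            "cds_dark_bp": cds_dark,
            "cds_dark_frac": frac,
            "any_dark_body": body_dark > 0,
            "any_dark_cds": cds_dark > 0,
            "dark_cds_gt5": coding and cds_dark / cfg.cds_len > 0.05,
            "dark_cds_gt20": coding and cds_dark / cfg.cds_len > 0.20,
        }

    # ----- locus truth (shared interval engine; per-base oracle in tests)
    locus_truth: Dict[str, dict] = {}
    for locus in loci:
        bp = normalize([locus.span]).intersect_length(dark_set)
        locus_truth[locus.locus_id] = {
            "n_dark_records": count_source_overlaps(dark_records, locus.span),
            "dark_bp": bp,
            "is_dark": bp > 0,
            "mapped_genes": list(locus.mapped_gene_ids),
        }

    # ----- cohort truth over the deduplicated mapped-gene universe
    mapped_ids: List[str] = []
    seen: Set[str] = set()
    for locus in loci:
        for gid in locus.mapped_gene_ids:
            if gid not in seen:
                seen.add(gid)
                mapped_ids.append(gid)
    mt = [gene_truth[g] for g in mapped_ids]
    cohort_truth = {
        "n_loci": len(loci),
        "n_loci_dark": sum(1 for l in locus_truth.values() if l["is_dark"]),
        "total_locus_dark_bp": sum(l["dark_bp"] for l in locus_truth.values()),
        "n_genes": len(mapped_ids),
        "n_genes_dark_body": sum(1 for t in mt if t["any_dark_body"]),
        "gene_dark_bp_total": sum(t["body_dark_bp"] for t in mt),
        "n_any_dark_cds": sum(1 for t in mt if t["any_dark_cds"]),
        "n_dark_cds_gt5": sum(1 for t in mt if t["dark_cds_gt5"]),
        "n_dark_cds_gt20": sum(1 for t in mt if t["dark_cds_gt20"]),
    }
    cohort_truth["pct_loci_dark"] = (
        100.0 * cohort_truth["n_loci_dark"] / cohort_truth["n_loci"]
    )
    cohort_truth["pct_genes_dark_body"] = (
        100.0 * cohort_truth["n_genes_dark_body"] / cohort_truth["n_genes"]
    )

    # ----- candidate-gene table + stratification truth
    dark_idx = cfg.dark_body_gene_indices
    gene_records, record_truth = _assign_gene_records(cfg, genes, dark_idx, rng)
    cells: Dict[Tuple[str, str], Dict[str, int]] = {}
    for row in record_truth:
        cat = row["category"] if row["category"] is not None else "uncategorized"
        cell = cells.setdefault(
            (cat, _strat_bin_label(row["q_value"], cfg.strat_bins)),
            {"n_genes": 0, "n_dark": 0},
        )
        cell["n_genes"] += 1
        cell["n_dark"] += int(row["dark_body"])
    strat_truth = [
        {
            "category": cat,
            "q_bin": qbin,
            "n_genes": c["n_genes"],
            "n_dark": c["n_dark"],
            "proportion_dark": c["n_dark"] / c["n_genes"],
        }
        for (cat, qbin), c in sorted(cells.items())
    ]

    # ----- term map
    dark_mapped = [g for g in mapped_ids if gene_truth[g]["any_dark_body"]]
    term_map = _build_term_map(cfg, genes, dark_mapped, rng)

    truth = {
        "seed": seed,
        "config": _config_to_dict(cfg),
        "genes": gene_truth,
        "loci": locus_truth,
        "cohort": cohort_truth,
        "stratification": strat_truth,
        "enrichment": {
            "planted_term": cfg.planted_term,
            "planted_term_size": len(term_map.terms[cfg.planted_term]),
            "dark_mapped_genes": dark_mapped,
            "effect": cfg.term_effect,
            "background": cfg.term_background,
        },
        "gene_records": record_truth,
    }
    return SyntheticCohort(
        config=cfg,
        seed=seed,
        genes=genes,
        dark_records=dark_records,
        loci=loci,
        gene_records=gene_records,
        term_map=term_map,
        truth=truth,
    )


def _config_to_dict(cfg: CohortConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["cds_dark_targets"] = {str(k): v for k, v in cfg.cds_dark_targets.items()}
    d["intron_dark_bp"] = {str(k): v for k, v in cfg.intron_dark_bp.items()}
    d["noncoding_genes"] = list(cfg.noncoding_genes)
    return d


def write_cohort(cohort: SyntheticCohort, outdir) -> Dict[str, Path]:
    """Write dark.bed, genes.gff3, grl.tsv, genes_table.tsv, terms.gmt and
    truth.json; byte-identical for identical cohorts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dark": outdir / "dark.bed",
        "genes": outdir / "genes.gff3",
        "grl": outdir / "grl.tsv",
        "gene_table": outdir / "genes_table.tsv",
        "terms": outdir / "terms.gmt",
        "truth": outdir / "truth.json",
    }
    dio.write_bed(cohort.dark_records, paths["dark"])
    dio.write_gff3(cohort.genes, paths["genes"])
    dio.write_grl_table(cohort.loci, paths["grl"])
    dio.write_gene_table(cohort.gene_records, paths["gene_table"])
    dio.write_gmt(cohort.term_map, paths["terms"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# Null and power simulations for the enrichment engine
# ---------------------------------------------------------------------------

def generate_null_study(
    universe: Sequence[str], study_size: int, seed: int
) -> List[str]:
    """Uniform sample of genes without replacement; deterministic per seed."""
    universe = list(universe)
    if study_size > len(universe):
        raise ValueError("study_size exceeds the universe")
    rng = np.random.default_rng(seed)
    if study_size == 0:
        return []
    return rng.choice(universe, size=study_size, replace=False).tolist()


@dataclass
class NullEnrichmentConfig:
    """Sizes for the null-calibration simulation.

    Chosen so the attainable level of the (discrete) hypergeometric test
    nearest 0.05 is close to 0.05: universe 1500, study 150, terms of 80.
    """

    universe_size: int = 1500
    study_size: int = 150
    n_terms: int = 30
    term_size: int = 80


def simulate_null_type1(
    n_draws: int,
    seed: int,
    config: Optional[NullEnrichmentConfig] = None,
    alpha: float = 0.05,
) -> float:
    """Fraction of (draw, term) tests with p < alpha under the null."""
    cfg = config or NullEnrichmentConfig()
    rng = np.random.default_rng(seed)
    universe = [f"U{i:05d}" for i in range(cfg.universe_size)]
    terms = {
        f"N{t:03d}": frozenset(
            rng.choice(universe, size=cfg.term_size, replace=False).tolist()
        )
        for t in range(cfg.n_terms)
    }
    term_map = TermMap(terms=terms)
    hits = 0
    total = 0
    for d in range(n_draws):
        study = generate_null_study(
            universe, cfg.study_size, seed=int(rng.integers(0, 2**31 - 1))
        )
        for res in enrich(study, universe, term_map, min_term_size=1):
            total += 1
            hits += res.p_value < alpha
    return hits / total


def simulate_term_recovery(
    n_replicates: int,
    seed: int,
    config: Optional[CohortConfig] = None,
) -> float:
    """Fraction of replicates in which the planted term attains the
    uniquely smallest q-value in the dark-vs-genome contrast.

    The cohort's gene/dark structure is fixed by the config; the term map
    (planted membership and background terms) is redrawn per replicate.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    base = generate_cohort(cfg, seed=seed)
    universe = [g.gene_id for g in base.genes]
    dark_mapped = base.truth["enrichment"]["dark_mapped_genes"]
    rng = np.random.default_rng(seed + 1)
    wins = 0
    for _ in range(n_replicates):
        term_map = _build_term_map(cfg, base.genes, dark_mapped, rng)
        results = enrich(dark_mapped, universe, term_map, min_term_size=1)
        best_q = min(r.q_value for r in results)
        winners = {r.term_id for r in results if r.q_value == best_q}
        wins += winners == {cfg.planted_term}
    return wins / n_replicates
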