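"""Test dark gene sets for term over-representation.

Two contrasts: (A) mapped genes with any dark body against all annotated
genes, and (B) mapped genes with dark CDS against the remaining mapped
genes. The generator planted one term preferentially annotated to the dark
genes; it should dominate contrast A and be FDR-significant. Writes one
TSV per contrast under results/.
"""

from pathlib import Path

from darkcov import io as dio
from darkcov.annotate import annotate_genes, summarize_cohort
from darkcov.enrich import run_contrasts
from darkcov.intervals import normalize
from darkcov.pipeline import contrast_frame

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"


def main() -> None:
    if not (COHORT / "dark.bed").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    dark_records = dio.read_bed(COHORT / "dark.bed")
    genes = dio.read_gene_models(COHORT / "genes.gff3")
    loci = dio.read_grl_table(COHORT / "grl.tsv")
    terms = dio.read_term_map(COHORT / "terms.gmt", format="gmt")

    reports = annotate_genes(genes, normalize(dark_records))
    _, mapped_reports = summarize_cohort(loci, genes, dark_records, reports=reports)
    outcomes = run_contrasts(
        reports, list(mapped_reports), [g.gene_id for g in genes], terms
    )
    for name, outcome in outcomes.items():
        out = ROOT / "results" / f"enrichment_{name}.tsv"
        dio.write_tsv(contrast_frame(outcome), out)
        print(f"wrote {out} (study n={outcome.study_size}, "
              f"universe N={outcome.universe_size})")
        for r in outcome.results[:3]:
            print(f"  {r.term_id}: k={r.k}/{r.n}, K={r.K}/{r.N}, "
                  f"p={r.p_value:.3g}, q={r.q_value:.3g}")


if __name__ == "__main__":
    main()
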