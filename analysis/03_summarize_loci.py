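"""Summarize dark-region overlap per risk locus and for the whole cohort.

For each locus: how many dark catalog records touch it (record counts on
the unmerged catalog) and how many of its bases are dark (on the merged
catalog). The cohort row aggregates these with the mapped-gene dark-CDS
class counts — the same shape as a per-disorder summary row in a GWAS
dark-region survey. Writes results/locus_summary.tsv and
results/cohort_summary.tsv.
"""

from pathlib import Path

from darkcov import io as dio
from darkcov.annotate import (
    cohort_summary_frame,
    locus_summary_frame,
    summarize_cohort,
    summarize_loci,
)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"


def main() -> None:
    if not (COHORT / "dark.bed").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    dark_records = dio.read_bed(COHORT / "dark.bed")
    genes = dio.read_gene_models(COHORT / "genes.gff3")
    loci = dio.read_grl_table(COHORT / "grl.tsv")

    locus_sum = summarize_loci(loci, dark_records)
    cohort, _ = summarize_cohort(loci, genes, dark_records)

    dio.write_tsv(locus_summary_frame(locus_sum), ROOT / "results" / "locus_summary.tsv",
                  sort_by=["locus_id"])
    dio.write_tsv(cohort_summary_frame(cohort), ROOT / "results" / "cohort_summary.tsv")
    print(f"wrote {ROOT / 'results' / 'locus_summary.tsv'}")
    print(f"wrote {ROOT / 'results' / 'cohort_summary.tsv'}")
    print(f"{cohort.n_loci_dark}/{cohort.n_loci} loci dark "
          f"({cohort.pct_loci_dark:.1f}%), {cohort.total_locus_dark_bp} bp of "
          f"locus sequence dark")
    print(f"{cohort.n_genes_dark_body}/{cohort.n_genes} mapped genes dark "
          f"({cohort.pct_genes_dark_body:.1f}%); dark-CDS classes "
          f"any/{cohort.n_any_dark_cds} >5%/{cohort.n_dark_cds_gt5} "
          f">20%/{cohort.n_dark_cds_gt20}")


if __name__ == "__main__":
    main()
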