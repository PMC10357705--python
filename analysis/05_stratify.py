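"""Stratify candidate genes by category and association q-value.

Partitions the candidate-gene table into q-value bins [0, 0.1), [0.1, 0.3],
(0.3, 1] crossed with the confidence category, and reports the proportion
of dark-body genes per cell. The generator planted one exact cell
(category Score2, q > 0.3, proportion 0.6) mimicking the observation that
weakly associated strong candidates are enriched for dark gene bodies.
Writes results/stratification.tsv.
"""

from pathlib import Path

from darkcov import io as dio
from darkcov.annotate import annotate_genes
from darkcov.intervals import normalize
from darkcov.stratify import stratify

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"


def main() -> None:
    if not (COHORT / "dark.bed").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    dark_records = dio.read_bed(COHORT / "dark.bed")
    genes = dio.read_gene_models(COHORT / "genes.gff3")
    records = dio.read_gene_table(COHORT / "genes_table.tsv")

    reports = annotate_genes(genes, normalize(dark_records))
    table = stratify(records, reports)
    out = ROOT / "results" / "stratification.tsv"
    dio.write_tsv(table, out)
    print(f"wrote {out}")
    for r in table.itertuples():
        print(f"  {r.category:>13s}  q {r.q_bin:>8s}: "
              f"{r.n_dark}/{r.n_genes} dark ({100 * r.proportion_dark:.0f}%)")


if __name__ == "__main__":
    main()
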