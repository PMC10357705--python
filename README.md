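# darkcov

Quantifying how much of the disease-relevant genome is "dark" to
short-read sequencing, and what that costs gene discovery.

## The problem

Short-read sequencing (SRS) cannot confidently call variants everywhere:
some regions attract too few mappable reads ("dark by depth"), others only
multi-mapping reads from duplicated sequence ("dark by alignment"). If a
causal variant sits in such a dark region, fine-mapping of a GWAS locus or
a rare-variant exome study will simply never see it — a silent contributor
to missing heritability. `darkcov` measures that exposure for three kinds
of input:

* **Genomic risk loci (GRLs)** — genome-wide-significant GWAS regions with
  precomputed mapped genes (MGs): how many loci contain dark regions, how
  many dark base pairs they hold.
* **Genes** — for each gene, the dark fraction of its body and of its
  **CDS union** (merged coding exons across all transcripts), with genes
  classified as any / > 5% / > 20% dark-CDS (strict inequalities).
* **Candidate-gene tables** — SCHEMA/ASC/SFARI-style per-gene statistics,
  stratified by confidence category × association q-value bin, reporting
  the dark-gene proportion per cell.

Dark gene sets are tested for term over-representation with the one-sided
hypergeometric test: for a study set of *n* genes in a universe of *N*, a
term annotated to *K* universe genes and *k* study genes gets
*p* = P(X ≥ k), X ~ Hypergeometric(N, K, n), with Benjamini–Hochberg
q-values across terms. Two contrasts are wired in: dark-body mapped genes
vs the whole annotation, and dark-CDS mapped genes vs the remaining mapped
genes.

Because the real inputs of such a study (a dark-region catalog, GWAS
annotations, gene models, a term database) are external, the package ships
a first-class **synthetic cohort generator**: a toy multi-chromosome
genome whose dark intervals are planted to hit exact per-gene dark-CDS
fractions (e.g. 7.7%, 0.4%, 73% — the regimes of well-known partially dark
disease genes), with a machine-readable `truth.json` covering every
downstream quantity. The entire pipeline is validated by zero-tolerance
recovery of that truth and by per-base brute-force oracles.

## Worked example

```sh
darkcov simulate --seed 1 --out results/cohort
darkcov run-all \
    --dark-bed results/cohort/dark.bed \
    --gene-models results/cohort/genes.gff3 \
    --grl-table results/cohort/grl.tsv \
    --gene-table results/cohort/genes_table.tsv \
    --term-map results/cohort/terms.gmt \
    --out results/run
```

or, as an analysis walk-through, `python analysis/01_simulate.py` …
`05_stratify.py`. Step 02 prints:

```
most dark-CDS genes:
  GENE41: CDS 100.0% dark (1000/1000 bp), body 20.00% dark
  GENE11: CDS 73.0% dark (730/1000 bp), body 14.60% dark
  GENE36: CDS 50.0% dark (500/1000 bp), body 10.00% dark
  GENE26: CDS 25.0% dark (250/1000 bp), body 5.00% dark
  GENE21: CDS 20.0% dark (200/1000 bp), body 4.00% dark
classes: any=10, >5%=7, >20%=4
```

Each line is a gene's dark-CDS percentage (dark bp over the 1000 bp CDS
union) — exactly the planted fractions. `GENE21` at exactly 20% is *not*
in the > 20% class: the thresholds are strict. Step 03 aggregates the
cohort (12/12 loci dark, 7643 bp of dark sequence under loci; 15/48 mapped
genes dark-bodied), step 04 shows the planted term dominating the
dark-vs-genome contrast (q ≈ 5e-13 against null terms at q ≥ 0.24), and
step 05 recovers the planted stratification cell (Score2, q > 0.3:
3/5 dark).

Outputs are TSVs plus a `run_manifest.json` with input hashes and
chromosome-name overlap diagnostics, so reruns are byte-identical and a
`chr1`-vs-`1` naming mismatch can never silently produce zero overlap.

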