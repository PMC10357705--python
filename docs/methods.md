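# Methods

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open; every length is
`end − start`. BED passes through verbatim; GFF3/GTF (1-based closed) and
locus tables (1-based closed by default, declarable per input) are
converted on read. Interval sets are kept per chromosome as sorted, merged
arrays; book-ended intervals are merged (coverage semantics — every
statistic here is a base-pair length or a presence test), while *record*
counts ("how many dark catalog entries touch this locus") are taken on the
unmerged catalog via `count_source_overlaps`, counting one per
(record, locus) pair with half-open overlap semantics (a record ending
exactly where a locus starts does not overlap). Algorithms are sort +
linear sweep, O(n log n); all queries are batch, so no interval tree is
used. Strand is ignored throughout: dark regions are mappability
artifacts and carry no strand. The engine is validated against a per-base
boolean-array brute force on randomized toy chromosomes (exact equality,
500 instances in the acceptance suite).

## Gene scoring

The CDS of a gene is, by default, the **union** of CDS exons over all of
its transcripts — the most inclusive defensible definition of a gene's
protein-coding footprint; `cds-mode: longest` restricts to the transcript
with the largest merged CDS instead. Dark fractions are
`dark_bp / length` carried at full precision; reports round only at the
presentation layer. Threshold classes use strict inequalities (> 5%,
> 20%), so a gene at exactly 5.000% dark-CDS is not in the > 5% class.
Genes without CDS are retained for gene-body statistics and report an NA
dark-CDS fraction. Gene statistics are gene-level, not locus-clipped: a
mapped gene partially outside its locus contributes its full body and
CDS, since the mapped-gene columns of a cohort summary are per-gene
quantities; locus bp columns are locus-clipped by construction, and the
cohort row reports both a gene-level and a locus-clipped gene dark-bp
total. A gene mapped by two loci counts once (the mapped-gene universe is
deduplicated); mapped ids that resolve to no gene model are logged and
counted, never fatal.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
(Fisher's exact enrichment tail), delegated to `scipy.stats.hypergeom.sf`
(log-space internally); the test suite verifies it against exhaustive
binomial-coefficient enumeration for every parameter combination with
N ≤ 30. Benjamini–Hochberg q-values come from
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`, verified
against a direct transcription of the step-up definition. Defaults:
`min_term_size = 3` after restriction to the universe; no upper size
filter; no term-hierarchy propagation (the term map is taken as given —
parent propagation belongs to term-map preparation). The "vs genome"
universe is all genes in the supplied annotation, keeping the background
an explicit input rather than an artifact of the term map. An empty study
set in a wired contrast yields an explicit "no study genes" outcome; an
empty study passed to `enrich` directly is an error.

## Stratification

Candidate genes are partitioned by confidence category × q-value bin.
With breakpoints (0.1, 0.3) the bins are [0, 0.1), [0.1, 0.3], (0.3, 1]:
q = 0.1 and q = 0.3 both fall in the middle bin, matching the verbal
convention "less than 0.1; 0.1 to 0.3, greater than 0.3". Genes without a
q-value form an "unscored" bin; records without a dark report an
"unannotated" row — the cells partition the records exactly. "Dark" means
any dark gene body by default (`dark_definition: cds` selects dark CDS
instead). No significance test is run across strata by default; a
chi-square option exists behind a flag, since the headline output is the
proportion table itself.

## Synthetic cohort

Defaults: 3 chromosomes of 1 Mb, 60 genes (gene body 5 kb; five 200 bp
CDS exons, union 1 kb; every second gene carries a second isoform whose
CDS is a truncated subset, so multi-transcript unions are exercised
without changing the union), 12 loci each mapping four of five consecutive
genes (48 mapped genes; each locus's right edge cuts into its last mapped
gene, and the fifth gene stays unmapped and outside), and two non-coding
genes. Planted dark-CDS fractions: 0.077, 0.004, 0.73 (the regimes of
well-known partially dark disease genes), 0.05 and 0.20 exactly (threshold
boundaries), 0.006, 0.10, 0.25, 0.50, 1.0; five further genes get
intron-only dark (dark body, clean CDS). A 1 kb CDS makes every target an
integer number of base pairs; unrealizable targets are rejected before
anything is written. Thirty intergenic noise dark intervals (50–400 bp)
are placed where they can never touch a gene body, so per-gene truth is
exact by construction, while locus-level truth (record counts, dark bp) is
computed by the generator with the same interval engine the pipeline uses
— the per-base oracle in the tests independently validates both. The
candidate-gene table plants one exact stratification cell (Score2,
q > 0.3, 3 of 5 dark) and keeps all other genes of that category below the
top bin, so the cell is exact; remaining categories and q-values are drawn
from the seeded generator. The term map contains one planted term
(membership probability 0.9 for dark mapped genes, 0.05 background) and
25 background terms of 8 genes. A single `numpy` generator seeded once
drives all randomness; identical seeds give byte-identical files.

What the generator does *not* emulate: read mapping and mappability (dark
intervals are planted abstractly), overlapping gene bodies, unbalanced
locus sizes, realistic term-size distributions, LD structure. Passing
tests therefore demonstrate arithmetic and statistical correctness of the
pipeline, not robustness to the messiness of real annotations.

## Simulation sizes and calibration

The null type-I simulation draws uniform study sets of 150 from a
universe of 1500 with 30 terms of 80 genes. These sizes were chosen
analytically: the hypergeometric test is discrete and strictly
conservative, and with these parameters the attainable rejection level
nearest 0.05 is 0.049, close enough that the empirical fraction of tests
with p < 0.05 over 2000 draws sits within Monte-Carlo error of the
nominal level; with small terms or small universes the attainable level
drops well below 0.05 and the comparison would be meaningless. The power
check redraws the term map 200 times over a fixed cohort and asks how
often the planted term attains the uniquely smallest q-value. The
interval-engine check uses 500 randomized instances on chromosomes of at
most 4 kb — small enough for the per-base oracle to be fast, large enough
to hit every merge/boundary configuration.

## Numerical and degenerate-input choices

`P(X ≥ 0)` is returned as exactly 1.0 (also covering the empty-universe
case, where the scipy survival function is undefined). Hypergeometric
agreement with enumeration is asserted at relative tolerance 1e-10 (float
evaluation of exact integer ratios). Fractions of empty denominators
(no CDS, zero loci) are NA, never 0. Ties in enrichment results are broken
by term id; output tables are sorted on their primary key, and all writers
are deterministic so identical configs and inputs reproduce byte-identical
outputs (hashes recorded in the run manifest). Chromosome names are
matched verbatim; `--strip-chr-prefix` applies to every input
symmetrically, and the manifest records pairwise chromosome-name overlap
between inputs so a naming mismatch is visible rather than a silent zero.

## Known limitations

Calling dark regions from sequencing data is out of scope — the catalog
is an input. No liftover between genome builds; the genome build is a
property of the inputs and never assumed. No GO-DAG handling or gene-id
mapping. The stratification chi-square is a convenience, not a calibrated
test (cells can be sparse). Record-count semantics count a dark region
once per locus it overlaps, so a region spanning two loci contributes to
both counts.
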