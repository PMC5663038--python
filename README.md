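# epiconcord

Cross-species chromatin-marking concordance analysis for gene orthologs.

Given per-gene chromatin-marking calls in three related species tied together
by an ortholog (protogene) table, `epiconcord` classifies each ortholog's
marking pattern, splits repressive-mark targets into developmentally
*plastic* vs *constrained* classes, and quantifies the correlates of the two
classes at several scales:

- **concordance** — per-ortholog pattern tabulation, summary fractions, the
  independence null over patterns, cross-clade (outgroup) marking fractions,
  and marking-frequency comparisons for duplicate/loss gene sets.
- **seqdist** — alignment-free promoter comparison via k-mer frequency
  profiles (Pearson distance and Jensen-Shannon divergence, with
  collection-level high-frequency k-mer removal) and a closed-form F84
  substitution-model distance for supplied pairwise alignments.
- **features** — promoter extraction (500 bp upstream of the TSS), 4-mer
  composition Z-scores against a reference gene class, transposable-element
  overlap flags (>50% of TE length), mean nucleosome-occupancy scores, and
  Shannon-entropy tissue specificity.
- **stats** — two-way Type II ANOVA with omega-squared effect sizes,
  per-synteny-block exact binomial enrichment tests, Fisher exact
  co-occurrence tests, and duplicate-pair class-concordance chi-square tests.
- **hic3d** — weak/moderate/strong contact classification of binned contact
  matrices, co-occurrence of marked genes with high-connectivity regions,
  and strong-contact distance ECDFs per synteny-block enrichment category.
- **wgd** — ohnolog detection through double-conserved-synteny blocks
  against an unduplicated outgroup, with tandem-duplicate exclusion.
- **synthdata** — seeded, byte-reproducible generators for every input the
  pipeline consumes (marking tables with tunable cross-species correlation,
  class-specific promoter composition, Dirichlet tissue-expression profiles,
  synteny blocks with injected enrichment, distance-decaying contact
  matrices with boosted long-range contacts, and toy whole-genome
  duplication fixtures), plus the exact reference pattern-count fixture.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact reference
statistics, oracle-equivalence checks for the exact tests and closed-form
distances, property suites, and calibration/recovery runs on synthetic
data); the other files are per-module unit and property tests.

## CLI

All functionality is exposed under a single `epiconcord` entry point:

```bash
epiconcord simulate --seed 1 --out sim/              # synthetic dataset
epiconcord classify --marking sim/marking.tsv --out classes.tsv
epiconcord concordance-summary --marking sim/marking.tsv
epiconcord seqdist --promoters a.fa b.fa --k auto --metric both
epiconcord f84 --alignment aligned.fa
epiconcord features --gff3 genes.gff3 --genome genome.fa --out-dir feats/
epiconcord enrich-synteny --blocks blocks.tsv --classes classes.tsv --out enr.tsv
epiconcord anova --data sim_table.tsv
epiconcord pairs --pairs pairs.tsv --classes classes.tsv
epiconcord hic --matrix contacts.tsv --out-dir hic/
epiconcord ohnolog --orthologs map.tsv --positions pos.tsv --order order.txt --out pairs.tsv
```

Run `epiconcord <subcommand> --help` for the full option list. Conventions:
internal coordinates are 0-based half-open everywhere (GFF3 converted on
read, BED native); marking flags are tri-state (marked / unmarked / NA for
absent genes); contact matrices are dense TSV with a `W` sentinel for
saturated cells.

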