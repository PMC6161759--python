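# intron-audit

Tools for auditing putatively tiny introns in a genome annotation.

Plant genome annotations predict a handful of implausibly small introns —
intervals of 30 bp or less between consecutive exons, far below the typical
~85 bp mode of the intron size distribution. Most of these "microintrons"
turn out to be annotation artifacts: tandem-repeat-induced mispredictions,
boundary errors where the real intron is much larger than annotated, or
pseudogene loci that are never spliced at all. `intron-audit` packages the
full desk-and-bench workflow for settling the question locus by locus:

1. **Census** (`annotation_core`): derive per-isoform introns from a
   genome FASTA + GFF3 and tally their size distribution
   (`audit stats`).
2. **Screen** (`candidate_screen`): select introns at or below a size
   threshold, exclude candidates that cannot be verified (no control intron
   in the gene, no usable primer sites), flag tandem-repeat contexts, and
   diff candidate sets across annotation releases (`audit screen`).
3. **Primer design** (`primer_design`): for each candidate, design an
   RT-PCR pair whose amplicon spans the candidate **and at least one control
   intron** of the same isoform (`audit primers`). Splicing of the control
   intron is what proves a product came from cDNA rather than genomic DNA:
   the genomic and cDNA product sizes differ by the summed lengths of the
   spanned introns.
4. **Verdicts** (`amplicon_verdict`): align each sequenced amplicon to its
   locus with a splice-aware anchor-chain aligner, normalise gap placements
   to canonical GT..AG boundaries, and classify (`audit verify`):
   * no splice gap → genomic DNA, **unable to judge** (UJ);
   * gaps, but none over the candidate → the "intron" is retained in the
     mature transcript — **not an intron**;
   * a gap exactly matching the prediction → **confirmed**;
   * a larger gap containing the prediction → **mispredicted boundaries**,
     re-annotated with the actual size;
   * gaps matching no annotated intron → reported as extra splicing.
5. **Reports** (`reporting`): panel tallies in the bench vocabulary
   (cDNA/gDNA, No/Yes/N bp/UJ) and an arithmetic consistency check that
   re-derives every percentage of a published census from its primitive
   counts (`audit report`).
6. **Simulation** (`synthetic_data`): generate toy genomes whose annotations
   contain planted errors of every class — true 59 bp introns, false
   microintrons, repeat-induced mispredictions, boundary shifts, unannotated
   extra introns, pseudogenes — together with a truth table and simulated
   sequencing reads, so the whole loop is testable without any download
   (`audit simulate`).

## Worked example

Generate a 50-gene synthetic genome with planted annotation errors, census
it, and screen for ultra-small candidates:

```sh
$ audit simulate --seed 13 -o demo
wrote demo/genome.fa, demo/annotation.gff3, demo/truth.tsv (50 genes)

$ audit stats --genome demo/genome.fa --gff demo/annotation.gff3 --max-len 100 -o demo/stats.tsv
116 introns shorter than 100 bp of 124 total

$ audit screen --genome demo/genome.fa --gff demo/annotation.gff3 --max-len 59 -o demo/candidates.tsv
62 candidates, 62 retained after exclusions
```

The census (`demo/stats.tsv`) shows the planted size law: a mode in the
80–99 bp bins plus the deliberately planted sub-30 bp microintron artifacts.
Each screened candidate row carries its size, exclusion label, repeat-risk
motif, and splice-variant count.

Summarising the package's shipped verification-panel table reproduces the
bench arithmetic:

```sh
$ audit report --verdicts src/intron_audit/data/table1.tsv -o summary.txt
amplicons judged:            78
  cDNA products:             57
  genomic (unable to judge): 21
  predicted intron retained: 37
  confirmed as predicted:    2
  larger than predicted:     18
smallest confirmed intron:   59 bp
```

Of the 78 loci in the panel, only two candidates were ever confirmed as real
introns — both 59 bp — and every candidate of 30 bp or less was either
genomic-only (UJ) or retained in the cDNA, i.e. not an intron at all.

## Scope

Genome-wide counts for real annotation releases (e.g. the TAIR10/Araport11
*Arabidopsis* totals) require the corresponding frozen public releases and
are consumed here only as fixture inputs to the arithmetic checks, never
recomputed. Homolog counts and expression scores are likewise consumed from
user-provided TSVs; the package performs no BLAST searches and no microarray
processing. See `docs/methods.md` for the model, parameter defaults, and
known limitations.
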