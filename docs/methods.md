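# Methods

## Problem and model

A predicted intron is the interval between two consecutive exons of one
transcript isoform. `intron-audit` treats an annotation's ultra-small
predicted introns (≤ 30 bp by default) as hypotheses to be falsified or
confirmed by spliced evidence: an RT-PCR product sequenced from the locus
either retains the interval (the "intron" is exonic), lacks exactly the
interval (confirmed), lacks a larger interval containing it (boundary
misprediction), or aligns contiguously end to end (the template was genomic
DNA and nothing can be concluded). The discriminating design constraint is
that every amplicon must span a *control* intron in addition to the
candidate: absence of the control intron from the product is the proof of
cDNA origin, which is why candidates in single-intron genes are excluded
from verification rather than tested.

Coordinates follow the common convention pair: GFF3 files are 1-based
inclusive; everything internal is 0-based half-open on the forward genomic
strand. Intron ordinals and donor/acceptor dinucleotides are always in
transcript orientation (a minus-strand intron's donor is the reverse
complement of the last two forward-strand bases of its interval). Introns
are counted per isoform occurrence by default, matching per-isoform ID
schemes such as `GENE.2-6`; a `--unique-loci` mode collapses identical
genomic intervals.

## Spliced alignment

Edit-distance alignment is the wrong tool for detecting splicing: with unit
costs, a spliced-out intron of length *g* costs *g* as a deletion, so any
misalignment of a flanking block cheaper than *g* is preferred (measured
directly with an infix edit-distance aligner: a 44 bp gap loses to a 30-edit
garbage alignment of a 60 bp block). The aligner therefore treats large
target gaps as structural, not penalised:

1. **Anchoring.** Exact k-mer matches (k = 15 by default) between amplicon
   and locus are merged into maximal exact segments per diagonal.
2. **Chaining.** Segments are chained collinearly to maximise anchored
   amplicon coverage; a target jump of up to `max_intron` (5 kb) between
   chained segments costs only a flat join penalty, so intron-sized gaps are
   effectively free. If the best chain anchors less than half of the
   amplicon, the alignment is rejected (`NoAlignmentError`).
3. **Junction refinement.** Between consecutive blocks on diagonals d₁ < d₂
   the exact split point is chosen within a window extending
   `junction_slack` (5 bp) beyond the anchor-run ends — slack is needed
   because a sequencing error adjacent to a junction can coincidentally
   extend an exact run past the true split. Splits are scored as
   2·mismatches − 3·[canonical], where *canonical* means the implied gap
   starts/ends with a splice motif (GT..AG, or CT..AC for a minus-strand
   gene seen on the forward strand). The weighting makes a canonical split
   beat a non-canonical one with one mismatch fewer — a single error at the
   junction must not displace the gap — but never one with two fewer. Ties
   go leftmost. Diagonal jumps smaller than `min_splice_gap` are folded into
   the flanking block as small indels and the block is re-scored with a
   base-level edit alignment.
4. **Boundary normalisation.** Each gap is then shifted among its
   sequence-preserving placements (possible when block ends repeat) to the
   leftmost canonical placement; with none, the leftmost placement is kept
   and the gap marked non-canonical. Classification is therefore invariant
   to gap-placement ambiguity.

`min_splice_gap` defaults to 8 bp: the smallest candidates worth testing are
in that range, so a gap that small must still count as splicing evidence;
anything smaller is treated as an alignment indel. Lowering it can only add
gaps, so a cDNA call can never regress to "unable to judge". Orientation is
resolved by aligning both strands and keeping the alignment with more
matched bases (exact tie → forward).

A verdict of `CDNA_CONFIRMED` requires the refined gap to equal the
predicted interval exactly. A gap strictly containing the prediction gives
`CDNA_LARGER` with the gap as the re-annotated intron. Any other overlap
(smaller, or equal-length but shifted) is labelled `CDNA_SMALLER`; it was
never observed at the bench and is never planted by the simulator, but the
decision tree can reach it and reports it honestly. Gaps matching no
annotated intron and not overlapping the candidate are reported as extra
splicing.

## Primer design

Primer placement is a deterministic scan, not an optimisation, because
primer optimality is not the point — reproducibility of the audit is.
Forward windows are scanned 5′→3′ through the exon upstream of the earliest
spanned intron, reverse windows 3′→5′ downstream of the latest; the first
pair satisfying all constraints wins. Defaults are conventional
Sanger-friendly ranges: length 18–25 nt, Wallace-rule Tm (2·AT + 4·GC) in
50–65 °C with |ΔTm| ≤ 5, GC 40–60%, cDNA product 120–1,000 bp, and a simple
3′ cross-dimer rejection (≥ 4 perfectly complementary 3′ bases). No
nearest-neighbour thermodynamics and no hairpin model: the scoring is meant
to be transparent, and the downstream verdict logic is what the package is
for. The control intron is the candidate's neighbour — downstream, or
upstream when the candidate is the isoform's last intron. In-silico PCR
considers both template orientations and every binding position within the
configured mismatch tolerance, so a designed pair can be replayed against
either the genomic locus or a spliced cDNA.

## Repeat flagging

A candidate's intron ± 30 bp flank is scanned for exact tandem repeats of
period ≤ 10 with ≥ 3 consecutive copies (the kind of context, e.g. a
CAACAG×n tract, that induces phantom microintron calls); the best hit is
reported as most copies, then smallest period. With these defaults even
3-base homopolymer runs are flagged, so the flag is a *risk marker* to be
read alongside the verdict, not an exclusion; all three thresholds are
configurable.

## Synthetic data

The generator emulates the study conditions the pipeline is meant to audit.
Each gene is a three-exon model (exons uniform 150–260 bp, i.i.d. uniform
ACGT background) carrying one scenario:

| kind | planted truth | expected verdict |
|---|---|---|
| TRUE_SMALL_INTRON (20%) | genuine 59 bp GT..AG intron, annotated exactly | confirmed |
| FALSE_MICROINTRON (30%) | 10–30 bp exonic interval annotated as intron | not an intron |
| BOUNDARY_SHIFT (20%) | 15–30 bp annotated sliver strictly inside a 70–150 bp real intron | larger, actual size |
| EXTRA_INTRON (10%) | confirmed small intron plus an unannotated real intron in the middle exon | confirmed + extra splicing |
| PSEUDOGENE (10%) | expression 0; only genomic template available | unable to judge |
| REPEAT_INDUCED (10%) | false microintron inside a CAACAG×5 tract | not an intron, repeat flag |

The 59 bp true-small length is the smallest intron size the package treats
as real — the verification floor the audit converges on. Every gene also
carries a control intron drawn from the true-intron length law: a discrete
distribution on 59–500 bp, Gaussian-shaped around a mode of 85 bp
(σ = 13 bp) with a 10% exponential tail (scale 80 bp) — qualitatively the
shape of real plant intron size distributions, fully configurable, and
exposed as an explicit pmf so generated genomes can be chi-square-tested
against it. A quarter of genes get a second isoform (last exon shortened) to
exercise per-isoform counting. Strands are random; expression is log-normal
for expressed genes and exactly 0 for pseudogenes.

One deliberate construction detail: the single exonic base on each side of
every *true* intron is forced non-G, which makes every splice gap's
sequence-preserving placement unique. Without this, a gap flanked by
repeated sequence has several indistinguishable placements and exact
truth-matching would be ill-posed.

Amplicon simulation templates the true spliced cDNA for expressed genes and
the genomic locus for pseudogenes, replays the designed primer pair in
silico, and injects i.i.d. substitution errors at a configurable rate
(default scenarios: 0 and 0.5%, the latter a pessimistic Sanger read
quality). A single integer seed drives generation gene by gene, so outputs
are byte-for-byte reproducible.

What the simulator does **not** model — and hence what passing tests do not
show about real data: branch-point or polypyrimidine signals, non-canonical
(GC..AG, AT..AC) splice sites, alternative splicing beyond one extra-intron
scenario, heterozygosity, chromatogram-level artifacts, and indel-rich
sequencing error (an optional 1–2 bp indel mode exists only to stress the
aligner's small-indel merging).

## Numerical and reporting choices

Percentages in the consistency report are rounded half-up to the number of
decimals their source printed (one decimal for the 95.9% share, two for the
0.16/0.08/0.28% shares), so matches are bit-for-bit. The genome-wide intron
total is never a primitive: it is inverted from the anchor pair (62,565
sub-100 bp introns ↔ 48.93% of all introns) and used only inside the
report, labelled derived. Panel tallies are permutation-invariant; the
smallest-confirmed-intron statistic is defined only when at least one
candidate was confirmed.

## Problem sizes

The test suite and acceptance script run the full loop on 30–50-gene
genomes (the panel scale of the underlying verification design), the
aligner-vs-oracle comparison on 100 random single-gap loci of ~120–180 bp,
and the length-law chi-square on 2,000 generated introns. These sizes were
chosen as the smallest at which each property is meaningfully exercised;
everything scales linearly with gene count.

## Known limitations

* The aligner's contract assumes blocks of at least k (15) bp between
  gaps; splicing structures with shorter exons than the anchor length are
  outside its guarantee.
* Exclusion screening evaluates "no control intron" at the gene level (any
  isoform with a second intron rescues the candidate); isoform-private
  judgements would need per-isoform panels.
* `AMBIGUOUS_PRODUCT` is reserved in the exclusion vocabulary for loci
  whose every primer pair yields cDNA/gDNA-indistinguishable products; the
  deterministic designer currently reports such loci as `NO_PRIMER_SITE`
  when no valid two-intron layout exists, and the distinct label is applied
  only when verdicts later prove indistinguishability.
* Homolog counts and expression are pass-through annotations; the package
  deliberately computes neither.
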