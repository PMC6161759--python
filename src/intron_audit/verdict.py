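"""Spliced alignment of amplicons to their locus and cDNA/gDNA verdicts.

The discrimination problem: a PCR product sequenced from a candidate locus is
either genomic DNA (all introns retained, the amplicon aligns contiguously)
or cDNA (spliced introns appear as intron-sized deletions against the locus).
The aligner therefore treats large target gaps as free "splice" gaps rather
than penalised deletions — a plain edit-distance alignment would rather
misalign a whole exon block than open a 60 bp deletion, so the decomposition
is anchor-based:

1. exact k-mer anchors between amplicon and locus are merged into maximal
   exact segments per diagonal;
2. segments are chained collinearly, maximising anchored amplicon coverage
   (target jumps up to ``max_intron`` are allowed at a flat join cost);
3. junctions between blocks on different diagonals are refined to the exact
   split minimising mismatches (leftmost on ties), turning each diagonal jump
   of at least ``min_splice_gap`` into a gap; smaller jumps are folded into
   the flanking block as small indels;
4. gap placements are normalised to canonical GT..AG boundaries when a
   sequence-preserving shift permits it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
from Bio import SeqIO

from ._seq import hamming, revcomp
from .annotation import GeneModel, GenomeSequence, Isoform, derive_introns
from .primers import PrimerPair


class NoAlignmentError(ValueError):
    """Raised when no anchor chain covers at least half of the amplicon."""


class CoverageError(ValueError):
    """Raised when the aligned amplicon does not span the candidate region."""


@dataclass(frozen=True)
class AlignParams:
    k: int = 15  # anchor seed length
    min_splice_gap: int = 8  # smallest target gap treated as splicing evidence
    max_mismatch_rate: float = 0.05
    edge_trim: int = 5  # tolerated unaligned bases at amplicon ends
    max_intron: int = 5000
    max_small_indel: int = 10  # diagonal jitter absorbed inside a block
    junction_slack: int = 5  # split search window beyond the anchor run ends


@dataclass
class Block:
    """One collinear aligned block: amplicon interval <-> target interval."""

    q: tuple[int, int]
    t: tuple[int, int]


@dataclass
class SplicedAlignmentResult:
    blocks: list[Block]
    gaps: list[tuple[int, int]]  # target intervals spliced out of the amplicon
    gap_canonical: list[bool] = field(default_factory=list)
    mismatches: int = 0
    small_indels: int = 0
    matched: int = 0  # aligned amplicon bases minus mismatches
    query_length: int = 0

    def __post_init__(self) -> None:
        assert len(self.gaps) == max(0, len(self.blocks) - 1)


class VerdictCall(str, enum.Enum):
    GDNA_UNABLE_TO_JUDGE = "GDNA_UNABLE_TO_JUDGE"
    CDNA_NOT_AN_INTRON = "CDNA_NOT_AN_INTRON"
    CDNA_CONFIRMED = "CDNA_CONFIRMED"
    CDNA_LARGER = "CDNA_LARGER"
    # Never observed at the bench and never planted by the simulator, but the
    # decision tree can meet it: a gap overlapping the prediction without
    # containing it (smaller, or equal-sized but shifted).
    CDNA_SMALLER = "CDNA_SMALLER"


@dataclass
class Verdict:
    call: VerdictCall
    actual_intron: tuple[int, int] | None = None
    canonical: bool | None = None
    extra_splicing: list[tuple[int, int]] = field(default_factory=list)

    @property
    def actual_length(self) -> int | None:
        if self.actual_intron is None:
            return None
        return self.actual_intron[1] - self.actual_intron[0]


# ---------------------------------------------------------------------------
# anchoring and chaining


@dataclass
class _Segment:
    qs: int
    qe: int
    d: int  # diagonal t - q

    @property
    def ts(self) -> int:
        return self.qs + self.d

    @property
    def te(self) -> int:
        return self.qe + self.d

    @property
    def length(self) -> int:
        return self.qe - self.qs


def _exact_segments(query: str, target: str, k: int) -> list[_Segment]:
    """Maximal exact match runs, one per (diagonal, run) pair."""
    index: dict[str, list[int]] = {}
    for t in range(len(target) - k + 1):
        index.setdefault(target[t : t + k], []).append(t)
    by_diag: dict[int, list[int]] = {}
    for q in range(len(query) - k + 1):
        for t in index.get(query[q : q + k], ()):
            by_diag.setdefault(t - q, []).append(q)
    segments: list[_Segment] = []
    for d, qs_list in by_diag.items():
        qs_list.sort()
        run_start = prev = qs_list[0]
        for q in qs_list[1:]:
            if q == prev + 1:
                prev = q
                continue
            segments.append(_Segment(run_start, prev + k, d))
            run_start = prev = q
        segments.append(_Segment(run_start, prev + k, d))
    segments.sort(key=lambda s: (s.qs, s.ts))
    return segments


def _chain(segments: list[_Segment], params: AlignParams) -> list[_Segment]:
    """Collinear chain maximising anchored query coverage (deterministic)."""
    n = len(segments)
    if n == 0:
        return []
    ov = params.k - 1  # tolerated anchor overlap across a junction
    score = [float(s.length) for s in segments]
    parent = [-1] * n
    join_cost = 0.5  # flat cost per junction: prefer fewer blocks at equal coverage
    for j in range(n):
        sj = segments[j]
        for i in range(j):
            si = segments[i]
            if si.qe > sj.qs + ov or si.te > sj.ts + ov:
                continue
            if sj.ts - si.te > params.max_intron:
                continue
            if sj.d - si.d < -params.max_small_indel:
                continue
            overlap = max(0, si.qe - sj.qs)
            cand = score[i] + sj.length - overlap - join_cost
            if cand > score[j] + 1e-9:
                score[j] = cand
                parent[j] = i
    best = max(range(n), key=lambda j: (score[j], -segments[j].qs, -segments[j].ts))
    chain = []
    while best != -1:
        chain.append(segments[best])
        best = parent[best]
    return chain[::-1]


_SPLICE_MOTIFS = {"GT": "AG", "CT": "AC"}  # donor..acceptor, either strand


def _junction_split(
    query: str, target: str, lo: int, hi: int, d_left: int, d_right: int
) -> tuple[int, int]:
    """Best split s in [lo, hi]: left of s on d_left, right on d_right.

    Splits are scored by mismatch count with a bonus for canonical splice
    motifs at the implied gap boundaries: a canonical split wins over a
    non-canonical one with one mismatch fewer (a single sequencing error at
    the junction must not displace the gap), but never over one with two
    fewer. Ties go to the leftmost split.
    """
    width = hi - lo
    left_mm = [0] * (width + 1)
    for x in range(width):
        q_pos, t_pos = lo + x, lo + x + d_left
        bad = not (0 <= t_pos < len(target)) or query[q_pos] != target[t_pos]
        left_mm[x + 1] = left_mm[x] + bad
    right_mm = [0] * (width + 1)
    for x in range(width - 1, -1, -1):
        q_pos, t_pos = lo + x, lo + x + d_right
        bad = not (0 <= t_pos < len(target)) or query[q_pos] != target[t_pos]
        right_mm[x] = right_mm[x + 1] + bad
    best_s = best_score = best_mm = None
    for x in range(width + 1):
        s = lo + x
        mm = left_mm[x] + right_mm[x]
        donor = target[s + d_left : s + d_left + 2]
        acceptor = target[s + d_right - 2 : s + d_right]
        canonical = _SPLICE_MOTIFS.get(donor) == acceptor
        score = 2 * mm - 3 * canonical
        if best_score is None or score < best_score:
            best_s, best_score, best_mm = s, score, mm
    return best_s, best_mm


def _block_stats(query: str, target: str, block: Block) -> tuple[int, int]:
    """(mismatches, indel events) within one block."""
    qseq = query[block.q[0] : block.q[1]]
    tseq = target[block.t[0] : block.t[1]]
    if len(qseq) == len(tseq):
        return hamming(qseq, tseq), 0
    res = edlib.align(qseq, tseq, mode="NW", task="path")
    mm = indels = 0
    in_indel = False
    for count, op in _cigar_ops(res["cigar"]):
        if op == "X":
            mm += count
            in_indel = False
        elif op in "ID":
            if not in_indel:
                indels += 1
            in_indel = True
        else:
            in_indel = False
    return mm, indels


def _cigar_ops(cigar: str) -> Iterable[tuple[int, str]]:
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def spliced_align(
    amplicon: str, locus: str, params: AlignParams = AlignParams()
) -> SplicedAlignmentResult:
    """Decompose an amplicon into locus blocks separated by splice gaps.

    Contract: when the amplicon is a concatenation of locus blocks (each at
    least ``k`` bp) separated by target gaps of at least ``min_splice_gap``,
    with per-block mismatch rate at most ``max_mismatch_rate``, the exact
    block structure is recovered. Raises :class:`NoAlignmentError` when no
    anchor chain covers at least half of the amplicon.
    """
    if not amplicon or not locus:
        raise ValueError("amplicon and locus must be non-empty")
    segments = _exact_segments(amplicon, locus, params.k)
    chain = _chain(segments, params)
    covered = 0
    prev_qe = 0
    for seg in chain:
        covered += max(0, seg.qe - max(seg.qs, prev_qe))
        prev_qe = max(prev_qe, seg.qe)
    if covered < 0.5 * len(amplicon):
        raise NoAlignmentError(
            f"anchor chain covers {covered}/{len(amplicon)} amplicon bases"
        )

    # group chained segments into blocks (same diagonal up to small indels)
    groups: list[list[_Segment]] = [[chain[0]]]
    for seg in chain[1:]:
        if seg.d - groups[-1][-1].d >= params.min_splice_gap:
            groups.append([seg])
        else:
            groups[-1].append(seg)

    blocks: list[Block] = []
    gaps: list[tuple[int, int]] = []
    # exact split points between consecutive groups (junction windows end up
    # inside the flanking blocks, so their mismatches are counted there)
    q_bounds: list[int] = [0] * (len(groups) + 1)
    for gi in range(len(groups) - 1):
        left, right = groups[gi][-1], groups[gi + 1][0]
        # slack beyond the anchor run ends: a sequencing error adjacent to the
        # junction can coincidentally extend an exact run past the true split
        lo = max(min(left.qe, right.qs) - params.junction_slack, left.qs + 1, 0)
        hi = min(max(left.qe, right.qs) + params.junction_slack, right.qe - 1,
                 len(amplicon))
        s, _ = _junction_split(amplicon, locus, lo, hi, left.d, right.d)
        q_bounds[gi + 1] = s
        gaps.append((s + left.d, s + right.d))

    # extend the first/last block to the amplicon ends (clipped to the locus)
    d_first, d_last = groups[0][0].d, groups[-1][-1].d
    q_bounds[0] = max(0, -d_first)
    q_bounds[-1] = min(len(amplicon), len(locus) - d_last)

    mismatches = 0
    small_indels = 0
    for gi, group in enumerate(groups):
        qs, qe = q_bounds[gi], q_bounds[gi + 1]
        ts, te = qs + group[0].d, qe + group[-1].d
        block = Block(q=(qs, qe), t=(ts, te))
        mm, ind = _block_stats(amplicon, locus, block)
        mismatches += mm
        small_indels += ind
        blocks.append(block)

    aligned = sum(b.q[1] - b.q[0] for b in blocks)
    if aligned and mismatches > params.max_mismatch_rate * aligned:
        raise NoAlignmentError(
            f"{mismatches} mismatches over {aligned} aligned bases exceeds "
            f"the tolerated rate {params.max_mismatch_rate}"
        )
    return SplicedAlignmentResult(
        blocks=blocks,
        gaps=gaps,
        gap_canonical=[False] * len(gaps),
        mismatches=mismatches,
        small_indels=small_indels,
        matched=aligned - mismatches,
        query_length=len(amplicon),
    )


# ---------------------------------------------------------------------------
# boundary refinement


def _shift_range(locus: str, g0: int, g1: int) -> tuple[int, int]:
    """(max_left, max_right) sequence-preserving shifts of gap [g0, g1)."""
    left = 0
    while g0 - left - 1 >= 0 and locus[g0 - left - 1] == locus[g1 - left - 1]:
        left += 1
    right = 0
    while g1 + right < len(locus) and locus[g0 + right] == locus[g1 + right]:
        right += 1
    return left, right


def refine_boundaries(
    alignment: SplicedAlignmentResult, locus: str, strand: str = "+"
) -> SplicedAlignmentResult:
    """Shift each gap to a canonical splice-site placement when possible.

    Among all sequence-preserving placements of a gap (shifts possible when
    the block ends repeat), the leftmost placement whose gap starts with the
    donor GT and ends with the acceptor AG (in transcript orientation; CT..AC
    on the forward strand for minus-strand genes) is chosen. With no
    canonical placement the leftmost placement is kept and the gap is marked
    non-canonical.
    """
    donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
    canonical_flags: list[bool] = []
    for i, (g0, g1) in enumerate(alignment.gaps):
        left, right = _shift_range(locus, g0, g1)
        chosen, canonical = -left, False
        for s in range(-left, right + 1):
            if (
                locus[g0 + s : g0 + s + 2] == donor
                and locus[g1 + s - 2 : g1 + s] == acceptor
            ):
                chosen, canonical = s, True
                break
        if not canonical:
            chosen = -left
        if chosen != 0:
            alignment.gaps[i] = (g0 + chosen, g1 + chosen)
            lb, rb = alignment.blocks[i], alignment.blocks[i + 1]
            alignment.blocks[i] = Block(
                q=(lb.q[0], lb.q[1] + chosen), t=(lb.t[0], lb.t[1] + chosen)
            )
            alignment.blocks[i + 1] = Block(
                q=(rb.q[0] + chosen, rb.q[1]), t=(rb.t[0] + chosen, rb.t[1])
            )
        canonical_flags.append(canonical)
    alignment.gap_canonical = canonical_flags
    return alignment


# ---------------------------------------------------------------------------
# classification


def classify_amplicon(
    alignment: SplicedAlignmentResult,
    candidate_interval: tuple[int, int],
    isoform_introns: Sequence[tuple[int, int]],
    locus_offset: int = 0,
    params: AlignParams = AlignParams(),
) -> Verdict:
    """Decide cDNA vs gDNA origin and re-annotate the candidate intron.

    Decision tree: no splice gap at all -> genomic DNA, unable to judge; some
    gap but none overlapping the candidate -> the candidate is retained in
    the mature transcript (not an intron); a gap overlapping the candidate ->
    confirmed when identical to the prediction, otherwise re-annotated with
    the gap as the actual intron. Gaps matching no annotated intron and not
    overlapping the candidate are reported as extra splicing.
    """
    span = (
        locus_offset + alignment.blocks[0].t[0],
        locus_offset + alignment.blocks[-1].t[1],
    )
    if not (span[0] <= candidate_interval[0] and candidate_interval[1] <= span[1]):
        raise CoverageError(
            f"amplicon span {span} does not cover candidate {candidate_interval}"
        )
    gaps = [
        (locus_offset + g0, locus_offset + g1)
        for (g0, g1) in alignment.gaps
        if g1 - g0 >= params.min_splice_gap
    ]
    flags = {
        (locus_offset + g0, locus_offset + g1): c
        for (g0, g1), c in zip(alignment.gaps, alignment.gap_canonical)
    }
    if not gaps:
        return Verdict(call=VerdictCall.GDNA_UNABLE_TO_JUDGE)

    c0, c1 = candidate_interval
    overlapping = [g for g in gaps if g[0] < c1 and c0 < g[1]]
    annotated = {tuple(iv) for iv in isoform_introns}
    extra = [
        g
        for g in gaps
        if g not in overlapping and tuple(g) not in annotated
    ]
    if not overlapping:
        return Verdict(call=VerdictCall.CDNA_NOT_AN_INTRON, extra_splicing=extra)

    # most overlap, then leftmost: the gap explaining the candidate
    gap = min(overlapping, key=lambda g: (-(min(g[1], c1) - max(g[0], c0)), g[0]))
    if gap == (c0, c1):
        call = VerdictCall.CDNA_CONFIRMED
    elif gap[1] - gap[0] > c1 - c0:
        call = VerdictCall.CDNA_LARGER
    else:
        call = VerdictCall.CDNA_SMALLER
    extra += [g for g in overlapping if g != gap and tuple(g) not in annotated]
    return Verdict(
        call=call,
        actual_intron=gap,
        canonical=flags.get(gap),
        extra_splicing=sorted(extra),
    )


# ---------------------------------------------------------------------------
# batch driver


LOCUS_MARGIN = 60  # bp of genomic context kept on each side of the amplicon


def locus_window(
    pair: PrimerPair, genome: GenomeSequence, margin: int = LOCUS_MARGIN
) -> tuple[str, int]:
    """(locus sequence, genomic offset) around a primer pair's amplicon."""
    chrom = genome.records[pair.seq_id]
    lo = max(0, pair.amplicon_genomic[0] - margin)
    hi = min(len(chrom), pair.amplicon_genomic[1] + margin)
    return chrom[lo:hi], lo


def align_both_strands(
    amplicon: str, locus: str, params: AlignParams = AlignParams()
) -> tuple[SplicedAlignmentResult, str]:
    """Align the amplicon and its reverse complement; keep the better one.

    The alignment with more matched bases wins; an exact tie keeps the
    forward orientation.
    """
    results = []
    for label, seq in (("+", amplicon), ("-", revcomp(amplicon))):
        try:
            results.append((spliced_align(seq, locus, params), label))
        except NoAlignmentError:
            continue
    if not results:
        raise NoAlignmentError("no orientation aligned")
    results.sort(key=lambda r: (-r[0].matched, r[1]))
    return results[0]


def verify_panel(
    amplicons_path: str | Path,
    primer_pairs: Mapping[str, PrimerPair],
    gene_models: Mapping[str, GeneModel],
    genome: GenomeSequence,
    params: AlignParams = AlignParams(),
) -> list[tuple[str, Verdict]]:
    """One verdict per amplicon in a FASTA of sequenced products.

    Headers are ``<candidateID>|<replicate>[|...]``; the candidate ID must
    match a primer-report entry. Orientation is resolved per amplicon by
    trying both strands.
    """
    isoform_index: dict[str, tuple[GeneModel, Isoform]] = {}
    for gene in gene_models.values():
        for iso in gene.isoforms:
            isoform_index[iso.isoform_id] = (gene, iso)

    verdicts: list[tuple[str, Verdict]] = []
    for rec in SeqIO.parse(str(amplicons_path), "fasta"):
        cand_id = rec.id.split("|")[0]
        if cand_id not in primer_pairs:
            raise KeyError(f"amplicon header names unknown candidate {cand_id!r}")
        pair = primer_pairs[cand_id]
        isoform_id, _, ordinal = cand_id.rpartition("-")
        gene, isoform = isoform_index[isoform_id]
        introns = derive_introns(isoform, genome)
        candidate_intron = introns[int(ordinal) - 1]
        locus, offset = locus_window(pair, genome)
        alignment, _ = align_both_strands(str(rec.seq).upper(), locus, params)
        refine_boundaries(alignment, locus, strand=isoform.strand)
        verdict = classify_amplicon(
            alignment,
            candidate_intron.interval,
            [i.interval for i in introns],
            locus_offset=offset,
            params=params,
        )
        verdicts.append((cand_id, verdict))
    return verdicts
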