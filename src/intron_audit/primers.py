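"""Two-intron RT-PCR primer design and in-silico PCR.

The design principle: the amplicon must span the candidate intron *and* at
least one control intron of the same isoform. On cDNA the control intron is
spliced out, so a product of the expected shortened size proves the template
was mature transcript rather than contaminating genomic DNA; the genomic and
cDNA product sizes differ by the summed lengths of all spanned introns.

Primer placement is a deterministic scan, not an optimisation: forward
windows are tried 5'->3' through the exon upstream of the earliest spanned
intron, reverse windows 3'->5' through the exon downstream of the latest; the
first pair satisfying all constraints wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import gc_fraction, hamming, revcomp
from .annotation import GeneModel, GenomeSequence, Isoform, derive_introns
from .screen import Candidate, Exclusion


@dataclass(frozen=True)
class PrimerConstraints:
    """Sanger-friendly defaults; the scan rejects any window violating one."""

    min_len: int = 18
    max_len: int = 25
    min_tm: float = 50.0
    max_tm: float = 65.0
    min_gc: float = 0.40
    max_gc: float = 0.60
    max_tm_diff: float = 5.0
    min_product_cdna: int = 120
    max_product_cdna: int = 1000
    dimer_3prime: int = 4  # reject >= this many perfectly complementary 3' bases


@dataclass
class PrimerPair:
    forward: str
    reverse: str  # written 5'->3' as ordered, i.e. reverse-complement strand
    forward_genomic: tuple[int, int]  # forward-strand genomic interval
    reverse_genomic: tuple[int, int]
    tm_forward: float
    tm_reverse: float
    amplicon_genomic: tuple[int, int]
    amplicon_cdna_len: int
    control_introns: list[str] = field(default_factory=list)
    isoform_id: str = ""
    seq_id: str = ""
    strand: str = "+"

    @property
    def amplicon_genomic_len(self) -> int:
        return self.amplicon_genomic[1] - self.amplicon_genomic[0]


@dataclass
class DesignFailure:
    reason: Exclusion
    detail: str = ""


def melting_temperature(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees C."""
    if not seq:
        raise ValueError("empty primer sequence")
    if set(seq) - set("ACGT"):
        raise ValueError(f"primer contains non-ACGT characters: {seq!r}")
    at = seq.count("A") + seq.count("T")
    return 2.0 * at + 4.0 * (len(seq) - at)


def _cdna_map(isoform: Isoform, genome: GenomeSequence) -> tuple[str, list[int]]:
    """Annotated cDNA sequence and per-base map cDNA index -> genomic position."""
    chrom = genome.records[isoform.seq_id]
    seq_parts: list[str] = []
    gmap: list[int] = []
    for s, e in isoform.exons:
        exon_seq = chrom[s:e]
        if isoform.strand == "+":
            seq_parts.append(exon_seq)
            gmap.extend(range(s, e))
        else:
            seq_parts.append(revcomp(exon_seq))
            gmap.extend(range(e - 1, s - 1, -1))
    return "".join(seq_parts), gmap


def _primer_ok(seq: str, c: PrimerConstraints) -> bool:
    if "N" in seq:
        return False
    tm = melting_temperature(seq)
    if not (c.min_tm <= tm <= c.max_tm):
        return False
    return c.min_gc <= gc_fraction(seq) <= c.max_gc


def _dimer_clash(fwd: str, rev: str, n: int) -> bool:
    """True when the 3' ends of the two primers are perfectly complementary."""
    if n <= 0 or len(fwd) < n or len(rev) < n:
        return False
    return fwd[-n:] == revcomp(rev[-n:])


def design_primers(
    gene: GeneModel,
    candidate: Candidate,
    genome: GenomeSequence,
    constraints: PrimerConstraints = PrimerConstraints(),
) -> PrimerPair | DesignFailure:
    """First acceptable primer pair spanning the candidate plus a control intron.

    The isoform used is the candidate's own; the control intron is the next
    intron downstream of the candidate in transcription order, or the previous
    one when the candidate is the isoform's last intron. Returns a
    :class:`DesignFailure` carrying NO_CONTROL_INTRON or NO_PRIMER_SITE when
    no layout or no window works.
    """
    isoform = next(
        (i for i in gene.isoforms if i.isoform_id == candidate.intron.isoform_id), None
    )
    if isoform is None:
        raise ValueError(
            f"candidate {candidate.candidate_id} not in gene {gene.gene_id}"
        )
    introns = derive_introns(isoform, genome)
    ordinal = candidate.intron.ordinal
    if not any(i.intron_id == candidate.candidate_id for i in introns):
        raise ValueError(
            f"candidate {candidate.candidate_id} does not match isoform structure"
        )
    if len(introns) < 2:
        return DesignFailure(Exclusion.NO_CONTROL_INTRON, "single-intron isoform")

    control_ord = ordinal + 1 if ordinal < len(introns) else ordinal - 1
    first_ord, last_ord = min(ordinal, control_ord), max(ordinal, control_ord)
    spanned = introns[first_ord - 1 : last_ord]

    cdna, gmap = _cdna_map(isoform, genome)
    # cDNA coordinates of exon boundaries in transcription order
    exon_lens = [e - s for s, e in isoform.exons]
    starts = [0]
    for length in exon_lens[:-1]:
        starts.append(starts[-1] + length)
    # forward exon = exon #first_ord (1-based), reverse exon = exon #last_ord+1
    f_lo = starts[first_ord - 1]
    f_hi = f_lo + exon_lens[first_ord - 1]
    r_lo = starts[last_ord]
    r_hi = r_lo + exon_lens[last_ord]

    c = constraints
    # Acceptable windows precomputed in scan order: forward 5'->3', reverse 3'->5'.
    fwd_windows = []
    for f_start in range(f_lo, f_hi - c.min_len + 1):
        for f_len in range(c.min_len, min(c.max_len, f_hi - f_start) + 1):
            seq = cdna[f_start : f_start + f_len]
            if _primer_ok(seq, c):
                fwd_windows.append((f_start, seq, melting_temperature(seq)))
    rev_windows = []
    for r_end in range(r_hi, r_lo + c.min_len - 1, -1):
        for r_len in range(c.min_len, min(c.max_len, r_end - r_lo) + 1):
            seq = revcomp(cdna[r_end - r_len : r_end])
            if _primer_ok(seq, c):
                rev_windows.append((r_end, seq, melting_temperature(seq)))

    for f_start, fwd, tm_f in fwd_windows:
        for r_end, rev, tm_r in rev_windows:
            if not (c.min_product_cdna <= r_end - f_start <= c.max_product_cdna):
                continue
            if abs(tm_f - tm_r) > c.max_tm_diff:
                continue
            if _dimer_clash(fwd, rev, c.dimer_3prime):
                continue
            return _build_pair(
                isoform, gmap, fwd, rev, f_start, r_end, tm_f, tm_r, spanned, candidate
            )
    return DesignFailure(Exclusion.NO_PRIMER_SITE, "no window satisfied constraints")


def _build_pair(
    isoform: Isoform,
    gmap: list[int],
    fwd: str,
    rev: str,
    f_start: int,
    r_end: int,
    tm_f: float,
    tm_r: float,
    spanned,
    candidate: Candidate,
) -> PrimerPair:
    f_positions = gmap[f_start : f_start + len(fwd)]
    r_positions = gmap[r_end - len(rev) : r_end]
    f_iv = (min(f_positions), max(f_positions) + 1)
    r_iv = (min(r_positions), max(r_positions) + 1)
    amp = (min(f_iv[0], r_iv[0]), max(f_iv[1], r_iv[1]))
    return PrimerPair(
        forward=fwd,
        reverse=rev,
        forward_genomic=f_iv,
        reverse_genomic=r_iv,
        tm_forward=tm_f,
        tm_reverse=tm_r,
        amplicon_genomic=amp,
        amplicon_cdna_len=r_end - f_start,
        control_introns=[
            i.intron_id for i in spanned if i.intron_id != candidate.candidate_id
        ],
        isoform_id=isoform.isoform_id,
        seq_id=isoform.seq_id,
        strand=isoform.strand,
    )


def _match_positions(template: str, probe: str, max_mismatch: int) -> list[int]:
    """Start positions where probe matches template with <= max_mismatch."""
    if max_mismatch == 0:
        hits, i = [], template.find(probe)
        while i != -1:
            hits.append(i)
            i = template.find(probe, i + 1)
        return hits
    m = len(probe)
    return [
        i
        for i in range(len(template) - m + 1)
        if hamming(template[i : i + m], probe) <= max_mismatch
    ]


def in_silico_pcr(
    template: str,
    pair: PrimerPair,
    max_mismatch: int = 0,
    max_product: int = 5000,
) -> list[tuple[int, int]]:
    """All convergent products of the pair on a template, as (start, end).

    Both template orientations are considered: the forward primer may anneal
    to either strand as long as the reverse primer anneals convergently
    downstream. Product intervals are in template coordinates, sorted and
    de-duplicated; product length is capped at ``max_product``.
    """
    products: set[tuple[int, int]] = set()
    for left, right in ((pair.forward, pair.reverse), (pair.reverse, pair.forward)):
        left_hits = _match_positions(template, left, max_mismatch)
        right_hits = _match_positions(template, revcomp(right), max_mismatch)
        for i in left_hits:
            for j in right_hits:
                end = j + len(right)
                if end > i and end - i <= max_product and j >= i:
                    products.add((i, end))
    return sorted(products)


def primer_feasibility_check(
    gene_models: dict[str, GeneModel], genome: GenomeSequence, constraints=None
):
    """Callback for :func:`intron_audit.screen.apply_exclusions`."""
    constraints = constraints or PrimerConstraints()

    def check(candidate: Candidate) -> Exclusion:
        result = design_primers(
            gene_models[candidate.gene_id], candidate, genome, constraints
        )
        if isinstance(result, DesignFailure):
            return result.reason
        return Exclusion.NONE

    return check
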