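"""Genome/annotation ingestion, per-isoform intron derivation, and the size census.

Coordinate conventions, stated once and used everywhere:

* GFF3 files are 1-based inclusive (the format's definition); internal intervals
  are 0-based half-open on the forward genomic strand.
* Exons of an isoform are stored in *transcription* order, i.e. descending
  genomic coordinate for minus-strand isoforms.
* Intron ordinals, donor and acceptor dinucleotides are in transcript
  orientation; intron genomic intervals are always forward-strand.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

from ._seq import normalize_dna, revcomp

#: Fig-1-style irregular decade bins, smallest last in the paper's figure but
#: stored here ascending: (low, high) inclusive in bp.
DEFAULT_BINS: tuple[tuple[int, int], ...] = (
    (1, 29),
    (30, 30),
    (31, 39),
    (40, 49),
    (50, 59),
    (60, 69),
    (70, 80),
    (81, 89),
    (90, 99),
)


@dataclass(frozen=True)
class GenomeSequence:
    """Uppercase ACGTN sequences keyed by sequence ID."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.records.items():
            if not seq:
                raise ValueError(f"genome record {name!r} is empty")

    def fetch(self, seq_id: str, start: int, end: int) -> str:
        """Forward-strand slice [start, end), 0-based half-open."""
        seq = self.records[seq_id]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval [{start}, {end}) outside {seq_id!r} (length {len(seq)})"
            )
        return seq[start:end]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.records


@dataclass(frozen=True)
class Isoform:
    """One transcript structure: exons in transcription order.

    ``exons`` are 0-based half-open forward-strand intervals; for minus-strand
    isoforms the first exon is the one with the largest genomic coordinates.
    """

    isoform_id: str
    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.isoform_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.isoform_id}: isoform has no exons")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"{self.isoform_id}: overlapping exons")
        want = genomic if self.strand == "+" else genomic[::-1]
        if tuple(want) != self.exons:
            raise ValueError(f"{self.isoform_id}: exons not in transcription order")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.isoform_id}: bad exon interval ({s}, {e})")

    @property
    def span(self) -> tuple[int, int]:
        """Forward-strand genomic span of the transcript."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass
class GeneModel:
    gene_id: str
    isoforms: list[Isoform]
    expression: float | None = None
    homolog_count: int | None = None

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValueError(f"{self.gene_id}: gene has no isoforms")
        for iso in self.isoforms:
            if iso.gene_id != self.gene_id:
                raise ValueError(
                    f"{self.gene_id}: isoform {iso.isoform_id} belongs to {iso.gene_id}"
                )

    @property
    def seq_id(self) -> str:
        return self.isoforms[0].seq_id

    @property
    def strand(self) -> str:
        return self.isoforms[0].strand

    @property
    def max_intron_count(self) -> int:
        return max(iso.n_introns for iso in self.isoforms)


@dataclass(frozen=True)
class Intron:
    """A derived intron of one isoform.

    ``intron_id`` is ``<isoform_id>-<ordinal>`` with the ordinal 1-based in
    transcription order, mirroring TAIR-style IDs such as ``AT4G24930.1-3``.
    Donor/acceptor are read in transcript orientation (canonically GT..AG).
    """

    intron_id: str
    isoform_id: str
    gene_id: str
    seq_id: str
    strand: str
    interval: tuple[int, int]
    ordinal: int
    donor: str
    acceptor: str

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def canonical(self) -> bool:
        return self.donor == "GT" and self.acceptor == "AG"


@dataclass
class SizeHistogram:
    """Intron-size tally over inclusive (low, high) bp bins."""

    bins: tuple[tuple[int, int], ...]
    counts: list[int]
    total_in_range: int
    total_all: int

    def __post_init__(self) -> None:
        if sum(self.counts) != self.total_in_range:
            raise ValueError("histogram counts do not sum to total_in_range")
        if self.total_in_range > self.total_all:
            raise ValueError("total_in_range exceeds total_all")

    def to_rows(self) -> list[dict]:
        rows = []
        for (lo, hi), n in zip(self.bins, self.counts):
            rows.append(
                {
                    "bin_low": lo,
                    "bin_high": hi,
                    "count": n,
                    "percent_of_range": 100.0 * n / self.total_in_range
                    if self.total_in_range
                    else 0.0,
                    "percent_of_all": 100.0 * n / self.total_all
                    if self.total_all
                    else 0.0,
                }
            )
        return rows


def read_genome(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence`.

    IDs are the first whitespace-delimited token of each header; sequences are
    uppercased and validated against ACGTN. Duplicate IDs and empty files are
    errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence ID {rec.id!r} in {path}")
        records[rec.id] = normalize_dna(str(rec.seq), context=f"record {rec.id!r}")
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(records)


def read_annotation(path: str | Path, genome: GenomeSequence) -> list[GeneModel]:
    """Parse a GFF3 gene/mRNA/exon hierarchy into :class:`GeneModel` objects.

    Exon intervals are converted from GFF3 1-based inclusive to 0-based
    half-open, and sorted into transcription order per isoform. Exons beyond
    the bounds of the named genome sequence are errors, as are exons whose
    Parent is not an mRNA in the file.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        isoforms = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = []
            for exon in db.children(mrna, featuretype="exon"):
                if exon.seqid not in genome:
                    raise ValueError(
                        f"exon of {mrna.id} on unknown sequence {exon.seqid!r}"
                    )
                start0, end0 = exon.start - 1, exon.end
                if end0 > len(genome.records[exon.seqid]) or start0 < 0:
                    raise ValueError(
                        f"exon of {mrna.id} at ({exon.start}, {exon.end}) exceeds "
                        f"bounds of {exon.seqid!r}"
                    )
                exons.append((start0, end0))
            exons.sort()
            if mrna.strand == "-":
                exons.reverse()
            isoforms.append(
                Isoform(
                    isoform_id=mrna.id,
                    gene_id=gene.id,
                    seq_id=mrna.seqid,
                    strand=mrna.strand,
                    exons=tuple(exons),
                )
            )
        if isoforms:
            genes.append(GeneModel(gene_id=gene.id, isoforms=isoforms))
    # Orphan exon check: every exon's Parent must exist as an mRNA.
    mrna_ids = {m.id for m in db.features_of_type("mRNA")}
    for exon in db.features_of_type("exon"):
        for parent in exon.attributes.get("Parent", []):
            if parent not in mrna_ids:
                raise ValueError(f"exon references unknown parent {parent!r}")
    return genes


def derive_introns(isoform: Isoform, genome: GenomeSequence) -> list[Intron]:
    """One intron per adjacent exon pair, numbered 1..n-1 in transcription order.

    A single-exon isoform yields an empty list. Donor/acceptor dinucleotides
    are read from the genome in transcript orientation (reverse-complemented
    for minus-strand isoforms).
    """
    introns: list[Intron] = []
    for ordinal, (ex_a, ex_b) in enumerate(zip(isoform.exons, isoform.exons[1:]), 1):
        if isoform.strand == "+":
            start, end = ex_a[1], ex_b[0]
        else:
            start, end = ex_b[1], ex_a[0]
        if end <= start:
            raise ValueError(
                f"{isoform.isoform_id}: zero-length intron between exons "
                f"{ordinal} and {ordinal + 1}"
            )
        seq5 = genome.fetch(isoform.seq_id, start, start + 2)
        seq3 = genome.fetch(isoform.seq_id, end - 2, end)
        if isoform.strand == "+":
            donor, acceptor = seq5, seq3
        else:
            donor, acceptor = revcomp(seq3), revcomp(seq5)
        introns.append(
            Intron(
                intron_id=f"{isoform.isoform_id}-{ordinal}",
                isoform_id=isoform.isoform_id,
                gene_id=isoform.gene_id,
                seq_id=isoform.seq_id,
                strand=isoform.strand,
                interval=(start, end),
                ordinal=ordinal,
                donor=donor,
                acceptor=acceptor,
            )
        )
    return introns


def all_introns(
    gene_models: Iterable[GeneModel],
    genome: GenomeSequence,
    *,
    unique_loci: bool = False,
) -> list[Intron]:
    """Derive introns for every isoform of every gene.

    By default each isoform occurrence counts separately (TAIR-style
    per-isoform IDs); with ``unique_loci`` identical (seq_id, interval, strand)
    intervals are collapsed to their first occurrence.
    """
    out: list[Intron] = []
    seen: set[tuple[str, int, int, str]] = set()
    for gene in gene_models:
        for iso in gene.isoforms:
            for intron in derive_introns(iso, genome):
                if unique_loci:
                    key = (intron.seq_id, *intron.interval, intron.strand)
                    if key in seen:
                        continue
                    seen.add(key)
                out.append(intron)
    return out


def census(
    introns: Sequence[Intron],
    bins: Sequence[tuple[int, int]] = DEFAULT_BINS,
) -> SizeHistogram:
    """Tally intron lengths into inclusive bp bins.

    ``total_in_range`` counts introns falling in any bin; ``total_all`` counts
    every intron supplied. Bins must be non-overlapping.
    """
    ordered = sorted(bins)
    for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
        if hi1 >= lo2:
            raise ValueError(f"overlapping bins ({lo1},{hi1}) and ({lo2},{hi2})")
    counts = [0] * len(bins)
    in_range = 0
    for intron in introns:
        for i, (lo, hi) in enumerate(bins):
            if lo <= intron.length <= hi:
                counts[i] += 1
                in_range += 1
                break
    return SizeHistogram(
        bins=tuple(tuple(b) for b in bins),
        counts=counts,
        total_in_range=in_range,
        total_all=len(introns),
    )


def write_gff3(gene_models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon features (1-based inclusive) for round-tripping."""
    lines = ["##gff-version 3"]
    for gene in gene_models:
        g_start = min(iso.span[0] for iso in gene.isoforms)
        g_end = max(iso.span[1] for iso in gene.isoforms)
        lines.append(
            "\t".join(
                [
                    gene.seq_id,
                    "intron_audit",
                    "gene",
                    str(g_start + 1),
                    str(g_end),
                    ".",
                    gene.strand,
                    ".",
                    f"ID={gene.gene_id}",
                ]
            )
        )
        for iso in gene.isoforms:
            s, e = iso.span
            lines.append(
                "\t".join(
                    [
                        iso.seq_id,
                        "intron_audit",
                        "mRNA",
                        str(s + 1),
                        str(e),
                        ".",
                        iso.strand,
                        ".",
                        f"ID={iso.isoform_id};Parent={iso.gene_id}",
                    ]
                )
            )
            for i, (es, ee) in enumerate(sorted(iso.exons), 1):
                lines.append(
                    "\t".join(
                        [
                            iso.seq_id,
                            "intron_audit",
                            "exon",
                            str(es + 1),
                            str(ee),
                            ".",
                            iso.strand,
                            ".",
                            f"ID={iso.isoform_id}.exon{i};Parent={iso.isoform_id}",
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_genome_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    """Write a GenomeSequence to FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in genome.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
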