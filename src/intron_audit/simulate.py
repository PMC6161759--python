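"""Synthetic genomes with planted annotation errors and simulated amplicons.

Every pipeline stage can be exercised without real data: the generator emits
a genome FASTA, a gene-model GFF3 in which some features are deliberately
wrong, and a truth table recording what is actually true at each locus and
which verdict a perfect verification experiment must reach.

Planted scenario kinds and their expected outcomes:

* ``TRUE_SMALL_INTRON`` — a genuine 59 bp GT..AG intron, annotated exactly;
  must come back confirmed.
* ``FALSE_MICROINTRON`` — a <=30 bp interval inside a real exon annotated as
  an intron; the mature transcript retains it, so it is not an intron.
* ``REPEAT_INDUCED`` — a false microintron placed inside a tandem repeat
  tract (>=3 exact copies of a short motif), emulating repeat-driven
  mispredictions; also not an intron, and the repeat flag must trip.
* ``BOUNDARY_SHIFT`` — the annotated interval lies strictly inside a larger
  true GT..AG intron; the verdict must re-annotate the larger actual size.
* ``EXTRA_INTRON`` — a genuine unannotated intron inside an annotated exon,
  on top of a confirmed small intron; shows up as extra splicing.
* ``PSEUDOGENE`` — expression zero, so the only obtainable product is
  genomic: unable to judge.

Background sequence is i.i.d. uniform ACGT; splice sites are forced GT..AG;
the single exonic base on each side of every true intron is forced non-G so
that each splice gap has a unique sequence-preserving placement (no shift
ambiguity, making truth comparisons exact). True intron lengths follow a
discrete law peaked at 85 bp (range 59-500) with a thin long tail.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from ._seq import revcomp
from .annotation import (
    GeneModel,
    GenomeSequence,
    Isoform,
    write_genome_fasta,
    write_gff3,
)
from .primers import PrimerPair, in_silico_pcr
from .verdict import VerdictCall, locus_window


class ScenarioKind(str, enum.Enum):
    TRUE_SMALL_INTRON = "TRUE_SMALL_INTRON"
    FALSE_MICROINTRON = "FALSE_MICROINTRON"
    BOUNDARY_SHIFT = "BOUNDARY_SHIFT"
    EXTRA_INTRON = "EXTRA_INTRON"
    PSEUDOGENE = "PSEUDOGENE"
    REPEAT_INDUCED = "REPEAT_INDUCED"


EXPECTED_CALL: dict[ScenarioKind, VerdictCall] = {
    ScenarioKind.TRUE_SMALL_INTRON: VerdictCall.CDNA_CONFIRMED,
    ScenarioKind.FALSE_MICROINTRON: VerdictCall.CDNA_NOT_AN_INTRON,
    ScenarioKind.REPEAT_INDUCED: VerdictCall.CDNA_NOT_AN_INTRON,
    ScenarioKind.BOUNDARY_SHIFT: VerdictCall.CDNA_LARGER,
    ScenarioKind.EXTRA_INTRON: VerdictCall.CDNA_CONFIRMED,
    ScenarioKind.PSEUDOGENE: VerdictCall.GDNA_UNABLE_TO_JUDGE,
}

DEFAULT_MIX: dict[ScenarioKind, float] = {
    ScenarioKind.TRUE_SMALL_INTRON: 0.20,
    ScenarioKind.FALSE_MICROINTRON: 0.30,
    ScenarioKind.BOUNDARY_SHIFT: 0.20,
    ScenarioKind.EXTRA_INTRON: 0.10,
    ScenarioKind.PSEUDOGENE: 0.10,
    ScenarioKind.REPEAT_INDUCED: 0.10,
}


@dataclass
class SimConfig:
    n_genes: int = 50
    seed: int = 17
    scenario_mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    exon_len: tuple[int, int] = (150, 260)
    micro_len: tuple[int, int] = (10, 30)
    boundary_annot_len: tuple[int, int] = (15, 30)
    boundary_intron_len: tuple[int, int] = (70, 150)
    true_small_len: int = 59
    repeat_motif: str = "CAACAG"
    repeat_copies: int = 5
    spacer_len: tuple[int, int] = (200, 400)
    second_isoform_fraction: float = 0.25
    # discrete true-intron length law: Gaussian-shaped peak plus thin tail
    intron_len_min: int = 59
    intron_len_max: int = 500
    intron_len_peak: int = 85
    intron_len_sd: float = 13.0
    intron_tail_weight: float = 0.10
    intron_tail_scale: float = 80.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        total = sum(self.scenario_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scenario proportions sum to {total}, expected 1")
        if self.true_small_len < 9 or self.true_small_len > min(
            self.exon_len[0], self.intron_len_max
        ):
            raise ValueError("true_small_len infeasible for the configured exons")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "scenario_mix" in raw:
            raw["scenario_mix"] = {
                ScenarioKind(k): float(v) for k, v in raw["scenario_mix"].items()
            }
        for key in ("exon_len", "micro_len", "boundary_annot_len",
                    "boundary_intron_len", "spacer_len"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PlantedScenario:
    kind: ScenarioKind
    gene_id: str
    candidate_id: str
    seq_id: str
    strand: str
    annotated_interval: tuple[int, int]
    true_interval: tuple[int, int] | None
    true_exons: tuple[tuple[int, int], ...]
    expected_call: VerdictCall
    expect_extra_splicing: bool
    expression: float


@dataclass
class TruthTable:
    scenarios: list[PlantedScenario]
    seed: int

    def by_candidate(self) -> dict[str, PlantedScenario]:
        return {s.candidate_id: s for s in self.scenarios}

    def write_tsv(self, path: str | Path) -> None:
        lines = [
            "kind\tgene_id\tcandidate_id\tseq_id\tstrand\tannotated_start\t"
            "annotated_end\ttrue_start\ttrue_end\ttrue_exons\texpected_call\t"
            "expect_extra_splicing\texpression"
        ]
        for s in self.scenarios:
            t0, t1 = s.true_interval if s.true_interval else ("", "")
            exons = ";".join(f"{a}-{b}" for a, b in s.true_exons)
            lines.append(
                f"{s.kind.value}\t{s.gene_id}\t{s.candidate_id}\t{s.seq_id}\t"
                f"{s.strand}\t{s.annotated_interval[0]}\t{s.annotated_interval[1]}\t"
                f"{t0}\t{t1}\t{exons}\t{s.expected_call.value}\t"
                f"{int(s.expect_extra_splicing)}\t{s.expression}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def intron_length_law(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(lengths, probabilities) of the true-intron length distribution."""
    lengths = np.arange(config.intron_len_min, config.intron_len_max + 1)
    peak = np.exp(-0.5 * ((lengths - config.intron_len_peak) / config.intron_len_sd) ** 2)
    tail = np.exp(-np.maximum(lengths - config.intron_len_peak, 0) / config.intron_tail_scale)
    probs = (1 - config.intron_tail_weight) * peak / peak.sum()
    probs = probs + config.intron_tail_weight * tail / tail.sum()
    return lengths, probs / probs.sum()


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _rand_intron(rng: np.random.Generator, length: int) -> str:
    return "GT" + _rand_dna(rng, length - 4) + "AG"


def _no_g(seq: str, first: bool) -> str:
    """Force the first (or last) base to be non-G."""
    if not seq:
        return seq
    if first and seq[0] == "G":
        return "A" + seq[1:]
    if not first and seq[-1] == "G":
        return seq[:-1] + "A"
    return seq


@dataclass
class _Piece:
    seq: str
    annot: str  # "e"xon or "i"ntron in the annotation
    true: str  # "e"xon or "i"ntron in reality


def _gene_pieces(
    kind: ScenarioKind, rng: np.random.Generator, config: SimConfig,
    lengths: np.ndarray, probs: np.ndarray,
) -> list[_Piece]:
    def exon(n: int) -> str:
        return _rand_dna(rng, n)

    def law_len() -> int:
        return int(rng.choice(lengths, p=probs))

    e1, e2, e3 = (int(rng.integers(*config.exon_len)) for _ in range(3))
    ci = _rand_intron(rng, law_len())
    x1, x2, x3 = exon(e1), exon(e2), exon(e3)

    if kind in (ScenarioKind.TRUE_SMALL_INTRON, ScenarioKind.EXTRA_INTRON):
        i1 = _rand_intron(rng, config.true_small_len)
        if kind is ScenarioKind.TRUE_SMALL_INTRON:
            pieces = [
                _Piece(x1, "e", "e"),
                _Piece(i1, "i", "i"),
                _Piece(x2, "e", "e"),
                _Piece(ci, "i", "i"),
                _Piece(x3, "e", "e"),
            ]
        else:
            half = len(x2) // 2
            extra = _rand_intron(rng, law_len())
            pieces = [
                _Piece(x1, "e", "e"),
                _Piece(i1, "i", "i"),
                _Piece(x2[:half], "e", "e"),
                _Piece(extra, "e", "i"),  # real intron the annotation missed
                _Piece(x2[half:], "e", "e"),
                _Piece(ci, "i", "i"),
                _Piece(x3, "e", "e"),
            ]
    elif kind in (ScenarioKind.FALSE_MICROINTRON, ScenarioKind.PSEUDOGENE):
        micro = _rand_dna(rng, int(rng.integers(*config.micro_len)))
        pieces = [
            _Piece(x1, "e", "e"),
            _Piece(micro, "i", "e"),  # annotated intron that does not exist
            _Piece(x2, "e", "e"),
            _Piece(ci, "i", "i"),
            _Piece(x3, "e", "e"),
        ]
    elif kind is ScenarioKind.REPEAT_INDUCED:
        motif, copies = config.repeat_motif, config.repeat_copies
        tract = motif * copies
        m = len(motif)
        pieces = [
            _Piece(x1 + tract[:m], "e", "e"),
            _Piece(tract[m : 4 * m], "i", "e"),  # false microintron in the repeat
            _Piece(tract[4 * m :] + x2, "e", "e"),
            _Piece(ci, "i", "i"),
            _Piece(x3, "e", "e"),
        ]
    elif kind is ScenarioKind.BOUNDARY_SHIFT:
        full = int(rng.integers(*config.boundary_intron_len))
        annot = int(rng.integers(*config.boundary_annot_len))
        off = int(rng.integers(2, 11))  # annotated interval near the donor end
        i1 = _rand_intron(rng, full)
        pieces = [
            _Piece(x1, "e", "e"),
            _Piece(i1[:off], "e", "i"),
            _Piece(i1[off : off + annot], "i", "i"),  # the annotated sliver
            _Piece(i1[off + annot :], "e", "i"),
            _Piece(x2, "e", "e"),
            _Piece(ci, "i", "i"),
            _Piece(x3, "e", "e"),
        ]
    else:
        raise ValueError(f"unknown scenario kind {kind}")

    # unique splice-gap placement: exonic base adjacent to a true intron != G
    for idx, piece in enumerate(pieces):
        if piece.true == "i":
            if idx > 0 and pieces[idx - 1].true == "e":
                pieces[idx - 1].seq = _no_g(pieces[idx - 1].seq, first=False)
            if idx + 1 < len(pieces) and pieces[idx + 1].true == "e":
                pieces[idx + 1].seq = _no_g(pieces[idx + 1].seq, first=True)
    return pieces


def _runs(pieces: Sequence[_Piece], attr: str, role: str) -> list[tuple[int, int]]:
    """Local intervals of maximal runs of pieces with the given role."""
    out, pos, run_start = [], 0, None
    for piece in pieces:
        if getattr(piece, attr) == role:
            if run_start is None:
                run_start = pos
        else:
            if run_start is not None:
                out.append((run_start, pos))
                run_start = None
        pos += len(piece.seq)
    if run_start is not None:
        out.append((run_start, pos))
    return out


def generate_genome(
    config: SimConfig,
) -> tuple[GenomeSequence, list[GeneModel], TruthTable]:
    """Build the genome, the (partly wrong) annotation, and the truth table.

    A single master seed (``config.seed``) drives all randomness; genes are
    generated one after another, each consuming a contiguous slice of the
    stream, so the output is byte-for-byte reproducible.
    """
    rng = np.random.default_rng(config.seed)
    lengths, probs = intron_length_law(config)
    kinds = list(config.scenario_mix.keys())
    kind_probs = np.array([config.scenario_mix[k] for k in kinds])

    chrom_parts: list[str] = []
    offset = 0
    seq_id = "chr1"
    gene_models: list[GeneModel] = []
    scenarios: list[PlantedScenario] = []

    for gi in range(config.n_genes):
        gene_id = f"SYN{gi + 1:04d}G"
        kind = kinds[int(rng.choice(len(kinds), p=kind_probs))]
        strand = "+" if rng.random() < 0.5 else "-"
        pieces = _gene_pieces(kind, rng, config, lengths, probs)
        local_seq = "".join(p.seq for p in pieces)
        ann_exons = _runs(pieces, "annot", "e")
        ann_introns = _runs(pieces, "annot", "i")
        true_exons = _runs(pieces, "true", "e")
        true_introns = _runs(pieces, "true", "i")

        spacer = _rand_dna(rng, int(rng.integers(*config.spacer_len)))
        chrom_parts.append(spacer)
        offset += len(spacer)
        L = len(local_seq)

        def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
            if strand == "+":
                return (offset + iv[0], offset + iv[1])
            return (offset + L - iv[1], offset + L - iv[0])

        chrom_parts.append(local_seq if strand == "+" else revcomp(local_seq))

        g_ann_exons = tuple(to_genomic(iv) for iv in ann_exons)
        g_true_exons = tuple(to_genomic(iv) for iv in true_exons)
        iso1 = Isoform(
            isoform_id=f"{gene_id}.1",
            gene_id=gene_id,
            seq_id=seq_id,
            strand=strand,
            exons=g_ann_exons,
        )
        isoforms = [iso1]
        if rng.random() < config.second_isoform_fraction:
            # variant isoform: last exon shortened at its 3' (transcript) end
            trimmed = list(g_ann_exons)
            (s, e) = trimmed[-1]
            if e - s > 60:
                trimmed[-1] = (s, e - 20) if strand == "+" else (s + 20, e)
                isoforms.append(
                    Isoform(
                        isoform_id=f"{gene_id}.2",
                        gene_id=gene_id,
                        seq_id=seq_id,
                        strand=strand,
                        exons=tuple(trimmed),
                    )
                )
        expression = (
            0.0
            if kind is ScenarioKind.PSEUDOGENE
            else round(float(rng.lognormal(3.0, 1.0)), 3)
        )
        gene_models.append(
            GeneModel(
                gene_id=gene_id,
                isoforms=isoforms,
                expression=expression,
                homolog_count=int(rng.poisson(1.0)),
            )
        )

        cand_local = ann_introns[0]
        if kind in (
            ScenarioKind.TRUE_SMALL_INTRON,
            ScenarioKind.EXTRA_INTRON,
        ):
            true_iv = to_genomic(cand_local)
        elif kind is ScenarioKind.BOUNDARY_SHIFT:
            true_iv = to_genomic(true_introns[0])
        else:
            true_iv = None
        scenarios.append(
            PlantedScenario(
                kind=kind,
                gene_id=gene_id,
                candidate_id=f"{gene_id}.1-1",
                seq_id=seq_id,
                strand=strand,
                annotated_interval=to_genomic(cand_local),
                true_interval=true_iv,
                true_exons=g_true_exons,
                expected_call=EXPECTED_CALL[kind],
                expect_extra_splicing=kind is ScenarioKind.EXTRA_INTRON,
                expression=expression,
            )
        )
        offset += L

    chrom_parts.append(_rand_dna(rng, int(rng.integers(*config.spacer_len))))
    genome = GenomeSequence({seq_id: "".join(chrom_parts)})
    return genome, gene_models, TruthTable(scenarios=scenarios, seed=config.seed)


def transcribe(
    true_exons: Sequence[tuple[int, int]], seq_id: str, strand: str,
    genome: GenomeSequence,
) -> str:
    """Mature cDNA: true exon sequences concatenated in transcription order."""
    chrom = genome.records[seq_id]
    parts = []
    for s, e in true_exons:
        exon = chrom[s:e]
        parts.append(exon if strand == "+" else revcomp(exon))
    return "".join(parts)


def simulate_amplicons(
    primer_pairs: Mapping[str, PrimerPair],
    truth: TruthTable,
    genome: GenomeSequence,
    path: str | Path,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Write one simulated sequencing read per candidate with a primer pair.

    Expressed genes template the true (spliced) cDNA; expression-zero genes
    template genomic DNA. Substitution errors are injected per base at
    ``error_rate``. Headers are ``<candidateID>|1|truth=<kind>``. Returns
    (candidate_id, status) rows, status PRODUCT or NO_PRODUCT.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = []
    records: list[tuple[str, str]] = []
    for scenario in truth.scenarios:
        pair = primer_pairs.get(scenario.candidate_id)
        if pair is None:
            rows.append((scenario.candidate_id, "NO_PRODUCT"))
            continue
        if scenario.expression > 0:
            template = transcribe(
                scenario.true_exons, scenario.seq_id, scenario.strand, genome
            )
        else:
            template, _ = locus_window(pair, genome)
        products = in_silico_pcr(template, pair, max_mismatch=0)
        if not products:
            rows.append((scenario.candidate_id, "NO_PRODUCT"))
            continue
        s, e = products[0]
        read = _inject_errors(template[s:e], error_rate, rng)
        header = f"{scenario.candidate_id}|1|truth={scenario.kind.value}"
        records.append((header, read))
        rows.append((scenario.candidate_id, "PRODUCT"))
    with open(path, "w") as fh:
        for header, read in records:
            fh.write(f">{header}\n{read}\n")
    return rows


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.where(rng.random(len(arr)) < rate)[0]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def write_outputs(
    genome: GenomeSequence,
    gene_models: Sequence[GeneModel],
    truth: TruthTable,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write genome.fa, annotation.gff3 and truth.tsv into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "gff3": out / "annotation.gff3",
        "truth": out / "truth.tsv",
    }
    write_genome_fasta(genome, paths["fasta"])
    write_gff3(list(gene_models), paths["gff3"])
    truth.write_tsv(paths["truth"])
    return paths
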