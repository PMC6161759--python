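"""Ultra-small intron candidate selection, exclusion rules and risk flags.

The screening logic mirrors how very small predicted introns are triaged
before bench verification:

* only introns at or below a size threshold (default 30 bp) become candidates;
* a candidate is excluded when its gene offers no second ("control") intron,
  because an amplicon covering only the candidate cannot distinguish spliced
  cDNA from genomic DNA;
* a candidate is excluded when no acceptable primer pair exists in the
  neighbouring exons;
* candidates sitting in a short-period tandem repeat are flagged as likely
  mispredictions (a repeat such as CAACAG can induce a phantom microintron).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GeneModel, GenomeSequence, Intron


class Exclusion(str, enum.Enum):
    NONE = "NONE"
    NO_CONTROL_INTRON = "NO_CONTROL_INTRON"
    NO_PRIMER_SITE = "NO_PRIMER_SITE"
    AMBIGUOUS_PRODUCT = "AMBIGUOUS_PRODUCT"


@dataclass
class RepeatRisk:
    flagged: bool = False
    motif: str | None = None
    copies: int = 0

    def __bool__(self) -> bool:
        return self.flagged


@dataclass
class Candidate:
    """A screened small intron with its exclusion label and annotations."""

    intron: Intron
    gene_id: str
    exclusion: Exclusion = Exclusion.NONE
    repeat_risk: RepeatRisk = field(default_factory=RepeatRisk)
    splice_variant_count: int = 1
    homolog_count: int | None = None
    expression: float | None = None

    @property
    def candidate_id(self) -> str:
        return self.intron.intron_id


@dataclass
class AnnotationDiff:
    retained: list[str]
    removed: list[str]

    def __post_init__(self) -> None:
        if set(self.retained) & set(self.removed):
            raise ValueError("retained and removed candidate sets overlap")


def select_candidates(
    introns: Iterable[Intron],
    max_len: int,
    gene_models: Mapping[str, GeneModel] | None = None,
) -> list[Candidate]:
    """All introns with length <= max_len, wrapped as unscreened candidates.

    Ordering is deterministic: (gene_id, intron_id). When gene models are
    supplied, splice-variant counts and expression/homolog annotations are
    copied onto the candidates.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    picked = [i for i in introns if i.length <= max_len]
    picked.sort(key=lambda i: (i.gene_id, i.intron_id))
    out = []
    for intron in picked:
        cand = Candidate(intron=intron, gene_id=intron.gene_id)
        if gene_models is not None and intron.gene_id in gene_models:
            gene = gene_models[intron.gene_id]
            cand.splice_variant_count = len(gene.isoforms)
            cand.expression = gene.expression
            cand.homolog_count = gene.homolog_count
        out.append(cand)
    return out


def apply_exclusions(
    candidates: Sequence[Candidate],
    gene_models: Mapping[str, GeneModel],
    primer_feasibility: Callable[[Candidate], Exclusion] | None = None,
) -> dict[Exclusion, list[Candidate]]:
    """Label every candidate with exactly one exclusion outcome.

    A candidate is NO_CONTROL_INTRON when no isoform of its gene carries a
    second intron (any isoform with >= 2 introns rescues it: some control
    intron is then co-amplifiable). Survivors are handed to the
    ``primer_feasibility`` callback, which returns ``Exclusion.NONE`` for a
    designable candidate or the exclusion explaining the failure.
    """
    partition: dict[Exclusion, list[Candidate]] = {e: [] for e in Exclusion}
    for cand in candidates:
        if cand.gene_id not in gene_models:
            raise KeyError(f"candidate gene {cand.gene_id!r} not in gene models")
        gene = gene_models[cand.gene_id]
        if gene.max_intron_count < 2:
            cand.exclusion = Exclusion.NO_CONTROL_INTRON
        elif primer_feasibility is not None:
            cand.exclusion = primer_feasibility(cand)
        else:
            cand.exclusion = Exclusion.NONE
        partition[cand.exclusion].append(cand)
    return partition


def find_tandem_repeat(
    seq: str,
    min_period: int = 1,
    max_period: int = 10,
    min_copies: int = 3,
) -> RepeatRisk:
    """Best exact tandem repeat in ``seq``: most copies, then smallest period.

    Scans every period in [min_period, max_period] and every phase for maximal
    runs of exact consecutive motif copies; a run qualifies when it reaches
    ``min_copies``.
    """
    best = RepeatRisk()
    n = len(seq)
    for period in range(min_period, max_period + 1):
        i = 0
        while i + period <= n:
            # extend run of period-spaced matches starting at i
            j = i
            while j + period < n and seq[j] == seq[j + period]:
                j += 1
            run_len = j - i + period  # total bases in the repeat tract
            copies = run_len // period
            if copies >= min_copies and (
                copies > best.copies
                or (copies == best.copies and best.motif and period < len(best.motif))
            ):
                best = RepeatRisk(True, seq[i : i + period], copies)
            i = j + 1 if j > i else i + 1
    return best


def flag_repeat_context(
    candidate: Candidate,
    genome: GenomeSequence,
    flank: int = 30,
    min_period: int = 1,
    max_period: int = 10,
    min_copies: int = 3,
) -> RepeatRisk:
    """Scan the candidate intron +/- flank for a short-period tandem repeat."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    intron = candidate.intron
    chrom = genome.records[intron.seq_id]
    lo = max(0, intron.interval[0] - flank)
    hi = min(len(chrom), intron.interval[1] + flank)
    risk = find_tandem_repeat(chrom[lo:hi], min_period, max_period, min_copies)
    candidate.repeat_risk = risk
    return risk


def diff_annotations(
    old_candidates: Iterable[Candidate | str],
    new_candidates: Iterable[Candidate | str],
) -> AnnotationDiff:
    """Partition the old candidate set into retained vs removed IDs."""

    def ids(items):
        return [c if isinstance(c, str) else c.candidate_id for c in items]

    old_ids, new_ids = ids(old_candidates), set(ids(new_candidates))
    retained = [i for i in old_ids if i in new_ids]
    removed = [i for i in old_ids if i not in new_ids]
    return AnnotationDiff(retained=retained, removed=removed)


def read_expression_tsv(path: str | Path) -> dict[str, float]:
    """gene_id <tab> score table into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "score"])
    return dict(zip(df.gene_id.astype(str), df.score.astype(float)))


def read_homologs_tsv(path: str | Path) -> dict[str, int]:
    """gene_id <tab> comma-separated homolog IDs into per-gene counts."""
    counts: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        gene = parts[0]
        homologs = parts[1].split(",") if len(parts) > 1 and parts[1].strip() else []
        counts[gene] = len([h for h in homologs if h.strip()])
    return counts


def annotate_candidates(
    candidates: Sequence[Candidate],
    expression: Mapping[str, float] | None = None,
    homologs: Mapping[str, int] | None = None,
) -> list[Candidate]:
    """Attach expression scores / homolog counts; rank by descending expression.

    Candidates with higher expression come first (bench verification tackles
    well-expressed genes first); missing scores sort last. Ties break on
    (gene_id, intron_id).
    """
    for cand in candidates:
        if expression is not None and cand.gene_id in expression:
            cand.expression = expression[cand.gene_id]
        if homologs is not None and cand.gene_id in homologs:
            cand.homolog_count = homologs[cand.gene_id]
    return sorted(
        candidates,
        key=lambda c: (
            -(c.expression if c.expression is not None else float("-inf")),
            c.gene_id,
            c.candidate_id,
        ),
    )


def candidates_to_frame(candidates: Sequence[Candidate]) -> pd.DataFrame:
    """Tabular report mirroring the bench-panel table columns."""
    rows = []
    for i, cand in enumerate(candidates, 1):
        rows.append(
            {
                "no": i,
                "intron_id": cand.candidate_id,
                "size_bp": cand.intron.length,
                "exclusion": cand.exclusion.value,
                "repeat_flag": cand.repeat_risk.motif if cand.repeat_risk else "",
                "repeat_copies": cand.repeat_risk.copies,
                "splice_variants": cand.splice_variant_count,
                "homolog_count": "" if cand.homolog_count is None else cand.homolog_count,
                "expression": "" if cand.expression is None else cand.expression,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "no",
            "intron_id",
            "size_bp",
            "exclusion",
            "repeat_flag",
            "repeat_copies",
            "splice_variants",
            "homolog_count",
            "expression",
        ],
    )
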