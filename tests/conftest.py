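"""Shared fixtures: tiny hand-built loci and a reusable synthetic world."""

from __future__ import annotations

import pytest

from intron_audit import (
    GenomeSequence,
    Intron,
    SimConfig,
    all_introns,
    generate_genome,
)
from intron_audit.primers import DesignFailure, design_primers
from intron_audit.screen import Candidate


def make_intron(
    length: int,
    intron_id: str = "G1.1-1",
    start: int = 100,
    seq_id: str = "chr1",
    strand: str = "+",
    donor: str = "GT",
    acceptor: str = "AG",
) -> Intron:
    """Dummy intron for tests that only care about lengths and IDs."""
    isoform_id, _, ordinal = intron_id.rpartition("-")
    return Intron(
        intron_id=intron_id,
        isoform_id=isoform_id,
        gene_id=isoform_id.rsplit(".", 1)[0],
        seq_id=seq_id,
        strand=strand,
        interval=(start, start + length),
        ordinal=int(ordinal),
        donor=donor,
        acceptor=acceptor,
    )


def write_fasta(path, records: dict[str, str]) -> str:
    lines = []
    for name, seq in records.items():
        lines.append(f">{name}")
        lines.append(seq)
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture(scope="session")
def synthetic_world():
    """A 30-gene synthetic genome with primer pairs for every truth candidate."""
    config = SimConfig(n_genes=30, seed=7)
    genome, gene_models, truth = generate_genome(config)
    model_map = {g.gene_id: g for g in gene_models}
    intron_map = {i.intron_id: i for i in all_introns(gene_models, genome)}
    pairs = {}
    for scenario in truth.scenarios:
        intron = intron_map[scenario.candidate_id]
        result = design_primers(
            model_map[intron.gene_id],
            Candidate(intron=intron, gene_id=intron.gene_id),
            genome,
        )
        if not isinstance(result, DesignFailure):
            pairs[scenario.candidate_id] = result
    return {
        "config": config,
        "genome": genome,
        "gene_models": gene_models,
        "model_map": model_map,
        "truth": truth,
        "intron_map": intron_map,
        "pairs": pairs,
    }
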