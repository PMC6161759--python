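"""Panel summaries and arithmetic consistency checks over published counts.

Two kinds of reporting live here: tallies over a verification panel (how many
amplicons proved cDNA vs genomic, how many candidate introns were confirmed,
retained, or re-annotated larger), and a consistency report that re-derives
every percentage from the primitive counts of a published census with the
same rounding the source used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .verdict import Verdict, VerdictCall

TABLE1_COLUMNS = [
    "no",
    "intron_id",
    "size_bp",
    "sequencing_result",
    "existence",
    "splice_variants",
    "homolog_count",
]


@dataclass
class PanelSummary:
    n_total: int = 0
    n_cdna: int = 0
    n_gdna_uj: int = 0
    n_not_intron: int = 0
    n_confirmed: int = 0
    n_larger: int = 0
    n_other: int = 0  # e.g. smaller-than-predicted re-annotations
    min_confirmed_len: int | None = None
    rows: list[tuple[str, Verdict]] = field(default_factory=list)

    def validate(self) -> None:
        assert self.n_cdna + self.n_gdna_uj == self.n_total
        assert self.n_not_intron + self.n_confirmed + self.n_larger <= self.n_cdna


def summarize_panel(verdicts: Sequence[tuple[str, Verdict]]) -> PanelSummary:
    """Tally a panel of per-candidate verdicts.

    ``min_confirmed_len`` is the smallest re-annotated length among confirmed
    introns, set only when at least one candidate was confirmed.
    """
    s = PanelSummary(rows=list(verdicts))
    confirmed_lens: list[int] = []
    for _, v in verdicts:
        s.n_total += 1
        if v.call is VerdictCall.GDNA_UNABLE_TO_JUDGE:
            s.n_gdna_uj += 1
            continue
        s.n_cdna += 1
        if v.call is VerdictCall.CDNA_NOT_AN_INTRON:
            s.n_not_intron += 1
        elif v.call is VerdictCall.CDNA_CONFIRMED:
            s.n_confirmed += 1
            confirmed_lens.append(v.actual_length)
        elif v.call is VerdictCall.CDNA_LARGER:
            s.n_larger += 1
        else:
            s.n_other += 1
    s.min_confirmed_len = min(confirmed_lens) if confirmed_lens else None
    s.validate()
    return s


# ---------------------------------------------------------------------------
# published-count arithmetic


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero, as printed tables conventionally do."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


#: Primitive counts of the published sub-100 bp intron census (bin counts per
#: decade, the two microintron counts, and the anchor share of the sub-100 bp
#: pool among all introns genome-wide).
PUBLISHED_COUNTS: dict[str, float] = {
    "sub100_total": 62565,
    "bin_90_99": 20395,
    "bin_81_89": 26585,
    "bin_71_80": 13050,
    "bin_60_69": 1738,
    "bin_50_59": 357,
    "bin_40_49": 253,
    "bin_30_39": 93,
    "exactly_30": 9,
    "below_30": 94,
    "sub100_share_of_all_pct": 48.93,
    "candidates_araport11": 71,
    "excluded_single_intron": 16,
    "excluded_no_primer_site": 7,
}


@dataclass
class ConsistencyItem:
    name: str
    derived: float
    printed: float
    decimals: int

    @property
    def match(self) -> bool:
        return round_half_up(self.derived, self.decimals) == self.printed

    @property
    def rounded(self) -> float:
        return round_half_up(self.derived, self.decimals)


def consistency_report(
    counts: Mapping[str, float] = PUBLISHED_COUNTS,
    printed: Mapping[str, float] | None = None,
) -> list[ConsistencyItem]:
    """Re-derive every published share from the primitive counts.

    The genome-wide intron total is not a primitive; it is inverted from the
    anchor pair (sub-100 bp total, its share of all introns) and used only
    here, labelled derived. Raises on a zero denominator.
    """
    c = dict(counts)
    if printed is None:
        printed = {
            "share_70_99_of_sub100_pct": 95.9,
            "share_le30_of_sub100_pct": 0.16,
            "share_le30_of_all_pct": 0.08,
            "share_30_39_of_all_pct": 0.07,
            "share_40_49_of_all_pct": 0.2,
            "share_50_59_of_all_pct": 0.28,
            "n_candidates_le30": 103,
            "n_pool_31_59": 694,
            "n_retained_after_exclusions": 48,
        }
    sub100 = c["sub100_total"]
    if sub100 == 0 or c["sub100_share_of_all_pct"] == 0:
        raise ZeroDivisionError("census anchors must be non-zero")
    total_all = sub100 / (c["sub100_share_of_all_pct"] / 100.0)  # derived total
    n_le30 = c["exactly_30"] + c["below_30"]
    items = [
        ConsistencyItem(
            "share_70_99_of_sub100_pct",
            100.0 * (c["bin_90_99"] + c["bin_81_89"] + c["bin_71_80"]) / sub100,
            printed["share_70_99_of_sub100_pct"],
            1,
        ),
        ConsistencyItem(
            "share_le30_of_sub100_pct",
            100.0 * n_le30 / sub100,
            printed["share_le30_of_sub100_pct"],
            2,
        ),
        ConsistencyItem(
            "share_le30_of_all_pct",
            100.0 * n_le30 / total_all,
            printed["share_le30_of_all_pct"],
            2,
        ),
        ConsistencyItem(
            "share_30_39_of_all_pct",
            100.0 * c["bin_30_39"] / total_all,
            printed["share_30_39_of_all_pct"],
            2,
        ),
        ConsistencyItem(
            "share_40_49_of_all_pct",
            100.0 * c["bin_40_49"] / total_all,
            printed["share_40_49_of_all_pct"],
            1,
        ),
        ConsistencyItem(
            "share_50_59_of_all_pct",
            100.0 * c["bin_50_59"] / total_all,
            printed["share_50_59_of_all_pct"],
            2,
        ),
        ConsistencyItem("n_candidates_le30", n_le30, printed["n_candidates_le30"], 0),
        ConsistencyItem(
            "n_pool_31_59",
            (c["bin_30_39"] - c["exactly_30"]) + c["bin_40_49"] + c["bin_50_59"],
            printed["n_pool_31_59"],
            0,
        ),
        ConsistencyItem(
            "n_retained_after_exclusions",
            c["candidates_araport11"]
            - c["excluded_single_intron"]
            - c["excluded_no_primer_site"],
            printed["n_retained_after_exclusions"],
            0,
        ),
    ]
    return items


# ---------------------------------------------------------------------------
# panel tables


def load_table1() -> pd.DataFrame:
    """The shipped verification-panel fixture table (rows 1-48 and S1-S30)."""
    with resources.files("intron_audit.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"no": str})


def verdict_from_table_row(row: Mapping) -> Verdict:
    """Translate a panel-table row's existence column into a Verdict.

    ``UJ`` -> genomic DNA, unable to judge; ``No`` -> the predicted intron is
    retained in the cDNA; ``Yes`` -> confirmed at the predicted size;
    ``<N> bp`` -> spliced, but the actual intron is N bp (larger than
    predicted for every such published row).
    """
    existence = str(row["existence"]).strip()
    size = int(row["size_bp"])
    if existence == "UJ":
        return Verdict(call=VerdictCall.GDNA_UNABLE_TO_JUDGE)
    if existence == "No":
        return Verdict(call=VerdictCall.CDNA_NOT_AN_INTRON)
    if existence == "Yes":
        return Verdict(call=VerdictCall.CDNA_CONFIRMED, actual_intron=(0, size))
    if existence.endswith("bp"):
        actual = int(existence.split()[0])
        call = VerdictCall.CDNA_LARGER if actual > size else VerdictCall.CDNA_SMALLER
        return Verdict(call=call, actual_intron=(0, actual))
    raise ValueError(f"unrecognised existence value {existence!r}")


def table_to_verdicts(table: pd.DataFrame) -> list[tuple[str, Verdict]]:
    return [(row["intron_id"], verdict_from_table_row(row)) for _, row in table.iterrows()]


def write_table1_like(rows: Iterable[Mapping], path: str | Path) -> None:
    """Write a panel table (stable column order); parsable by read_table1_like."""
    df = pd.DataFrame(list(rows), columns=TABLE1_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_table1_like(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"no": str})


def verdicts_to_rows(
    verdicts: Sequence[tuple[str, Verdict]],
    sizes: Mapping[str, int] | None = None,
    splice_variants: Mapping[str, int] | None = None,
    homologs: Mapping[str, int] | None = None,
) -> list[dict]:
    """Panel-table rows from computed verdicts (inverse of verdict_from_table_row)."""
    rows = []
    for i, (cand_id, v) in enumerate(verdicts, 1):
        size = sizes.get(cand_id) if sizes else None
        if v.call is VerdictCall.GDNA_UNABLE_TO_JUDGE:
            result, existence = "gDNA", "UJ"
        elif v.call is VerdictCall.CDNA_NOT_AN_INTRON:
            result, existence = "cDNA", "No"
        elif v.call is VerdictCall.CDNA_CONFIRMED:
            result, existence = "cDNA", "Yes"
        else:
            result, existence = "cDNA", f"{v.actual_length} bp"
        rows.append(
            {
                "no": str(i),
                "intron_id": cand_id,
                "size_bp": size if size is not None else "",
                "sequencing_result": result,
                "existence": existence,
                "splice_variants": splice_variants.get(cand_id, "") if splice_variants else "",
                "homolog_count": homologs.get(cand_id, "") if homologs else "",
            }
        )
    return rows


def format_summary(summary: PanelSummary) -> str:
    """Human-readable panel summary."""
    lines = [
        f"amplicons judged:            {summary.n_total}",
        f"  cDNA products:             {summary.n_cdna}",
        f"  genomic (unable to judge): {summary.n_gdna_uj}",
        f"  predicted intron retained: {summary.n_not_intron}",
        f"  confirmed as predicted:    {summary.n_confirmed}",
        f"  larger than predicted:     {summary.n_larger}",
    ]
    if summary.n_other:
        lines.append(f"  other re-annotations:      {summary.n_other}")
    if summary.min_confirmed_len is not None:
        lines.append(f"smallest confirmed intron:   {summary.min_confirmed_len} bp")
    return "\n".join(lines)
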