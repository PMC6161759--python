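"""Spliced alignment, boundary refinement and cDNA/gDNA classification."""

import edlib
import numpy as np
import pytest

from intron_audit import (
    AlignParams,
    ScenarioKind,
    classify_amplicon,
    refine_boundaries,
    spliced_align,
)
from intron_audit.simulate import simulate_amplicons
from intron_audit.verdict import (
    Block,
    NoAlignmentError,
    SplicedAlignmentResult,
    Verdict,
    VerdictCall,
    verify_panel,
)


def rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def make_alignment(blocks, gaps, canonical=None):
    return SplicedAlignmentResult(
        blocks=[Block(q=b[0], t=b[1]) for b in blocks],
        gaps=list(gaps),
        gap_canonical=list(canonical) if canonical else [True] * len(gaps),
        query_length=sum(b[0][1] - b[0][0] for b in blocks),
    )


class TestSplicedAlign:
    def test_exact_substring_is_single_block(self):
        rng = np.random.default_rng(0)
        locus = rand_dna(rng, 400)
        result = spliced_align(locus[50:250], locus)
        assert result.gaps == []
        assert result.blocks[0].t == (50, 250)
        assert result.mismatches == 0

    @staticmethod
    def plant_gap(locus, g0, g1):
        """Make [g0, g1) a canonical intron with unique placement."""
        s = list(locus)
        s[g0], s[g0 + 1], s[g1 - 2], s[g1 - 1] = "G", "T", "A", "G"
        if s[g0 - 1] == s[g1 - 1]:
            s[g0 - 1] = "A" if s[g1 - 1] != "A" else "C"
        if s[g1] == s[g0]:
            s[g1] = "A"
        return "".join(s)

    def test_two_block_construction(self):
        rng = np.random.default_rng(1)
        locus = self.plant_gap(rand_dna(rng, 400), 200, 260)
        amplicon = locus[0:200] + locus[260:400]
        result = spliced_align(amplicon, locus)
        assert [b.q for b in result.blocks] == [(0, 200), (200, 340)]
        assert result.gaps == [(200, 260)]

    def test_unrelated_sequences_raise(self):
        rng = np.random.default_rng(2)
        with pytest.raises(NoAlignmentError):
            spliced_align(rand_dna(rng, 150), rand_dna(rng, 400))

    def test_reconstruction_up_to_mismatches(self):
        rng = np.random.default_rng(3)
        locus = self.plant_gap(rand_dna(rng, 500), 180, 240)
        amplicon = list(locus[20:180] + locus[240:430])
        for pos in (40, 250):  # substitutions well inside blocks
            amplicon[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[amplicon[pos]]
        amplicon = "".join(amplicon)
        result = spliced_align(amplicon, locus)
        rebuilt = "".join(locus[t0:t1] for (_, _), (t0, t1) in
                          ((b.q, b.t) for b in result.blocks))
        assert len(rebuilt) == len(amplicon)
        mm = sum(a != b for a, b in zip(rebuilt, amplicon))
        assert mm == result.mismatches == 2

    @staticmethod
    def brute_force_single_gap(amplicon, locus, min_gap=8):
        """Enumerate every (donor, acceptor) cut pair; score by edit distance.

        The spliced target is the locus with [d, a) excised; the best cut is
        the one minimising infix edit distance of the amplicon, ties broken
        leftmost. Returns the winning cut pair.
        """
        best = None
        for d in range(1, len(locus)):
            for a in range(d + min_gap, len(locus) + 1):
                spliced = locus[:d] + locus[a:]
                if len(spliced) < len(amplicon):
                    continue
                ed = edlib.align(amplicon, spliced, mode="HW")["editDistance"]
                if best is None or ed < best[0]:
                    best = (ed, (d, a))
        return best[1]

    def test_matches_brute_force_oracle_on_random_single_gap_cases(self):
        rng = np.random.default_rng(42)
        n_cases = 100
        for case in range(n_cases):
            e1 = int(rng.integers(30, 55))
            e2 = int(rng.integers(30, 55))
            gap = int(rng.integers(20, 45))
            flank1 = int(rng.integers(5, 15))
            flank2 = int(rng.integers(5, 15))
            locus = rand_dna(rng, flank1 + e1 + gap + e2 + flank2)
            d = flank1 + e1
            a = d + gap
            # canonical GT..AG gap with a unique placement, like a real intron
            locus = self.plant_gap(locus, d, a)
            amplicon = list(locus[flank1:d] + locus[a : a + e2])
            if case % 2:  # up to 1% substitutions, away from the junction
                pos = int(rng.integers(6, len(amplicon) - 6))
                if abs(pos - e1) > 6:
                    amplicon[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[
                        amplicon[pos]
                    ]
            amplicon = "".join(amplicon)
            oracle = self.brute_force_single_gap(amplicon, locus)
            result = spliced_align(amplicon, locus, AlignParams(k=11))
            assert len(result.gaps) == 1, f"case {case}"
            assert result.gaps[0] == oracle, f"case {case}"

    def test_lowering_min_splice_gap_never_loses_gaps(self):
        rng = np.random.default_rng(5)
        locus = rand_dna(rng, 500)
        amplicon = locus[0:150] + locus[162:300] + locus[360:500]
        strict = spliced_align(amplicon, locus, AlignParams(min_splice_gap=20))
        loose = spliced_align(amplicon, locus, AlignParams(min_splice_gap=8))
        assert len(loose.gaps) >= len(strict.gaps)
        assert set(strict.gaps) <= set(loose.gaps)


class TestRefineBoundaries:
    def _one_gap(self, locus, gap):
        amplicon = locus[: gap[0]] + locus[gap[1] :]
        return make_alignment(
            [((0, gap[0]), (0, gap[0])),
             ((gap[0], len(amplicon)), (gap[1], len(locus)))],
            [gap],
        )

    def test_unique_canonical_placement_unchanged(self):
        #           0123456789
        locus = "TTTA" + "GT" + "CCCCAAT" + "AG" + "ATTT"
        aln = self._one_gap(locus, (4, 15))
        refine_boundaries(aln, locus)
        assert aln.gaps == [(4, 15)] and aln.gap_canonical == [True]

    def test_shift_finds_the_canonical_placement(self):
        # the two bases before the true gap repeat its last two ("AG"), so
        # the gap can slide 2 left without changing the spliced sequence;
        # only the true placement is GT..AG and refinement must pick it
        locus = "TTAG" + "GTCCCCAAAACCCCAG" + "CTTT"
        true_gap = (4, 20)
        shifted = (2, 18)
        assert locus[:2] + locus[18:] == locus[:4] + locus[20:]
        aln = self._one_gap(locus, shifted)
        refine_boundaries(aln, locus)
        assert aln.gaps == [true_gap]
        assert aln.gap_canonical == [True]
        # blocks were adjusted consistently
        assert aln.blocks[0].t[1] == true_gap[0]
        assert aln.blocks[1].t[0] == true_gap[1]

    def test_no_canonical_placement_keeps_leftmost(self):
        locus = "TTTA" + "CC" + "CCCCAAT" + "TT" + "ATTT"
        aln = self._one_gap(locus, (4, 15))
        refine_boundaries(aln, locus)
        assert aln.gap_canonical == [False]
        # leftmost placement: shifted as far left as sequence allows
        g0, g1 = aln.gaps[0]
        assert g0 == 0 or locus[g0 - 1] != locus[g1 - 1]

    @staticmethod
    def brute_force_shifts(locus, gap):
        """All placements of the gap that preserve the spliced sequence."""
        g0, g1 = gap
        reference = locus[:g0] + locus[g1:]
        out = []
        for s in range(-g0, len(locus) - g1 + 1):
            if locus[: g0 + s] + locus[g1 + s :] == reference:
                out.append(s)
        return out

    def test_agrees_with_brute_force_shift_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            locus = rand_dna(rng, 120)
            g0 = int(rng.integers(20, 60))
            g1 = g0 + int(rng.integers(10, 40))
            shifts = self.brute_force_shifts(locus, (g0, g1))
            assert shifts  # 0 is always sequence-preserving
            canonical = [
                s
                for s in shifts
                if locus[g0 + s : g0 + s + 2] == "GT"
                and locus[g1 + s - 2 : g1 + s] == "AG"
            ]
            aln = self._one_gap(locus, (g0, g1))
            refine_boundaries(aln, locus)
            chosen = aln.gaps[0][0] - g0
            if canonical:
                assert chosen == min(canonical)
                assert aln.gap_canonical == [True]
            else:
                assert chosen == min(shifts)
                assert aln.gap_canonical == [False]


class TestClassifyAmplicon:
    CAND = (300, 330)
    INTRONS = [(300, 330), (500, 580)]

    def test_contiguous_alignment_is_genomic(self):
        aln = make_alignment([((0, 600), (100, 700))], [])
        v = classify_amplicon(aln, self.CAND, self.INTRONS)
        assert v.call is VerdictCall.GDNA_UNABLE_TO_JUDGE

    def test_control_spliced_candidate_retained(self):
        aln = make_alignment(
            [((0, 400), (100, 500)), ((400, 520), (580, 700))], [(500, 580)]
        )
        v = classify_amplicon(aln, self.CAND, self.INTRONS)
        assert v.call is VerdictCall.CDNA_NOT_AN_INTRON
        assert v.extra_splicing == []

    def test_exact_gap_confirms_the_intron(self):
        aln = make_alignment(
            [((0, 200), (100, 300)), ((200, 370), (330, 500)),
             ((370, 490), (580, 700))],
            [(300, 330), (500, 580)],
        )
        v = classify_amplicon(aln, self.CAND, self.INTRONS)
        assert v.call is VerdictCall.CDNA_CONFIRMED
        assert v.actual_intron == self.CAND and v.canonical is True

    def test_larger_gap_reannotates_the_intron(self):
        # 30 bp prediction inside an 83 bp actual gap
        aln = make_alignment(
            [((0, 190), (100, 290)), ((190, 317), (373, 500)),
             ((317, 437), (580, 700))],
            [(290, 373), (500, 580)],
        )
        v = classify_amplicon(aln, self.CAND, self.INTRONS)
        assert v.call is VerdictCall.CDNA_LARGER
        assert v.actual_length == 83

    def test_unannotated_gap_reported_as_extra_splicing(self):
        aln = make_alignment(
            [((0, 200), (100, 300)), ((200, 250), (330, 380)),
             ((250, 300), (420, 470)), ((300, 330), (580, 610))],
            [(300, 330), (380, 420), (470, 580)],
        )
        v = classify_amplicon(aln, self.CAND, self.INTRONS)
        assert v.call is VerdictCall.CDNA_CONFIRMED
        assert (380, 420) in v.extra_splicing

    def test_uncovered_candidate_is_error(self):
        from intron_audit.verdict import CoverageError

        aln = make_alignment([((0, 100), (400, 500))], [])
        with pytest.raises(CoverageError):
            classify_amplicon(aln, self.CAND, self.INTRONS)

    def test_locus_offset_applied(self):
        aln = make_alignment(
            [((0, 200), (0, 200)), ((200, 320), (230, 350))], [(200, 230)]
        )
        v = classify_amplicon(aln, (300, 330), [(300, 330)], locus_offset=100)
        assert v.call is VerdictCall.CDNA_CONFIRMED
        assert v.actual_intron == (300, 330)


class TestVerifyPanel:
    def _run(self, world, tmp_path, error_rate, seed):
        out = tmp_path / "amps.fa"
        simulate_amplicons(
            world["pairs"], world["truth"], world["genome"], out,
            error_rate=error_rate, seed=seed,
        )
        return verify_panel(
            out, world["pairs"], world["model_map"], world["genome"]
        )

    def _check(self, world, verdicts):
        truth = world["truth"].by_candidate()
        assert len(verdicts) == len(world["pairs"])
        for cand_id, v in verdicts:
            sc = truth[cand_id]
            assert v.call is sc.expected_call, cand_id
            if sc.kind is ScenarioKind.BOUNDARY_SHIFT:
                assert v.actual_intron == sc.true_interval, cand_id
                assert v.canonical is True
            if sc.expect_extra_splicing:
                assert v.extra_splicing, cand_id

    def test_error_free_panel_recovers_truth(self, synthetic_world, tmp_path):
        self._check(synthetic_world, self._run(synthetic_world, tmp_path, 0.0, 3))

    def test_sequencing_noise_does_not_change_verdicts(
        self, synthetic_world, tmp_path
    ):
        self._check(synthetic_world, self._run(synthetic_world, tmp_path, 0.005, 3))

    def test_empty_fasta_gives_empty_result(self, synthetic_world, tmp_path):
        empty = tmp_path / "empty.fa"
        empty.write_text("")
        assert verify_panel(
            empty, synthetic_world["pairs"], synthetic_world["model_map"],
            synthetic_world["genome"],
        ) == []

    def test_unknown_candidate_header_is_error(self, synthetic_world, tmp_path):
        bad = tmp_path / "bad.fa"
        bad.write_text(">NOSUCH.1-1|1\nACGTACGTACGT\n")
        with pytest.raises(KeyError):
            verify_panel(
                bad, synthetic_world["pairs"], synthetic_world["model_map"],
                synthetic_world["genome"],
            )
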