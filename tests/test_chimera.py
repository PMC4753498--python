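"""Coverage-gap scanning, direct-repeat search, excision and validation."""

import numpy as np
import pytest

from gluegene import (
    ChimeraConfig,
    ChimeraSpec,
    CoverageGap,
    NucSeq,
    build_chimeric_cdna,
    call_chimera,
    excise_and_validate,
    find_coverage_gaps,
    flanking_direct_repeats,
)
from gluegene.mapping import CoverageTrack
from gluegene.synthetic_data import random_nucseq


def _track(depths):
    return CoverageTrack("t", np.array(depths, dtype=int))


class TestCoverageGaps:
    def test_run_scan_by_hand(self):
        gaps = find_coverage_gaps(
            _track([5, 5, 0, 0, 0, 5, 5]), min_gap_len=3, end_margin=0
        )
        assert len(gaps) == 1 and gaps[0].interval == (2, 5)
        assert gaps[0].internal_depth_max == 0
        assert gaps[0].flank_depth_mean == 5.0

    def test_uniform_positive_depth_no_gaps(self):
        assert find_coverage_gaps(_track([3] * 100), end_margin=0) == []

    def test_gap_touching_end_suppressed(self):
        depths = [0] * 60 + [5] * 100
        assert find_coverage_gaps(_track(depths), min_gap_len=50, end_margin=25) == []
        assert (
            find_coverage_gaps(_track(depths), min_gap_len=50, end_margin=0)[0].interval
            == (0, 60)
        )

    def test_short_runs_filtered(self):
        depths = [5] * 30 + [0] * 10 + [5] * 30
        assert find_coverage_gaps(_track(depths), min_gap_len=50, end_margin=0) == []


def _brute_force_repeats(s, gap, min_repeat, max_offset, max_mismatch, max_repeat_len):
    """O(n^2 L) reference search with the same tie-break as the implementation."""
    gs, ge = gap
    n = len(s)
    best = None
    for rs in range(max(0, ge - max_offset), min(n - min_repeat, ge + max_offset) + 1):
        for e in range(max(min_repeat, gs - max_offset), min(gs + max_offset, rs) + 1):
            for L in range(min_repeat, min(e, max_repeat_len, n - rs) + 1):
                x0 = e - L
                if e > rs:
                    continue
                mm = sum(a != b for a, b in zip(s[x0:e], s[rs : rs + L]))
                if mm > max_mismatch:
                    continue
                dist = abs(e - gs) + abs(rs - ge)
                cand = (-L, dist, x0, rs, mm)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    L, dist, x0, rs, mm = -best[0], best[1], best[2], best[3], best[4]
    return ((x0, x0 + L), (rs, rs + L), L, 1 - mm / L)


class TestDirectRepeats:
    def test_planted_60bp_repeat_found_with_full_identity(self):
        base = random_nucseq(1000, seed=31, seq_id="b")
        chim, truth = build_chimeric_cdna(
            base, ChimeraSpec(insertion_point=500), seed=32
        )
        gap = CoverageGap(truth.inserted_interval, 30.0, 0)
        pair = flanking_direct_repeats(chim, gap)
        assert pair is not None
        # the search may extend past the planted 60-mer when the flanking
        # base coincides by chance; the copies stay 100% identical
        assert pair.length >= 60 and pair.identity == 1.0
        assert pair.left[0] == truth.left_repeat[0]
        assert pair.right[0] == truth.right_repeat[0]
        assert chim.bases[slice(*pair.left)] == chim.bases[slice(*pair.right)]

    def test_no_repeat_returns_none(self):
        seq = random_nucseq(300, seed=33, seq_id="s")
        gap = CoverageGap((100, 200), 10.0, 0)
        assert flanking_direct_repeats(seq, gap) is None

    def test_agrees_with_brute_force_on_planted_cases(self):
        rng = np.random.default_rng(34)
        n_checked = 0
        for case in range(50):
            rep_len = int(rng.integers(20, 45))
            insert_len = int(rng.integers(60, 120))
            pre = "".join(rng.choice(list("ACGT"), size=int(rng.integers(60, 100))))
            post = "".join(rng.choice(list("ACGT"), size=int(rng.integers(60, 100))))
            rep = "".join(rng.choice(list("ACGT"), size=rep_len))
            ins = "".join(rng.choice(list("ACGT"), size=insert_len))
            s = pre + rep + ins + rep + post
            seq = NucSeq(f"case{case}", s)
            gs = len(pre) + rep_len  # desert = foreign + second repeat copy
            ge = gs + insert_len + rep_len
            gap = CoverageGap((gs, ge), 30.0, 0)
            kwargs = dict(
                min_repeat=20, max_offset=40, max_mismatch=0, max_repeat_len=200
            )
            got = flanking_direct_repeats(seq, gap, **kwargs)
            want = _brute_force_repeats(s, (gs, ge), **kwargs)
            assert got is not None and want is not None
            assert (got.left, got.right, got.length, got.identity) == want
            n_checked += 1
        assert n_checked == 50


class TestExciseAndValidate:
    def test_excision_restores_base_sequence(self, gene, chimeric_cdna, genomic_reads):
        g, _ = gene
        chim, truth = chimeric_cdna
        reads, _ = genomic_reads
        calls = call_chimera(chim, reads=reads)
        assert len(calls) == 1
        call = calls[0]
        assert call.validated
        assert call.excised_len == 363 + 60
        assert call.edited_seq.bases == g.bases
        # the planted copies are 60 bp; chance matching can extend the pair
        assert call.repeats.length >= 60 and call.repeats.identity == 1.0

    def test_excised_length_and_edited_length_consistent(self, chimeric_cdna, genomic_reads):
        chim, _ = chimeric_cdna
        reads, _ = genomic_reads
        (call,) = call_chimera(chim, reads=reads)
        assert len(call.edited_seq) == len(chim) - call.excised_len

    def test_without_repeats_excises_bare_gap(self, gene, genomic_reads):
        g, _ = gene
        reads, _ = genomic_reads
        gap = CoverageGap((1000, 1100), 30.0, 0)
        call = excise_and_validate(g, gap, None, reads)
        assert call.excised_interval == (1000, 1100) and call.excised_len == 100

    def test_true_dropout_fails_validation(self, gene):
        # reads genuinely span the "gap" (deterministic 300 bp tiles at
        # stride 50): after excision the junction is discordant, no tile maps
        # across it, and none ends exactly at the junction, so the junction
        # window is uncovered
        from gluegene import FastqRead, ReadPair

        g, _ = gene
        tiles = [
            FastqRead(f"t{s}", g.bases[s : s + 300], (40,) * 300)
            for s in range(0, len(g) - 300 + 1, 50)
        ]
        reads = [
            ReadPair(
                tiles[i],
                FastqRead(
                    tiles[i + 1].id + "b",
                    NucSeq("x", tiles[i + 1].bases).revcomp().bases,
                    (40,) * 300,
                ),
            )
            for i in range(0, len(tiles) - 1, 2)
        ]
        gap = CoverageGap((1501, 1924), 30.0, 0)
        cfg = ChimeraConfig(max_mismatch_frac=0.0)
        call = excise_and_validate(g, gap, None, reads, cfg)
        assert not call.validated and call.junction_min_depth == 0

    def test_excising_everything_rejected(self, gene, genomic_reads):
        g, _ = gene
        reads, _ = genomic_reads
        gap = CoverageGap((0, len(g)), 0.0, 0)
        with pytest.raises(ValueError, match="empty"):
            excise_and_validate(g, gap, None, reads)


class TestCallChimera:
    def test_clean_transcript_yields_no_calls(self, gene, genomic_reads):
        g, _ = gene
        reads, _ = genomic_reads
        assert call_chimera(g, reads=reads) == []

    def test_reads_simulated_from_genomic_contig(self, gene, chimeric_cdna):
        g, _ = gene
        chim, truth = chimeric_cdna
        (call,) = call_chimera(chim, genomic=g, cfg=ChimeraConfig(seed=42))
        assert call.validated and call.excised_interval == truth.inserted_interval

    def test_two_planted_insertions_both_recovered(self, gene):
        g, _ = gene
        first, t1 = build_chimeric_cdna(
            g, ChimeraSpec(insertion_point=1000), seed=43
        )
        second, t2 = build_chimeric_cdna(
            first, ChimeraSpec(insertion_point=2500), seed=44
        )
        calls = call_chimera(second, genomic=g, cfg=ChimeraConfig(seed=45))
        assert len(calls) == 2
        intervals = sorted(c.excised_interval for c in calls)
        # first insertion's coordinates, as seen in the double chimera
        assert intervals[0] == t1.inserted_interval
        assert intervals[1] == t2.inserted_interval

    def test_requires_reads_or_genomic(self, chimeric_cdna):
        chim, _ = chimeric_cdna
        with pytest.raises(ValueError, match="reads or a genomic contig"):
            call_chimera(chim)
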