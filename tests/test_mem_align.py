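from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reconasm.seqio import Contig, reverse_complement
from reconasm.mem_align import (
    AlignParams,
    MatchBlock,
    best_chain,
    chain_mems,
    coverage,
    find_mems,
    is_contained,
)

from _oracles import contained_oracle, mems_oracle
from conftest import random_dna


def as_tuples(blocks):
    return {(b.strand, b.q_start, b.q_end, b.t_start, b.t_end) for b in blocks}


def related_pair(rng, n_max=300):
    """A pair of sequences with planted shared structure so that MEMs
    actually occur: shared segments, mutated copies, or tandem text."""
    kind = rng.integers(0, 4)
    n = int(rng.integers(30, n_max))
    a = random_dna(rng, n)
    if kind == 0:  # independent random pair
        return a, random_dna(rng, int(rng.integers(30, n_max)))
    if kind == 1:  # shared segment, possibly reverse-complemented
        m = int(rng.integers(10, n))
        s, t = sorted(rng.integers(0, n - m + 1, 2))
        seg = a[s : s + m]
        if rng.random() < 0.5:
            seg = reverse_complement(seg)
        b = random_dna(rng, 20) + seg + random_dna(rng, 20)
        return a, b
    if kind == 2:  # mutated copy with occasional Ns
        arr = list(a)
        for i in rng.integers(0, n, max(1, n // 15)):
            arr[i] = "ACGTN"[rng.integers(0, 5)]
        return a, "".join(arr)
    unit = random_dna(rng, int(rng.integers(2, 8)))  # tandem repeats
    return unit * int(rng.integers(2, 12)), unit * int(rng.integers(2, 12))


class TestFindMems:
    def test_equal_sequences_single_forward_block(self):
        blocks = find_mems("AAACCC", "AAACCC", 4)
        assert as_tuples(blocks) == {("+", 0, 6, 0, 6)}

    def test_reverse_complement_only_match(self):
        blocks = find_mems("TTTTT", "AAAAA", 4)
        assert as_tuples(blocks) == {("-", 0, 5, 0, 5)}

    def test_random_pair_has_no_long_mems(self, rng):
        q, t = random_dna(rng, 200), random_dna(rng, 200)
        assert find_mems(q, t, 20) == []
        assert as_tuples(find_mems(q, t, 8)) == mems_oracle(q, t, 8)

    def test_n_never_matches(self):
        assert find_mems("ACGTNACGT", "ACGTNACGT", 9) == []
        blocks = find_mems("AANAA", "AANAA", 2)
        assert all(b.length == 2 for b in blocks)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_mems("", "ACGT", 2)

    @pytest.mark.parametrize("trial", range(40))
    def test_agrees_with_diagonal_scan_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        q, t = related_pair(rng)
        k = int(rng.integers(3, 22))
        assert as_tuples(find_mems(q, t, k)) == mems_oracle(q, t, k)

    @pytest.mark.parametrize("trial", range(10))
    def test_symmetry_transpose(self, trial):
        rng = np.random.default_rng(2000 + trial)
        q, t = related_pair(rng, 150)
        k = int(rng.integers(4, 15))
        fwd = as_tuples(find_mems(q, t, k))
        rev = as_tuples(find_mems(t, q, k))
        # transposition swaps the coordinate pairs on either strand
        assert {(s, ts, te, qs, qe) for s, qs, qe, ts, te in fwd} == rev

    def test_self_comparison_identity_excluded_repeats_kept(self):
        g = "ACGTACGTAC"
        blocks = find_mems(g, g, 4, exclude_identity=True)
        assert ("+", 0, 10, 0, 10) not in as_tuples(blocks)
        assert any(b.strand == "+" for b in blocks)  # the shifted repeat match
        assert as_tuples(blocks) == mems_oracle(g, g, 4, exclude_identity=True)


def mk_block(qs, qe, ts, te, strand="+", q="q", t="t"):
    return MatchBlock(q, t, qs, qe, ts, te, strand)


class TestChaining:
    def test_single_block_chain(self):
        [c] = chain_mems([mk_block(0, 150, 0, 150)], AlignParams())
        assert (c.matched, c.max_indel) == (150, 0)

    def test_two_blocks_equal_gaps_no_indel(self):
        blocks = [mk_block(0, 120, 0, 120), mk_block(130, 260, 130, 260)]
        [c] = chain_mems(blocks, AlignParams())
        assert (c.matched, c.max_indel) == (250, 0)

    def test_gap_above_maxgap_splits(self):
        blocks = [mk_block(0, 120, 0, 120), mk_block(120, 260, 720, 860)]
        chains = chain_mems(blocks, AlignParams())
        assert len(chains) == 2
        assert {c.matched for c in chains} == {120, 140}

    def test_gap_at_maxgap_joins(self):
        blocks = [mk_block(0, 120, 0, 120), mk_block(120, 260, 620, 760)]
        [c] = chain_mems(blocks, AlignParams())
        assert c.max_indel == 500

    def test_indel_is_gap_difference(self):
        # query carries a 200 bp insertion between the two exact pieces
        blocks = [mk_block(0, 120, 0, 120), mk_block(320, 440, 120, 240)]
        [c] = chain_mems(blocks, AlignParams())
        assert c.max_indel == 200

    def test_mincluster_drops_short_chains(self):
        assert chain_mems([mk_block(0, 60, 0, 60)], AlignParams()) == []

    def test_matched_never_exceeds_block_total(self, rng):
        blocks = []
        for _ in range(15):
            qs = int(rng.integers(0, 500))
            ts = int(rng.integers(0, 500))
            ln = int(rng.integers(20, 80))
            blocks.append(mk_block(qs, qs + ln, ts, ts + ln))
        total = sum(b.length for b in blocks)
        for c in chain_mems(blocks, AlignParams(mincluster=20)):
            assert c.matched <= total

    def test_overlapping_blocks_trimmed(self):
        blocks = [mk_block(0, 120, 0, 120), mk_block(100, 240, 100, 240)]
        [c] = chain_mems(blocks, AlignParams())
        assert c.matched == 240  # 120 + 140 - 20 overlap
        assert c.max_indel == 0


class TestBestChain:
    def test_identical_contigs(self, rng):
        s = random_dna(rng, 400)
        c = best_chain(Contig("a", s), Contig("b", s), AlignParams())
        assert c.matched == 400 and c.max_indel == 0

    def test_substring_beats_spurious_short_match(self, rng):
        target_seq = random_dna(rng, 2000)
        q = target_seq[300:900]
        # append a second spurious shared 20-mer elsewhere in the query
        q = q + target_seq[1500:1520]
        c = best_chain(Contig("q", q), Contig("t", target_seq), AlignParams())
        assert c.matched >= 600
        assert c.t_span[0] == 300

    def test_no_match_returns_none(self, rng):
        assert (
            best_chain(
                Contig("q", random_dna(rng, 300)),
                Contig("t", random_dna(rng, 300)),
                AlignParams(),
            )
            is None
        )


class TestCoverage:
    def test_interval_union(self):
        chains = chain_mems(
            [mk_block(0, 50, 0, 50), mk_block(60, 110, 25, 75)],
            AlignParams(min_match=10, mincluster=20),
        )
        assert coverage(chains, 100).fraction == pytest.approx(0.75)

    def test_empty_and_full(self):
        assert coverage([], 100).fraction == 0.0
        [c] = chain_mems([mk_block(0, 100, 0, 100)], AlignParams())
        assert coverage([c], 100).fraction == 1.0

    def test_monotone_under_adding_chains(self):
        c1 = chain_mems([mk_block(0, 100, 0, 100)], AlignParams())
        c2 = chain_mems([mk_block(100, 220, 150, 270)], AlignParams())
        one = coverage(c1, 300).fraction
        both = coverage(c1 + c2, 300).fraction
        assert 0 <= one <= both <= 1

    def test_bad_target_length(self):
        with pytest.raises(ValueError):
            coverage([], 0)


class TestContainment:
    def test_identity_and_substring(self, rng):
        s = random_dna(rng, 200)
        assert is_contained(Contig("a", s), Contig("b", s))
        assert is_contained(Contig("a", s[10:60]), Contig("b", s))

    def test_reverse_complement_substring(self, rng):
        s = random_dna(rng, 200)
        a = reverse_complement(s[5:50])
        assert is_contained(Contig("a", a), Contig("b", s))

    @pytest.mark.parametrize("trial", range(20))
    def test_agrees_with_position_scan_oracle(self, trial):
        rng = np.random.default_rng(3000 + trial)
        b = random_dna(rng, int(rng.integers(50, 300)))
        if rng.random() < 0.6:
            m = int(rng.integers(5, len(b)))
            s = int(rng.integers(0, len(b) - m + 1))
            a = b[s : s + m]
            if rng.random() < 0.5:
                a = reverse_complement(a)
        else:
            a = random_dna(rng, int(rng.integers(5, 60)))
        assert is_contained(Contig("a", a), Contig("b", b)) == contained_oracle(a, b)
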