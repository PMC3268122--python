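from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from reconasm.seqio import reverse_complement
from reconasm.metrics import complexity, similarity
from reconasm.simulate import (
    SimParams,
    build_fixture,
    generate_genome,
    make_fixture_acontigs,
    make_fixture_assemblies,
    make_reference,
    mutate_reference,
    simulate_reads,
    tile_genome,
)


class TestGenerateGenome:
    def test_deterministic_per_seed(self):
        g1, a1 = generate_genome(5_000, ((300, 2),), seed=9)
        g2, a2 = generate_genome(5_000, ((300, 2),), seed=9)
        assert g1 == g2 and a1 == a2
        g3, _ = generate_genome(5_000, ((300, 2),), seed=10)
        assert g3 != g1

    def test_planted_repeats_annotated_and_measurable(self):
        g, ann = generate_genome(50_000, ((2_500, 2),), seed=4)
        assert len(ann) == 2
        (r1, s1, e1), (r2, s2, e2) = ann
        assert g[s1:e1] == g[s2:e2]
        assert complexity(g) == pytest.approx(0.1, abs=0.005)

    def test_no_repeats_zero_complexity(self):
        g, ann = generate_genome(30_000, (), seed=4)
        assert ann == [] and complexity(g) == 0.0

    def test_infeasible_placement_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(1_000, ((600, 2),), seed=1)


class TestMutateReference:
    def test_zero_rates_identity(self):
        g, _ = generate_genome(20_000, seed=2)
        ref, log = mutate_reference(g, 0.0)
        assert ref == g and log == []

    def test_similarity_decreases_with_rate(self):
        g, _ = generate_genome(30_000, seed=2)
        s1 = similarity(g, mutate_reference(g, 0.01, seed=7)[0])
        s2 = similarity(g, mutate_reference(g, 0.05, seed=7)[0])
        assert 0 < s2 < s1 < 1

    def test_structural_events_logged_faithfully(self):
        g, _ = generate_genome(60_000, seed=3)
        ref, log = mutate_reference(g, 0.0, n_rearrangements=4, seed=3)
        events = [e for e in log if e["kind"] != "substitutions"]
        assert len(events) == 4
        for ev in events:
            if ev["kind"] == "insertion":
                assert ev["seq"] in ref and ev["seq"] not in g
            elif ev["kind"] == "deletion":
                assert g[ev["g_start"] : ev["g_end"]] not in ref
            elif ev["kind"] == "inversion":
                assert reverse_complement(g[ev["g_start"] : ev["g_end"]]) in ref
            else:  # translocation: segment still present, context moved
                assert g[ev["g_start"] : ev["g_end"]] in ref

    def test_calibration_reaches_band(self):
        g, _ = generate_genome(60_000, ((800, 2),), seed=6)
        ref, log, sim = make_reference(g, seed=6)
        assert 0.80 <= sim <= 0.92
        assert sim == pytest.approx(similarity(g, ref))
        assert any(e["kind"] != "substitutions" for e in log)


class TestSimulateReads:
    def test_pair_count_follows_coverage_formula(self):
        g, _ = generate_genome(15_000, seed=1)
        pairs = simulate_reads(g, SimParams(seed=1))
        # G*C/(2R) = 15000*60/150
        assert len(pairs) == 6_000
        assert all(len(p.fwd) == 75 and len(p.rev) == 75 for p in pairs[:100])

    def test_tiny_coverage_floor_zero(self):
        g, _ = generate_genome(1_000, seed=1)
        assert simulate_reads(g, SimParams(C=0.1, L=300, R=160, seed=1)) == []

    def test_reads_reconstruct_fragment_ends(self):
        g, _ = generate_genome(5_000, seed=8)
        p = SimParams(C=2, seed=8)
        for rp in simulate_reads(g, p)[:50]:
            frag = g[rp.frag_start : rp.frag_start + p.L]
            assert rp.fwd == frag[: p.R]
            assert rp.rev == reverse_complement(frag[p.L - p.R :])

    def test_uniform_start_positions(self):
        g, _ = generate_genome(50_000, seed=5)
        p = SimParams(C=10, seed=5)
        starts = np.array([rp.frag_start for rp in simulate_reads(g, p)])
        res = sps.kstest(starts, sps.uniform(loc=0, scale=len(g) - p.L).cdf)
        assert res.pvalue > 0.001

    def test_mean_depth_matches_coverage(self):
        g, _ = generate_genome(100_000, seed=5)
        p = SimParams(seed=5)
        pairs = simulate_reads(g, p)
        depth = np.zeros(len(g))
        for rp in pairs:
            depth[rp.frag_start : rp.frag_start + p.R] += 1
            depth[rp.frag_start + p.L - p.R : rp.frag_start + p.L] += 1
        mean = depth[p.L : -p.L].mean()  # interior, away from edge effects
        se = depth[p.L : -p.L].std() / np.sqrt(len(pairs))
        assert abs(mean - p.C) <= 3 * max(se, 0.1)

    def test_bit_reproducible(self):
        g, _ = generate_genome(5_000, seed=3)
        a = simulate_reads(g, SimParams(C=2, seed=11))
        b = simulate_reads(g, SimParams(C=2, seed=11))
        assert [(x.fwd, x.rev, x.frag_start) for x in a] == [
            (x.fwd, x.rev, x.frag_start) for x in b
        ]

    def test_genome_shorter_than_fragment_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads("ACGT" * 10, SimParams())


class TestFixtureAssemblies:
    def test_zero_chimera_rate_all_bona_fide(self):
        g, _ = generate_genome(30_000, seed=2)
        asms = make_fixture_assemblies(g, 3, 1_500, 0.0, seed=2)
        assert len(asms) == 3
        for a in asms:
            for c in a:
                assert c.truth == "bona_fide"
                assert c.seq in g

    def test_chimeras_labeled_and_never_shared(self):
        g, _ = generate_genome(60_000, seed=7)
        asms = make_fixture_assemblies(g, 3, 2_000, 0.3, seed=7)
        chims = [{c.seq for c in a if c.truth == "chimeric"} for a in asms]
        assert all(chims)
        assert not (chims[0] & chims[1] or chims[0] & chims[2] or chims[1] & chims[2])
        for a in asms:
            for c in a:
                assert (c.seq in g) == (c.truth == "bona_fide")

    def test_single_assembly_rejected(self):
        g, _ = generate_genome(10_000, seed=2)
        with pytest.raises(ValueError):
            make_fixture_assemblies(g, 1, 1_500, 0.0, seed=2)


@pytest.fixture(scope="module")
def genome_and_refs():
    g, _ = generate_genome(60_000, seed=9)
    refs = []
    for j in range(2):
        ref, log = mutate_reference(g, 0.02, n_rearrangements=3, seed=20 + j)
        refs.append((f"ref{j + 1}", ref, log))
    return g, refs


class TestFixtureAcontigs:

    def test_miss_rate_zero_all_genuine(self, genome_and_refs):
        g, refs = genome_and_refs
        for aset in make_fixture_acontigs(g, refs, miss_rate=0.0, seed=1):
            assert all(c.truth == "bona_fide" and c.seq in g for c in aset)

    def test_miss_rate_one_chimera_per_event(self, genome_and_refs):
        g, refs = genome_and_refs
        sets = make_fixture_acontigs(g, refs, miss_rate=1.0, seed=1)
        for aset, (_rid, _r, log) in zip(sets, refs):
            n_events = sum(1 for e in log if e["kind"] != "substitutions")
            chims = [c for c in aset if c.truth == "chimeric"]
            assert len(chims) == n_events
            for c in chims:
                assert c.seq not in g
                assert c.meta["variant"] in (
                    "insertion",
                    "deletion",
                    "inversion",
                    "translocation",
                )

    def test_genuine_contigs_are_genome_substrings(self, genome_and_refs):
        g, refs = genome_and_refs
        for aset in make_fixture_acontigs(g, refs, miss_rate=1.0, seed=1):
            for c in aset:
                if c.truth == "bona_fide":
                    assert c.seq in g and len(c.seq) >= 500


class TestTilingAndFixture:
    def test_tiling_covers_genome_with_overlap(self):
        g, _ = generate_genome(30_000, seed=1)
        dbg = tile_genome(g, 5_000, 2_000)
        assert all(c.seq in g for c in dbg)
        covered = np.zeros(len(g), dtype=int)
        pos = 0
        for c in dbg:
            start = g.find(c.seq)
            covered[start : start + len(c.seq)] += 1
        assert covered.min() >= 1
        assert covered[2_500:-2_500].min() >= 2  # interior double coverage

    def test_build_fixture_reproducible(self):
        fx1 = build_fixture(2, genome_len=30_000, n_rearrangements=2, n_refs=1)
        fx2 = build_fixture(2, genome_len=30_000, n_rearrangements=2, n_refs=1)
        assert fx1.genome == fx2.genome
        assert [c.seq for a in fx1.acontig_sets for c in a] == [
            c.seq for a in fx2.acontig_sets for c in a
        ]
        assert 0.80 <= similarity(fx1.genome, fx1.references[0][1]) <= 0.92
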