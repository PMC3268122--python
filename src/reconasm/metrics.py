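"""Evaluation quantities: repeat complexity, genome similarity,
contiguity statistics, bona fide classification and rank scoring.

Definitions
-----------
complexity
    Fraction of genome positions inside at least one non-identity
    maximal exact self-match of a minimum length (both strands) — a
    simple repeat-content measure.
similarity
    (covered_a + covered_b) / (len_a + len_b), where covered_x is the
    union length of positions of x inside maximal exact matches
    between the two genomes. Positions are unioned, not summed, so
    identical genomes score exactly 1. Diverged reference genomes
    suitable for comparative assembly sit in the 0.80-0.92 band.
N50 (genome-relative, a.k.a. NG50)
    After sorting contigs by descending length, the length of the
    first contig at which the cumulative length reaches half the
    *genome* length (0 if it never does).
accuracy
    The proportion of bona fide contigs — contigs mapping colinearly,
    near-full-length, to the truth genome in a single chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .seqio import Assembly, Contig
from .mem_align import (
    AlignParams,
    KmerIndex,
    _chain_rank,
    chains_against_index,
    find_mems,
    merge_intervals,
)


@dataclass(frozen=True)
class BonaFideParams:
    """Thresholds for calling a contig bona fide against the truth
    genome: one chain must match at least ``min_cov`` of the contig
    with no indel above ``max_indel``."""

    min_cov: float = 0.95
    max_indel: int = 50
    align: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if not 0 < self.min_cov <= 1:
            raise ValueError("min_cov must be in (0, 1]")


@dataclass
class AssemblyStats:
    total_len: int
    n_contigs: int
    avg_len: float
    n50: int
    longest: int
    genome_fraction: float | None = None
    accuracy: float | None = None


@dataclass
class GenomeMetrics:
    length: int
    complexity: float
    similarity_to: dict[str, float]


def complexity(genome: str, min_repeat_len: int = 20) -> float:
    """Fraction of genome positions lying inside a non-identity maximal
    exact self-match of length >= ``min_repeat_len`` (both strands)."""
    if not genome:
        raise ValueError("empty genome")
    if len(genome) < min_repeat_len:
        raise ValueError("genome shorter than min_repeat_len")
    blocks = find_mems(
        genome, genome, min_repeat_len, q_id="g", t_id="g", exclude_identity=True
    )
    ivs = [(b.q_start, b.q_end) for b in blocks] + [
        (b.t_start, b.t_end) for b in blocks
    ]
    covered = sum(b - a for a, b in merge_intervals(ivs))
    return covered / len(genome)


def similarity(a: str, b: str, min_match_len: int = 20) -> float:
    """Symmetric exact-match similarity between two genomes in [0, 1]."""
    if not a or not b:
        raise ValueError("empty input sequence")
    blocks = find_mems(a, b, min_match_len, q_id="a", t_id="b")
    cov_a = sum(e - s for s, e in merge_intervals((x.q_start, x.q_end) for x in blocks))
    cov_b = sum(e - s for s, e in merge_intervals((x.t_start, x.t_end) for x in blocks))
    return (cov_a + cov_b) / (len(a) + len(b))


def genome_metrics(
    genome: str,
    references: Mapping[str, str] | None = None,
    min_match_len: int = 20,
) -> GenomeMetrics:
    sims = {
        rid: similarity(genome, rseq, min_match_len)
        for rid, rseq in (references or {}).items()
    }
    return GenomeMetrics(len(genome), complexity(genome, min_match_len), sims)


def n50(contig_lengths: Sequence[int], genome_len: int) -> int:
    """Genome-relative N50; 0 if the total never reaches half the
    genome length."""
    if genome_len <= 0:
        raise ValueError("genome length must be positive")
    total = 0
    for length in sorted(contig_lengths, reverse=True):
        total += length
        if 2 * total >= genome_len:
            return length
    return 0


def _truth_index(truth_genome: str, params: BonaFideParams) -> KmerIndex:
    return KmerIndex([("truth", truth_genome)], params.align.min_match)


def _best_truth_chain(c: Contig, index: KmerIndex, params: BonaFideParams):
    chains = chains_against_index(c, index, params.align)
    if not chains:
        return None
    return min(chains, key=lambda ch: _chain_rank(ch, index.t_lens[0]))


def classify_bona_fide(
    c: Contig,
    truth_genome: str,
    params: BonaFideParams = BonaFideParams(),
    _index: KmerIndex | None = None,
) -> bool:
    """True iff the contig's best chain to the truth genome matches at
    least ``min_cov`` of it with no indel above ``max_indel``."""
    index = _index if _index is not None else _truth_index(truth_genome, params)
    chain = _best_truth_chain(c, index, params)
    return (
        chain is not None
        and chain.matched >= params.min_cov * len(c.seq)
        and chain.max_indel <= params.max_indel
    )


def accuracy(
    assembly: Assembly,
    truth_genome: str,
    params: BonaFideParams = BonaFideParams(),
) -> float:
    """Proportion of bona fide contigs in an assembly."""
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    index = _truth_index(truth_genome, params)
    n_good = sum(
        1 for c in assembly if classify_bona_fide(c, truth_genome, params, _index=index)
    )
    return n_good / len(assembly)


def genome_fraction(
    assembly: Assembly,
    truth_genome: str,
    params: BonaFideParams = BonaFideParams(),
) -> float:
    """Fraction of truth-genome positions covered by bona fide
    contigs."""
    index = _truth_index(truth_genome, params)
    ivs: list[tuple[int, int]] = []
    for c in assembly:
        chain = _best_truth_chain(c, index, params)
        if (
            chain is not None
            and chain.matched >= params.min_cov * len(c.seq)
            and chain.max_indel <= params.max_indel
        ):
            ivs.extend((b.t_start, b.t_end) for b in chain.blocks)
    covered = sum(e - s for s, e in merge_intervals(ivs))
    return covered / len(truth_genome)


def assembly_stats(
    assembly: Assembly,
    genome_len: int | None = None,
    truth_genome: str | None = None,
    params: BonaFideParams = BonaFideParams(),
) -> AssemblyStats:
    lengths = [len(c.seq) for c in assembly]
    if not lengths:
        raise ValueError("empty assembly")
    glen = genome_len if genome_len is not None else (
        len(truth_genome) if truth_genome else None
    )
    stats = AssemblyStats(
        total_len=sum(lengths),
        n_contigs=len(lengths),
        avg_len=sum(lengths) / len(lengths),
        n50=n50(lengths, glen) if glen else 0,
        longest=max(lengths),
    )
    if truth_genome:
        stats.accuracy = accuracy(assembly, truth_genome, params)
        stats.genome_fraction = genome_fraction(assembly, truth_genome, params)
    return stats


RANK_CATEGORIES = ("avg_len", "n50", "longest", "genome_fraction")


def rank_scores(
    datasets: Sequence[Mapping[str, Mapping[str, float]]],
    categories: Sequence[str] = RANK_CATEGORIES,
) -> dict[str, float]:
    """Weighted rank scoring of 4 methods across 4 categories.

    For each dataset and category, methods are ranked by descending
    value; the best gets weight 4 and the worst weight 1 (ties share
    the mean of the tied weights). The score of a method is the sum of
    its weights over all datasets and categories.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    methods = sorted(datasets[0])
    if len(methods) != 4:
        raise ValueError("the rank scoring scheme is defined for exactly 4 methods")
    scores = {m: 0.0 for m in methods}
    for table in datasets:
        if sorted(table) != methods:
            raise ValueError("datasets must report the same 4 methods")
        for cat in categories:
            vals = {m: table[m][cat] for m in methods}
            ordered = sorted(methods, key=lambda m: (-vals[m], m))
            weights = [4.0, 3.0, 2.0, 1.0]
            i = 0
            while i < len(ordered):
                j = i
                while j < len(ordered) and vals[ordered[j]] == vals[ordered[i]]:
                    j += 1
                w = sum(weights[i:j]) / (j - i)
                for m in ordered[i:j]:
                    scores[m] += w
                i = j
    return scores


def proportion_extended(
    denovo: Assembly,
    comparative: Assembly,
    align: AlignParams = AlignParams(),
    min_ext: int = 10,
) -> float:
    """Fraction of de novo contigs that a comparative contig could
    extend: the best-hit comparative contig protrudes at least
    ``min_ext`` bp beyond one end of the contig, or two de novo
    contigs share a best-hit comparative contig (a merge opportunity).
    """
    if len(denovo) == 0 or len(comparative) == 0:
        raise ValueError("both assemblies must be non-empty")
    index = KmerIndex([(c.id, c.seq) for c in comparative], align.min_match)
    t_len = {c.id: len(c.seq) for c in comparative}
    best_hit: dict[str, str] = {}
    extended: set[str] = set()
    for c in denovo:
        chains = chains_against_index(c, index, align)
        if not chains:
            continue
        ch = min(chains, key=lambda x: _chain_rank(x, t_len[x.t_id]))
        best_hit[c.id] = ch.t_id
        lq, lt = len(c.seq), t_len[ch.t_id]
        qs, qe = ch.q_span
        ts, te = ch.t_span
        if ch.strand == "+":
            left = ts - qs
            right = (lt - te) - (lq - qe)
        else:
            left = (lt - te) - qs
            right = ts - (lq - qe)
        if max(left, right) >= min_ext:
            extended.add(c.id)
    hits_per_target: dict[str, list[str]] = {}
    for cid, tid in best_hit.items():
        hits_per_target.setdefault(tid, []).append(cid)
    for cids in hits_per_target.values():
        if len(cids) > 1:
            extended.update(cids)
    return len(extended) / len(denovo)
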