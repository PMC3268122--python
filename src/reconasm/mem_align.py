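"""Maximal exact match discovery, colinear chaining and coverage.

This is the alignment engine behind every comparison the pipeline makes
(contig containment, best-hit assignment, repeat and similarity
measures). It mirrors the behaviour of a classical exact-match genome
aligner run in all-maximal-matches mode: seed maximal exact matches
(MEMs) of a minimum length on both strands, chain colinear ones with
bounded gaps, and drop chains below a minimum clustered length.

Conventions
-----------
* Coordinates are 0-based half-open internally; TSV reports emit
  1-based inclusive coordinates.
* The target is always in forward orientation; the ``strand`` flag
  describes the query.
* N never matches anything, including another N — a MEM cannot cover
  an N on either sequence.
* When query and target are the same sequence, the trivial identity
  diagonal is excluded but all other self-matches (including
  reverse-complement ones) are kept.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import Contig, reverse_complement


@dataclass(frozen=True)
class AlignParams:
    """Alignment settings.

    ``maxgap`` (max gap between chained matches, bp) and ``mincluster``
    (min total matched bp per retained chain) follow the classical
    exact-match aligner defaults used throughout the pipeline;
    ``min_match`` is the MEM seed length.
    """

    min_match: int = 20
    maxgap: int = 500
    mincluster: int = 100

    def __post_init__(self) -> None:
        if min(self.min_match, self.maxgap, self.mincluster) < 1:
            raise ValueError("all alignment parameters must be positive")
        if self.mincluster < self.min_match:
            raise ValueError("mincluster must be >= min_match")


@dataclass(frozen=True)
class MatchBlock:
    """One maximal exact match (or a trimmed piece of one, in chains)."""

    q_id: str
    t_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str  # '+' or '-', orientation of the query

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    def __post_init__(self) -> None:
        if self.q_end - self.q_start != self.t_end - self.t_start:
            raise ValueError("match block must have equal spans")
        if self.q_end <= self.q_start:
            raise ValueError("match block must have positive length")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class AlignmentChain:
    """A colinear chain of same-strand match blocks between one query
    and one target, with gap/indel accounting.

    ``max_indel`` is the largest absolute difference between the query
    gap and the target gap over adjacent block pairs — the chain-level
    signature of an insertion or deletion.
    """

    q_id: str
    t_id: str
    strand: str
    blocks: list[MatchBlock]
    matched: int
    max_indel: int
    q_span: tuple[int, int]
    t_span: tuple[int, int]


@dataclass
class CoverageProfile:
    """Union of covered target intervals and the covered fraction."""

    t_id: str
    t_len: int
    intervals: list[tuple[int, int]]
    fraction: float


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping half-open intervals into a disjoint
    sorted list."""
    ivs = sorted((a, b) for a, b in intervals if b > a)
    out: list[tuple[int, int]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


class KmerIndex:
    """Seed index over one or more target sequences.

    Targets are concatenated with a ``#`` sentinel so that no seed or
    extension can cross a target boundary; seeds containing N are not
    indexed, which together with the extension rule enforces the
    "N matches nothing" contract.
    """

    def __init__(self, targets: Sequence[tuple[str, str]], k: int):
        if k < 1:
            raise ValueError("seed length must be >= 1")
        for t_id, seq in targets:
            if not seq:
                raise ValueError(f"target {t_id!r} is empty")
        self.k = k
        self.t_ids = [t for t, _ in targets]
        self.seqs = [s for _, s in targets]
        self.t_lens = [len(s) for s in self.seqs]
        self.big = "#".join(self.seqs)
        offsets = []
        pos = 0
        for s in self.seqs:
            offsets.append(pos)
            pos += len(s) + 1
        self.offsets = offsets
        index: dict[str, list[int]] = {}
        big, n = self.big, len(self.big)
        for i in range(n - k + 1):
            seed = big[i : i + k]
            if "#" in seed or "N" in seed:
                continue
            index.setdefault(seed, []).append(i)
        self.index = index

    def _target_of(self, gpos: int) -> int:
        return bisect_right(self.offsets, gpos) - 1

    def _scan(
        self,
        q: str,
        strand: str,
        q_id: str,
        out: list[MatchBlock],
        exclude_self: bool,
        orig_len: int,
    ) -> None:
        k, big, index = self.k, self.big, self.index
        nq, nbig = len(q), len(self.big)
        self_targets: set[int] = set()
        if exclude_self and strand == "+":
            self_targets = {i for i, s in enumerate(self.seqs) if s == q}
        covered: dict[int, int] = {}  # diagonal -> query scan end of found run
        for i in range(nq - k + 1):
            hits = index.get(q[i : i + k])
            if hits is None:
                continue
            for g in hits:
                d = i - g
                if i < covered.get(d, 0):
                    continue  # inside a maximal run already reported
                ti = self._target_of(g)
                if self_targets and ti in self_targets and g - self.offsets[ti] == i:
                    continue  # identity diagonal of a self-comparison
                qi, gi = i, g
                while qi > 0 and gi > 0:
                    c = q[qi - 1]
                    if c != big[gi - 1] or c == "N":
                        break
                    qi -= 1
                    gi -= 1
                qe, ge = i + k, g + k
                while qe < nq and ge < nbig:
                    c = q[qe]
                    if c != big[ge] or c == "N":
                        break
                    qe += 1
                    ge += 1
                covered[d] = qe
                off = self.offsets[ti]
                ts, te = gi - off, ge - off
                if strand == "+":
                    qs, qend = qi, qe
                else:
                    qs, qend = orig_len - qe, orig_len - qi
                out.append(
                    MatchBlock(q_id, self.t_ids[ti], qs, qend, ts, te, strand)
                )

    def find_mems(
        self, query: str, q_id: str = "query", exclude_self: bool = False
    ) -> list[MatchBlock]:
        """All MEMs of ``query`` against every indexed target, both
        strands, of length >= the index seed length."""
        if not query:
            raise ValueError("query sequence is empty")
        out: list[MatchBlock] = []
        self._scan(query, "+", q_id, out, exclude_self, len(query))
        self._scan(reverse_complement(query), "-", q_id, out, exclude_self, len(query))
        out = _suppress_dominated(out)
        out.sort(key=lambda b: (b.t_id, b.t_start, b.q_start, b.strand))
        return out


def _suppress_dominated(blocks: list[MatchBlock]) -> list[MatchBlock]:
    """Drop blocks shadowed by a longer block in *both* coordinate
    systems (same target and strand).

    Seed-extension reports every diagonal run that cannot be extended,
    which near sequence boundaries or inside tandem repeats includes
    shifted sub-matches of a longer match; a maximal common substring
    enumeration reports only the unshadowed ones. Shadowed blocks never
    change interval unions, only the block list itself.
    """
    groups: dict[tuple[str, str], list[MatchBlock]] = {}
    for b in blocks:
        groups.setdefault((b.t_id, b.strand), []).append(b)
    out: list[MatchBlock] = []
    for bs in groups.values():
        if len(bs) == 1:
            out.extend(bs)
            continue
        bs.sort(key=lambda b: (b.q_start, -b.q_end))
        # a block can only be shadowed if an earlier block's q-interval
        # contains its own; most groups have none such (cheap prefix test)
        pref = -1
        candidates = []
        for b in bs:
            if pref >= b.q_end:
                candidates.append(b)
            pref = max(pref, b.q_end)
        if not candidates:
            out.extend(bs)
            continue
        cand_ids = {id(b) for b in candidates}
        for b in bs:
            if id(b) not in cand_ids:
                out.append(b)
                continue
            shadowed = any(
                a.length > b.length
                and a.q_start <= b.q_start
                and a.q_end >= b.q_end
                and a.t_start <= b.t_start
                and a.t_end >= b.t_end
                for a in bs
            )
            if not shadowed:
                out.append(b)
    return out


def find_mems(
    query: str,
    target: str,
    min_match: int,
    q_id: str = "query",
    t_id: str = "target",
    exclude_identity: bool = False,
) -> list[MatchBlock]:
    """Every maximal exact match of length >= ``min_match`` between
    query and target, on both strands.

    ``exclude_identity=True`` drops the trivial identity diagonal of a
    self-comparison while keeping all other self-matches — the
    convention used for repeat detection."""
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    idx = KmerIndex([(t_id, target)], min_match)
    return idx.find_mems(query, q_id=q_id, exclude_self=exclude_identity)


def _frame(b: MatchBlock) -> tuple[int, int, int, int]:
    """Chaining frame: x follows the target; y follows the query,
    negated for '-' strand so colinear blocks increase in both axes."""
    if b.strand == "+":
        return b.t_start, b.t_end, b.q_start, b.q_end
    return b.t_start, b.t_end, -b.q_end, -b.q_start


def _trimmed(b: MatchBlock, trim: int) -> MatchBlock:
    if trim == 0:
        return b
    if b.strand == "+":
        return MatchBlock(
            b.q_id, b.t_id, b.q_start + trim, b.q_end, b.t_start + trim, b.t_end, "+"
        )
    return MatchBlock(
        b.q_id, b.t_id, b.q_start, b.q_end - trim, b.t_start + trim, b.t_end, "-"
    )


def _best_dp_chain(blocks: list[MatchBlock], maxgap: int):
    """Max-matched-bp colinear chain over one (query, target, strand)
    group by sparse dynamic programming; overlapping blocks are trimmed
    at the start of the later block."""
    bs = sorted(blocks, key=lambda b: (_frame(b)[0], _frame(b)[2], _frame(b)[1]))
    frames = [_frame(b) for b in bs]
    n = len(bs)
    score = [f[1] - f[0] for f in frames]
    prev = [-1] * n
    trims = [0] * n
    for i in range(n):
        x0i, x1i, y0i, y1i = frames[i]
        leni = x1i - x0i
        for j in range(i):
            x0j, x1j, y0j, y1j = frames[j]
            if x0j >= x0i or y0j >= y0i:
                continue
            ov = max(x1j - x0i, y1j - y0i, 0)
            eff = leni - ov
            if eff <= 0:
                continue
            gap_x = x0i + ov - x1j
            gap_y = y0i + ov - y1j
            if gap_x > maxgap or gap_y > maxgap:
                continue
            cand = score[j] + eff
            if cand > score[i]:
                score[i] = cand
                prev[i] = j
                trims[i] = ov
    best = max(range(n), key=lambda i: (score[i], -frames[i][0], -frames[i][2]))
    chain_idx = []
    i = best
    while i != -1:
        chain_idx.append(i)
        i = prev[i]
    chain_idx.reverse()
    chain_blocks = [_trimmed(bs[i], trims[i] if i != chain_idx[0] else 0) for i in chain_idx]
    # first block of the chain keeps its full extent
    chain_blocks[0] = bs[chain_idx[0]]
    return chain_blocks, [bs[i] for i in chain_idx]


def _finish_chain(blocks: list[MatchBlock]) -> AlignmentChain:
    matched = sum(b.length for b in blocks)
    max_indel = 0
    for a, b in zip(blocks, blocks[1:]):
        xa, ya = _frame(a)[1], _frame(a)[3]
        xb, yb = _frame(b)[0], _frame(b)[2]
        max_indel = max(max_indel, abs((xb - xa) - (yb - ya)))
    q_span = (min(b.q_start for b in blocks), max(b.q_end for b in blocks))
    t_span = (min(b.t_start for b in blocks), max(b.t_end for b in blocks))
    b0 = blocks[0]
    return AlignmentChain(
        b0.q_id, b0.t_id, b0.strand, blocks, matched, max_indel, q_span, t_span
    )


def chain_mems(
    blocks: Sequence[MatchBlock], params: AlignParams
) -> list[AlignmentChain]:
    """Partition same-strand blocks into maximal-score colinear chains.

    Chains are extracted greedily (best chain first, its blocks
    removed, repeat); adjacent gaps above ``maxgap`` on either sequence
    break chains, and chains with fewer than ``mincluster`` matched bp
    are dropped.
    """
    groups: dict[tuple[str, str, str], list[MatchBlock]] = {}
    for b in blocks:
        groups.setdefault((b.q_id, b.t_id, b.strand), []).append(b)
    chains: list[AlignmentChain] = []
    for key in sorted(groups):
        remaining = groups[key]
        while remaining:
            chain_blocks, used = _best_dp_chain(remaining, params.maxgap)
            chains.append(_finish_chain(chain_blocks))
            used_set = {id(b) for b in used}
            remaining = [b for b in remaining if id(b) not in used_set]
    chains = [c for c in chains if c.matched >= params.mincluster]
    chains.sort(
        key=lambda c: (-c.matched, c.max_indel, c.t_id, c.strand, c.t_span, c.q_span)
    )
    return chains


def _chain_rank(c: AlignmentChain, t_len: int) -> tuple:
    """Deterministic preference order across candidate chains: most
    matched bp, then fewest indels, then longer target, then id."""
    return (-c.matched, c.max_indel, -t_len, c.t_id, c.strand, c.t_span, c.q_span)


def chains_against_index(
    query: Contig, index: KmerIndex, params: AlignParams, exclude_self: bool = False
) -> list[AlignmentChain]:
    """All surviving chains of one contig against every indexed target."""
    blocks = index.find_mems(query.seq, q_id=query.id, exclude_self=exclude_self)
    return chain_mems(blocks, params)


def best_chain(
    query: Contig, target: Contig, params: AlignParams
) -> AlignmentChain | None:
    """The chain with maximal matched bp between two contigs over both
    strands, or None if no chain survives ``mincluster``."""
    idx = KmerIndex([(target.id, target.seq)], params.min_match)
    chains = chains_against_index(query, idx, params)
    if not chains:
        return None
    return min(chains, key=lambda c: _chain_rank(c, len(target.seq)))


def coverage(chains: Sequence[AlignmentChain], t_len: int) -> CoverageProfile:
    """Union of chain block target-intervals on one target."""
    if t_len <= 0:
        raise ValueError("target length must be positive")
    t_ids = {c.t_id for c in chains}
    if len(t_ids) > 1:
        raise ValueError(f"chains target multiple sequences: {sorted(t_ids)}")
    t_id = next(iter(t_ids)) if t_ids else ""
    ivs = merge_intervals(
        (max(0, b.t_start), min(t_len, b.t_end)) for c in chains for b in c.blocks
    )
    frac = sum(b - a for a, b in ivs) / t_len
    return CoverageProfile(t_id, t_len, ivs, frac)


def is_contained(
    a: Contig,
    b: Contig,
    params: AlignParams | None = None,
    min_identity: float = 1.0,
) -> bool:
    """True iff ``a`` occurs as a substring of ``b`` or of its reverse
    complement.

    The default test is exact, which keeps consensus voting
    byte-deterministic. ``min_identity < 1`` switches to a
    mismatch-tolerant mode requiring a single chain matching at least
    that fraction of ``a``.
    """
    if min_identity >= 1.0:
        return a.seq in b.seq or a.seq in reverse_complement(b.seq)
    params = params or AlignParams()
    chain = best_chain(a, b, params)
    return chain is not None and chain.matched >= min_identity * len(a.seq)


def write_alignment_report(
    chains: Sequence[AlignmentChain],
    t_lens: dict[str, int],
    path: str | Path,
) -> Path:
    """TSV alignment report, 1-based inclusive coordinates."""
    by_target: dict[str, list[AlignmentChain]] = {}
    for c in chains:
        by_target.setdefault(c.t_id, []).append(c)
    fractions = {
        t_id: coverage(cs, t_lens[t_id]).fraction for t_id, cs in by_target.items()
    }
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "t_id\tq_id\tt_start\tt_end\tq_start\tq_end\tstrand\t"
            "matched\tmax_indel\tt_cov_fraction\n"
        )
        for c in chains:
            fh.write(
                f"{c.t_id}\t{c.q_id}\t{c.t_span[0] + 1}\t{c.t_span[1]}\t"
                f"{c.q_span[0] + 1}\t{c.q_span[1]}\t{c.strand}\t"
                f"{c.matched}\t{c.max_indel}\t{fractions[c.t_id]:.4f}\n"
            )
    return path
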