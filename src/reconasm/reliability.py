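"""Reliability filtering of comparative (A-) contigs using DBG contigs.

Comparative assembly against a diverged reference imports the
reference's structure wherever it disagrees with the target genome,
producing mis-assembled contigs. The filter aligns the high-confidence
DBG contigs onto the pooled A-contig sets and keeps an A-contig only
if

1. no assigned alignment chain shows a significant insertion or
   deletion (``max_indel`` above the threshold), and
2. the fraction of the A-contig covered by its assigned DBG-contig
   chains reaches the coverage threshold ``tau`` (0.8 by default).

Assignment is best-hit: each DBG contig supports only the single
A-contig it aligns to best, competed across *all* references pooled
together. A mis-assembled contig loses that competition to the genuine
version of the same region from another reference, so its coverage
falls below ``tau`` even when its constituent pieces are individually
genuine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .seqio import Assembly, Contig
from .mem_align import (
    AlignParams,
    AlignmentChain,
    KmerIndex,
    _chain_rank,
    chains_against_index,
    coverage,
)


@dataclass(frozen=True)
class ReliabilityParams:
    tau: float = 0.8
    max_indel: int = 50
    min_len: int = 500
    align: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if not 0 < self.tau <= 1:
            raise ValueError("tau must be in (0, 1]")
        if self.max_indel < 0:
            raise ValueError("max_indel must be >= 0")


@dataclass
class ReliabilityVerdict:
    a_id: str
    length: int
    source: str
    coverage: float
    n_assigned_dbg: int
    worst_indel: int
    reliable: bool
    reason: str  # ok | too_short | indel | low_coverage


def assign_dbg_to_acontigs(
    dbg: Assembly,
    acontigs: Assembly,
    align: AlignParams = AlignParams(),
) -> dict[str, tuple[str, AlignmentChain]]:
    """Best-hit assignment: each DBG contig maps to exactly one
    A-contig (ties broken deterministically); DBG contigs with no
    surviving chain are omitted."""
    if len(dbg) == 0 or len(acontigs) == 0:
        raise ValueError("both assemblies must be non-empty")
    index = KmerIndex([(c.id, c.seq) for c in acontigs], align.min_match)
    t_len = {c.id: len(c.seq) for c in acontigs}
    out: dict[str, tuple[str, AlignmentChain]] = {}
    for d in dbg:
        chains = chains_against_index(d, index, align)
        if not chains:
            continue
        best = min(chains, key=lambda c: _chain_rank(c, t_len[c.t_id]))
        out[d.id] = (best.t_id, best)
    return out


def evaluate_acontig(
    a: Contig,
    assigned_chains: Sequence[AlignmentChain],
    params: ReliabilityParams = ReliabilityParams(),
) -> ReliabilityVerdict:
    """Apply the two reliability criteria to one A-contig given the
    chains of the DBG contigs assigned to it. The reason records the
    first failing criterion (too_short, indel, low_coverage)."""
    for c in assigned_chains:
        if c.t_id != a.id:
            raise ValueError(f"chain targets {c.t_id!r}, not {a.id!r}")
    cov = coverage(assigned_chains, len(a.seq)).fraction if assigned_chains else 0.0
    worst = max((c.max_indel for c in assigned_chains), default=0)
    if len(a.seq) < params.min_len:
        reason = "too_short"
    elif worst > params.max_indel:
        reason = "indel"
    elif cov < params.tau:
        reason = "low_coverage"
    else:
        reason = "ok"
    return ReliabilityVerdict(
        a_id=a.id,
        length=len(a.seq),
        source=a.source,
        coverage=cov,
        n_assigned_dbg=len(assigned_chains),
        worst_indel=worst,
        reliable=(reason == "ok"),
        reason=reason,
    )


def select_reliable_acontigs(
    acontig_sets: Sequence[Assembly],
    dbg: Assembly,
    params: ReliabilityParams = ReliabilityParams(),
    pooled: bool = True,
) -> tuple[Assembly, list[ReliabilityVerdict]]:
    """Pool the per-reference A-contig sets, run best-hit assignment of
    DBG contigs against the pool, and keep the A-contigs passing both
    criteria.

    ``pooled=False`` switches to per-reference assignment (each set
    filtered in isolation), provided for comparison only — the
    multi-reference competition requires pooling.
    """
    if not acontig_sets:
        raise ValueError("need at least one A-contig set")
    pool_contigs: list[Contig] = []
    seen: set[str] = set()
    for aset in acontig_sets:
        for c in aset:
            cid = c.id if c.id not in seen else f"{aset.label}:{c.id}"
            if cid in seen:
                raise ValueError(f"duplicate A-contig id {cid!r} across sets")
            seen.add(cid)
            pool_contigs.append(Contig(cid, c.seq, c.source, c.truth, dict(c.meta)))

    if not pooled:
        verdicts: list[ReliabilityVerdict] = []
        kept: list[Contig] = []
        for aset in acontig_sets:
            sub, v = select_reliable_acontigs([aset], dbg, params, pooled=True)
            kept.extend(sub.contigs)
            verdicts.extend(v)
        return Assembly("reliable_A", kept), verdicts

    long_enough = [c for c in pool_contigs if len(c.seq) >= params.min_len]
    by_target: dict[str, list[AlignmentChain]] = {}
    if len(dbg) > 0 and long_enough:
        assignment = assign_dbg_to_acontigs(
            dbg, Assembly("pool", long_enough), params.align
        )
        for a_id, chain in assignment.values():
            by_target.setdefault(a_id, []).append(chain)

    verdicts = [
        evaluate_acontig(c, by_target.get(c.id, []), params) for c in pool_contigs
    ]
    reliable_ids = {v.a_id for v in verdicts if v.reliable}
    kept = [c for c in pool_contigs if c.id in reliable_ids]
    kept.sort(key=lambda c: (-len(c.seq), c.id))
    return Assembly("reliable_A", kept), verdicts


def write_verdicts(verdicts: Sequence[ReliabilityVerdict], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "a_id\tlength\tsource\tcoverage\tn_assigned_dbg\tworst_indel\t"
            "reliable\treason\n"
        )
        for v in verdicts:
            fh.write(
                f"{v.a_id}\t{v.length}\t{v.source}\t{v.coverage:.4f}\t"
                f"{v.n_assigned_dbg}\t{v.worst_indel}\t{int(v.reliable)}\t{v.reason}\n"
            )
    return path
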