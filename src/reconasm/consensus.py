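"""Consensus selection of contigs from multiple de novo assemblies.

De Bruijn graph assemblers resolve repeat-induced graph ambiguities in
different ways, so their mis-assembled contigs are largely disjoint
while genuine sequence is shared. A contig is therefore selected only
if it is identical to, or a subsequence of, contigs from at least
``min_support`` of the input assemblies (its own assembly counts — the
contig trivially contains itself, so the default of 2 demands one
independent corroboration). The selected set, with containment
redundancy removed, is the high-confidence "DBG contig" set of the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .seqio import Assembly, Contig, reverse_complement
from .mem_align import is_contained


@dataclass(frozen=True)
class ConsensusParams:
    min_support: int = 2
    min_len: int = 500

    def __post_init__(self) -> None:
        if self.min_support < 2:
            raise ValueError("min_support must be >= 2")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


def _containment_blob(assembly: Assembly) -> str:
    """Concatenate an assembly's contigs and their reverse complements
    with sentinels, so substring search against the blob answers
    'contained in some contig of this assembly (either strand)'."""
    parts = []
    for c in assembly:
        parts.append(c.seq)
        parts.append(reverse_complement(c.seq))
    return "#" + "#".join(parts) + "#"


def support_count(c: Contig, assemblies: Sequence[Assembly]) -> int:
    """Number of distinct assemblies containing a contig in which ``c``
    is contained (either strand); the contig's own assembly counts."""
    return sum(1 for a in assemblies if c.seq in _containment_blob(a))


def remove_redundant(contigs: Sequence[Contig]) -> list[Contig]:
    """Drop every contig contained (either strand) in another kept
    contig; among identical contigs the lexicographically smallest id
    is kept. Processing order: descending length, then id."""
    ordered = sorted(contigs, key=lambda c: (-len(c.seq), c.id))
    kept: list[Contig] = []
    for c in ordered:
        if any(is_contained(c, k) for k in kept):
            continue
        kept.append(c)
    return kept


def select_dbg_contigs(
    assemblies: Sequence[Assembly],
    params: ConsensusParams = ConsensusParams(),
) -> Assembly:
    """Containment voting over >= 2 de novo assemblies.

    Candidates are contigs of length >= ``min_len`` with support from
    at least ``min_support`` assemblies; redundancy is then removed and
    the result labeled ``DBG``.
    """
    if len(assemblies) < 2:
        raise ValueError("consensus selection needs at least 2 assemblies")
    blobs = [_containment_blob(a) for a in assemblies]
    candidates = []
    for a in assemblies:
        for c in a:
            if len(c.seq) < params.min_len:
                continue
            support = sum(1 for blob in blobs if c.seq in blob)
            if support >= params.min_support:
                candidates.append(c)
    kept = remove_redundant(candidates)
    # ids may collide across input assemblies; qualify with the source
    ids = [c.id for c in kept]
    if len(set(ids)) != len(ids):
        kept = [
            Contig(f"{c.source}:{c.id}", c.seq, c.source, c.truth, dict(c.meta))
            for c in kept
        ]
    return Assembly("DBG", sorted(kept, key=lambda c: (-len(c.seq), c.id)))


def support_report(
    assemblies: Sequence[Assembly],
    params: ConsensusParams,
    selected: Assembly,
    path: str | Path,
) -> Path:
    """TSV report: contig id, length, source, support count, kept flag."""
    blobs = [_containment_blob(a) for a in assemblies]
    kept_ids = set(selected.ids())
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("contig_id\tlength\tsource\tsupport\tkept\n")
        for a in assemblies:
            for c in a:
                support = sum(1 for blob in blobs if c.seq in blob)
                fh.write(
                    f"{c.id}\t{len(c.seq)}\t{c.source}\t{support}\t"
                    f"{int(c.id in kept_ids)}\n"
                )
    return path
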