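"""Greedy overlap merging of DBG contigs and reliable A-contigs.

The final pipeline stage plays the role of a stringent light-weight
assembler: it absorbs contained contigs, then joins contigs by
dovetail (suffix-prefix) overlaps, longest overlap first, each contig
end being used at most once. Only sequence-confirmed joins are made —
no scaffolding with Ns. Where the two copies of an overlap disagree,
the DBG contig's bases win (the DBG set is the high-accuracy one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .seqio import Assembly, Contig, reverse_complement
from .mem_align import AlignParams, KmerIndex, chains_against_index, is_contained


@dataclass(frozen=True)
class MergeParams:
    min_overlap: int = 30
    min_overlap_ident: float = 0.94
    max_end_trim: int = 20

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 < self.min_overlap_ident <= 1:
            raise ValueError("min_overlap_ident must be in (0, 1]")
        if self.max_end_trim < 0:
            raise ValueError("max_end_trim must be >= 0")


@dataclass(frozen=True)
class Overlap:
    """A pairwise overlap.

    ``containment`` means ``a_id`` is contained in ``b_id``;
    ``dovetail`` means an end of ``a_id`` overlaps an end of ``b_id``
    (which ends is carried in ``ends``). ``strand`` is '+' when both
    contigs keep their forward orientation across the junction.
    """

    a_id: str
    b_id: str
    type: str  # 'dovetail' | 'containment'
    strand: str
    length: int
    identity: float
    # internal layout data: the physical ends joined and the matched
    # interval on each contig in its own forward coordinates
    ends: tuple[tuple[str, str], tuple[str, str]] = (("", ""), ("", ""))
    a_match: tuple[int, int] = (0, 0)
    b_match: tuple[int, int] = (0, 0)


def _align_params_for(params: MergeParams) -> AlignParams:
    k = min(20, params.min_overlap)
    return AlignParams(min_match=k, maxgap=500, mincluster=max(k, params.min_overlap))


def find_overlaps(contigs: Sequence[Contig], params: MergeParams) -> list[Overlap]:
    """All pairwise dovetail and containment overlaps meeting the
    thresholds, both strands, detected via alignment chains anchored at
    sequence ends. Symmetric: every junction is reported from both
    contigs' perspectives."""
    if not contigs:
        raise ValueError("need at least one contig")
    align = _align_params_for(params)
    index = KmerIndex([(c.id, c.seq) for c in contigs], align.min_match)
    lens = {c.id: len(c.seq) for c in contigs}
    trim = params.max_end_trim
    best: dict[tuple, Overlap] = {}

    def consider(key: tuple, ov: Overlap) -> None:
        old = best.get(key)
        if old is None or (ov.length, ov.identity) > (old.length, old.identity):
            best[key] = ov

    for q in contigs:
        chains = chains_against_index(q, index, align)
        la = lens[q.id]
        for c in chains:
            if c.t_id == q.id:
                continue
            lb = lens[c.t_id]
            qs, qe = c.q_span
            ts, te = c.t_span
            span = max(qe - qs, te - ts)
            identity = c.matched / span if span else 0.0
            if span < params.min_overlap or identity < params.min_overlap_ident:
                continue
            s = c.strand
            q_left, q_right = qs <= trim, la - qe <= trim
            t_left, t_right = ts <= trim, lb - te <= trim
            if q_left and q_right:
                consider(
                    ("cont", q.id, c.t_id),
                    Overlap(q.id, c.t_id, "containment", s, span, identity),
                )
                continue
            if t_left and t_right:
                consider(
                    ("cont", c.t_id, q.id),
                    Overlap(c.t_id, q.id, "containment", s, span, identity),
                )
                continue
            junctions = []
            if s == "+":
                if q_right and t_left:
                    junctions.append(((q.id, "R"), (c.t_id, "L")))
                if q_left and t_right:
                    junctions.append(((c.t_id, "R"), (q.id, "L")))
            else:
                if q_right and t_right:
                    junctions.append(((q.id, "R"), (c.t_id, "R")))
                if q_left and t_left:
                    junctions.append(((c.t_id, "L"), (q.id, "L")))
            for ea, eb in junctions:
                a_first = ea[0] == q.id
                ov = Overlap(
                    ea[0],
                    eb[0],
                    "dovetail",
                    s,
                    span,
                    identity,
                    ends=(ea, eb),
                    a_match=(qs, qe) if a_first else (ts, te),
                    b_match=(ts, te) if a_first else (qs, qe),
                )
                consider(("dove", frozenset([ea, eb])), ov)
    out = list(best.values())
    out.sort(key=lambda o: (-o.length, -o.identity, o.a_id, o.b_id, o.type))
    return out


class _DSU:
    def __init__(self, ids):
        self.p = {i: i for i in ids}

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b):
        self.p[self.find(a)] = self.find(b)


def _oriented_interval(iv: tuple[int, int], length: int, orient: str) -> tuple[int, int]:
    if orient == "+":
        return iv
    return length - iv[1], length - iv[0]


def merge_assembly(
    dbg: Assembly,
    reliable_a: Assembly,
    params: MergeParams = MergeParams(),
) -> tuple[Assembly, list[dict]]:
    """Merge DBG contigs with reliable A-contigs into the hybrid
    assembly.

    Greedy layout: containments are absorbed first, then dovetails are
    merged longest-overlap-first with each contig end used at most
    once; finally any output contained in another output is absorbed.
    Returns the hybrid assembly and the join records (for the joins
    TSV; joins unsupported by any DBG contig are tagged).
    """
    pool: list[Contig] = list(dbg) + list(reliable_a)
    if not pool:
        raise ValueError("nothing to merge")
    ids = [c.id for c in pool]
    if len(set(ids)) != len(ids):
        raise ValueError("contig ids must be unique across the two inputs")
    dbg_ids = {c.id for c in dbg}
    contigs = {c.id: c for c in pool}
    overlaps = find_overlaps(pool, params)

    # 1. containment absorption
    alive = set(contigs)
    for ov in overlaps:
        if ov.type != "containment":
            continue
        a, b = ov.a_id, ov.b_id
        if a not in alive or a == b:
            continue
        la, lb = len(contigs[a].seq), len(contigs[b].seq)
        if la == lb and a < b:
            continue  # among identical contigs keep the smaller id
        alive.discard(a)

    # 2. greedy dovetail joins
    dsu = _DSU(alive)
    end_map: dict[tuple[str, str], Overlap] = {}
    joins: list[dict] = []
    for ov in overlaps:
        if ov.type != "dovetail":
            continue
        (aid, aend), (bid, bend) = ov.ends
        if aid not in alive or bid not in alive:
            continue
        if (aid, aend) in end_map or (bid, bend) in end_map:
            continue
        if dsu.find(aid) == dsu.find(bid):
            continue  # would close a cycle
        dsu.union(aid, bid)
        end_map[(aid, aend)] = ov
        end_map[(bid, bend)] = ov
        joins.append(
            {
                "left_id": aid,
                "right_id": bid,
                "strand": ov.strand,
                "overlap_len": ov.length,
                "identity": ov.identity,
                "dbg_supported": int(aid in dbg_ids or bid in dbg_ids),
            }
        )

    # 3. walk paths and build merged sequences
    def junction_side(ov: Overlap, cid: str) -> tuple[tuple[int, int], tuple[str, str]]:
        (aid, aend), (bid, bend) = ov.ends
        if cid == aid:
            return ov.a_match, (bid, bend)
        return ov.b_match, (aid, aend)

    visited: set[str] = set()
    outputs: list[tuple[str, list[str]]] = []  # (sequence, member ids)
    for start_id in sorted(alive):
        if start_id in visited:
            continue
        # walk to a terminal end of this path
        comp = [start_id]
        seen = {start_id}
        # find terminal endpoints by walking both directions
        def neighbors(cid):
            for e in ("L", "R"):
                ov = end_map.get((cid, e))
                if ov is not None:
                    _, (oid, _) = junction_side(ov, cid)
                    yield oid
        # BFS to collect component
        frontier = [start_id]
        while frontier:
            nxt = []
            for cid in frontier:
                for oid in neighbors(cid):
                    if oid not in seen:
                        seen.add(oid)
                        comp.append(oid)
                        nxt.append(oid)
            frontier = nxt
        visited |= seen
        terminals = [
            (cid, e)
            for cid in comp
            for e in ("L", "R")
            if (cid, e) not in end_map
        ]
        # a linear path has exactly two free ends; prefer starting at a
        # left end (forward orientation), then the smaller contig id
        terminals.sort(key=lambda t: (t[1] != "L", t[0]))
        scid, send = terminals[0]
        orient = "+" if send == "L" else "-"
        pieces: list[str] = []
        members: list[str] = []
        cur, start_off = scid, 0
        while True:
            members.append(cur)
            c = contigs[cur]
            lcur = len(c.seq)
            oseq = c.seq if orient == "+" else reverse_complement(c.seq)
            leading = "R" if orient == "+" else "L"
            ov = end_map.get((cur, leading))
            if ov is None:
                pieces.append(oseq[start_off:])
                break
            m_fwd, (nid, nend) = junction_side(ov, cur)
            m0, m1 = _oriented_interval(m_fwd, lcur, orient)
            nxt_c = contigs[nid]
            n_orient = "+" if nend == "L" else "-"
            n_fwd, _ = junction_side(ov, nid)
            n0, n1 = _oriented_interval(n_fwd, len(nxt_c.seq), n_orient)
            keep_cur = cur in dbg_ids or nid not in dbg_ids
            cut = m1 if keep_cur else m0
            base = n1 if keep_cur else n0
            deficit = max(0, start_off - cut)
            pieces.append(oseq[start_off : max(cut, start_off)])
            cur, orient, start_off = nid, n_orient, base + deficit
        outputs.append(("".join(pieces), members))

    # 4. final containment pass over outputs (keeps merging idempotent)
    outputs.sort(key=lambda o: (-len(o[0]), o[1]))
    final: list[tuple[str, list[str]]] = []
    for seq, members in outputs:
        probe = Contig("probe", seq)
        if any(is_contained(probe, Contig("kept", k)) for k, _ in final):
            continue
        final.append((seq, members))

    out_contigs: list[Contig] = []
    n_merged = 0
    for seq, members in final:
        if len(members) == 1:
            # untouched contig: keep its identity and truth label
            c = contigs[members[0]]
            out_contigs.append(Contig(c.id, seq, c.source, c.truth, dict(c.meta)))
        else:
            n_merged += 1
            out_contigs.append(
                Contig(
                    f"hybrid_{n_merged}", seq, source="hybrid", meta={"members": members}
                )
            )
    hybrid = Assembly("hybrid", out_contigs)
    return hybrid, joins


def write_joins(joins: Sequence[dict], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("left_id\tright_id\tstrand\toverlap_len\tidentity\tdbg_supported\n")
        for j in joins:
            fh.write(
                f"{j['left_id']}\t{j['right_id']}\t{j['strand']}\t"
                f"{j['overlap_len']}\t{j['identity']:.4f}\t{j['dbg_supported']}\n"
            )
    return path
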