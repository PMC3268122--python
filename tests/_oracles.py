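"""Independent brute-force oracles used to validate the alignment and
metric implementations.

These deliberately use a different algorithm from the package:
exhaustive per-diagonal scanning with numpy run extraction, instead of
seeded hash extension. They are quadratic and only suitable for
sequences up to a few kbp.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _diagonal_runs(q: str, t: str, k: int):
    """All maximal equal runs of length >= k on every diagonal,
    N matching nothing. Yields (q_start, q_end, t_start, t_end)."""
    qa, ta = _encode(q), _encode(t)
    nq, nt = len(q), len(t)
    N = ord("N")
    for d in range(-(nt - 1), nq):
        qs = max(0, d)
        ts = qs - d
        L = min(nq - qs, nt - ts)
        if L < k:
            continue
        seg_q = qa[qs : qs + L]
        seg_t = ta[ts : ts + L]
        eq = (seg_q == seg_t) & (seg_q != N)
        padded = np.concatenate(([0], eq.astype(np.int8), [0]))
        edges = np.flatnonzero(np.diff(padded))
        for a, b in zip(edges[::2], edges[1::2]):
            if b - a >= k:
                yield (qs + a, qs + b, ts + a, ts + b)


def _suppress(blocks):
    """Drop blocks contained in a strictly longer same-strand block in
    both coordinate systems."""
    out = []
    for s, qs, qe, ts, te in blocks:
        shadowed = any(
            s2 == s
            and (qe2 - qs2) > (qe - qs)
            and qs2 <= qs
            and qe2 >= qe
            and ts2 <= ts
            and te2 >= te
            for s2, qs2, qe2, ts2, te2 in blocks
        )
        if not shadowed:
            out.append((s, qs, qe, ts, te))
    return out


def mems_oracle(q: str, t: str, k: int, exclude_identity: bool = False):
    """Set of (strand, q_start, q_end, t_start, t_end) maximal exact
    matches between q and t."""
    blocks = []
    for qs, qe, ts, te in _diagonal_runs(q, t, k):
        if exclude_identity and q == t and qs == ts:
            continue
        blocks.append(("+", qs, qe, ts, te))
    nq = len(q)
    for qs, qe, ts, te in _diagonal_runs(rc(q), t, k):
        blocks.append(("-", nq - qe, nq - qs, ts, te))
    return set(_suppress(blocks))


def complexity_oracle(genome: str, k: int) -> float:
    covered = np.zeros(len(genome), dtype=bool)
    for _s, qs, qe, ts, te in mems_oracle(genome, genome, k, exclude_identity=True):
        covered[qs:qe] = True
        covered[ts:te] = True
    return covered.sum() / len(genome)


def similarity_oracle(a: str, b: str, k: int) -> float:
    cov_a = np.zeros(len(a), dtype=bool)
    cov_b = np.zeros(len(b), dtype=bool)
    for _s, qs, qe, ts, te in mems_oracle(a, b, k):
        cov_a[qs:qe] = True
        cov_b[ts:te] = True
    return (cov_a.sum() + cov_b.sum()) / (len(a) + len(b))


def n50_oracle(lengths, genome_len: int) -> int:
    """Exhaustive prefix enumeration over the descending-sorted list."""
    ordered = sorted(lengths, reverse=True)
    for i in range(1, len(ordered) + 1):
        if 2 * sum(ordered[:i]) >= genome_len:
            return ordered[i - 1]
    return 0


def contained_oracle(a: str, b: str) -> bool:
    """Explicit position-by-position substring check on both strands."""
    la = len(a)
    for hay in (b, rc(b)):
        for i in range(len(hay) - la + 1):
            if hay[i : i + la] == a:
                return True
    return False
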