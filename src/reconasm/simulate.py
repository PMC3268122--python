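"""Synthetic data generation: genomes with controlled repeat content,
diverged reference genomes, paired-end short reads, and labeled
fixture contig sets with planted misassemblies.

The generators emulate the study conditions the pipeline is designed
for: bacterial-scale target genomes with non-trivial repeat content,
reference genomes diverged into the 0.80-0.92 exact-match similarity
band, forward-reverse paired-end libraries (coverage C=60, fragment
length L=300, read length R=75 by default), de novo assemblies whose
chimeric contigs are independent between assemblers, and comparative
contig sets that import reference structure at divergent regions.

All generators are bit-reproducible given their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import Assembly, Contig, reverse_complement
from .metrics import similarity

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, stream)])


def random_dna(rng: np.random.Generator, n: int) -> str:
    codes = rng.integers(0, 4, n, dtype=np.uint8)
    return _BASES[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class SimParams:
    """Read-simulation settings: fold coverage C, fragment length L,
    read length R, per-base substitution error rate, and seed."""

    C: float = 60.0
    L: int = 300
    R: int = 75
    sub_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.R > self.L:
            raise ValueError("read length R must not exceed fragment length L")
        if self.C <= 0:
            raise ValueError("coverage C must be positive")
        if not 0 <= self.sub_error < 1:
            raise ValueError("sub_error must be in [0, 1)")


@dataclass
class ReadPair:
    """Forward-reverse pair: fwd is the fragment's first R bases, rev
    the reverse complement of its last R bases."""

    id: str
    fwd: str
    rev: str
    frag_start: int


@dataclass
class GenomeFixture:
    """A complete synthetic test universe for one target genome."""

    genome: str
    repeat_annotation: list[tuple[str, int, int]]
    references: list[tuple[str, str, list[dict]]]
    assemblies: list[Assembly]
    acontig_sets: list[Assembly]
    dbg: Assembly


# ---------------------------------------------------------------------------
# genomes


def generate_genome(
    length: int,
    repeats: Sequence[tuple[int, int]] = (),
    seed: int = 0,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Uniform random genome with exact planted repeat families.

    ``repeats`` lists (unit_len, copies) families; copies are placed at
    non-overlapping random positions, so the repeat-complexity of the
    result is close to sum(unit_len * copies) / length.
    """
    if sum(u * c for u, c in repeats) > length:
        raise ValueError("requested repeat content exceeds genome length")
    rng = _rng(seed, 1)
    genome = bytearray(random_dna(rng, length), "ascii")
    occupied: list[tuple[int, int]] = []
    annotation: list[tuple[str, int, int]] = []
    for fam, (unit_len, copies) in enumerate(repeats):
        if unit_len < 1 or copies < 1:
            raise ValueError("repeat unit_len and copies must be positive")
        unit = random_dna(rng, unit_len).encode("ascii")
        placed = 0
        for _ in range(200 * copies):
            if placed == copies:
                break
            p = int(rng.integers(0, length - unit_len + 1))
            if any(p < e and p + unit_len > s for s, e in occupied):
                continue
            genome[p : p + unit_len] = unit
            occupied.append((p, p + unit_len))
            annotation.append((f"rep{fam}", p, p + unit_len))
            placed += 1
        if placed < copies:
            raise ValueError("could not place repeats without overlap")
    annotation.sort(key=lambda r: r[1])
    return genome.decode("ascii"), annotation


# ---------------------------------------------------------------------------
# diverged references

_EVENT_KINDS = ("insertion", "deletion", "inversion", "translocation")


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    idx = np.nonzero(mask)[0]
    if idx.size:
        # map A/C/G/T to 0..3, shift by 1..3, map back (N left alone)
        lut = np.full(256, 255, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        codes = lut[arr[idx]]
        ok = codes != 255
        shift = rng.integers(1, 4, idx.size).astype(np.uint8)
        new = (codes + shift) % 4
        arr[idx[ok]] = _BASES[new[ok]]
    return arr.tobytes().decode("ascii")


def mutate_reference(
    genome: str,
    sub_rate: float,
    indel_rate: float = 0.0,
    indel_len: tuple[int, int] = (1, 5),
    n_rearrangements: int = 0,
    seed: int = 0,
    event_len: tuple[int, int] = (800, 1500),
) -> tuple[str, list[dict]]:
    """Derive a diverged reference from a target genome.

    Applies, in order: block structural events (insertion of novel
    sequence, deletion, inversion, or translocation of a segment to a
    distant site), small indels at ``indel_rate`` per base, and point
    substitutions at ``sub_rate``. Structural events are logged in
    target-genome coordinates (what the comparative fixture generator
    consumes); small edits are logged in reference coordinates.
    """
    for r in (sub_rate, indel_rate):
        if not 0 <= r < 1:
            raise ValueError("rates must be in [0, 1)")
    rng = _rng(seed, 2)
    G = len(genome)
    log: list[dict] = []
    edits: list[tuple[int, str, object]] = []  # (genome pos, kind, payload)
    if n_rearrangements:
        margin = max(2000, event_len[1] + 500)
        usable = G - 2 * margin
        zone = usable // n_rearrangements
        if zone < 2 * event_len[1] + 1000:
            raise ValueError("genome too short for requested rearrangements")
        for i in range(n_rearrangements):
            kind = _EVENT_KINDS[int(rng.integers(0, len(_EVENT_KINDS)))]
            lo = margin + i * zone
            p = int(rng.integers(lo + 500, lo + zone - event_len[1] - 500))
            ell = int(rng.integers(event_len[0], event_len[1] + 1))
            if kind == "insertion":
                ins = random_dna(rng, ell)
                edits.append((p, "insert", ins))
                log.append({"kind": "insertion", "g_pos": p, "length": ell, "seq": ins})
            elif kind == "deletion":
                edits.append((p, "delete", ell))
                log.append({"kind": "deletion", "g_start": p, "g_end": p + ell})
            elif kind == "inversion":
                edits.append((p, "invert", ell))
                log.append({"kind": "inversion", "g_start": p, "g_end": p + ell})
            else:  # translocation: remove here, re-insert mid-zone elsewhere
                j = (i + n_rearrangements // 2) % n_rearrangements
                dest = margin + j * zone + zone // 2 + event_len[1] + 750
                edits.append((p, "delete", ell))
                edits.append((dest, "insert", genome[p : p + ell]))
                log.append(
                    {
                        "kind": "translocation",
                        "g_start": p,
                        "g_end": p + ell,
                        "dest": dest,
                    }
                )
    edits.sort(key=lambda e: e[0])
    parts: list[str] = []
    cursor = 0
    for p, action, payload in edits:
        parts.append(genome[cursor:p])
        if action == "insert":
            parts.append(payload)  # type: ignore[arg-type]
            cursor = p
        elif action == "delete":
            cursor = p + int(payload)  # type: ignore[arg-type]
        else:  # invert
            ell = int(payload)  # type: ignore[arg-type]
            parts.append(reverse_complement(genome[p : p + ell]))
            cursor = p + ell
    parts.append(genome[cursor:])
    ref = "".join(parts)

    if indel_rate > 0:
        arr = []
        n_ind = int(rng.binomial(len(ref), indel_rate))
        positions = sorted(int(x) for x in rng.integers(0, len(ref), n_ind))
        cursor = 0
        for p in positions:
            arr.append(ref[cursor:p])
            ell = int(rng.integers(indel_len[0], indel_len[1] + 1))
            if rng.random() < 0.5:
                ins = random_dna(rng, ell)
                arr.append(ins)
                cursor = p
                log.append({"kind": "small_ins", "ref_pos": p, "length": ell})
            else:
                cursor = min(len(ref), p + ell)
                log.append({"kind": "small_del", "ref_pos": p, "length": ell})
        arr.append(ref[cursor:])
        ref = "".join(arr)

    if sub_rate > 0:
        before = ref
        ref = _substitute(ref, sub_rate, rng)
        n_subs = sum(1 for a, b in zip(before, ref) if a != b)
        log.append({"kind": "substitutions", "rate": sub_rate, "count": n_subs})
    return ref, log


def make_reference(
    genome: str,
    seed: int = 0,
    band: tuple[float, float] = (0.80, 0.92),
    n_rearrangements: int = 6,
    event_len: tuple[int, int] = (800, 1500),
    min_match_len: int = 20,
) -> tuple[str, list[dict], float]:
    """Build a diverged reference whose exact-match similarity to the
    target lands inside ``band``, by bisecting the substitution rate.

    The rate is first bisected on a substitution-only window (cheap),
    then verified on the full construction and nudged if the
    structural events pushed the value outside the band. Returns
    (reference, variant log, achieved similarity).
    """
    window = genome[: min(len(genome), 30000)]
    target_mid = 0.5 * (band[0] + band[1])
    lo, hi = 5e-4, 0.25
    rate = 0.02
    wrng = _rng(seed, 3)
    for _ in range(14):
        s = similarity(window, _substitute(window, rate, wrng), min_match_len)
        if abs(s - target_mid) < 0.01:
            break
        if s > target_mid:
            lo = rate
        else:
            hi = rate
        rate = math.sqrt(lo * hi)
    for _ in range(8):
        ref, log = mutate_reference(
            genome,
            rate,
            n_rearrangements=n_rearrangements,
            seed=seed,
            event_len=event_len,
        )
        s = similarity(genome, ref, min_match_len)
        if band[0] <= s <= band[1]:
            return ref, log, s
        rate = rate * 0.8 if s < band[0] else rate * 1.25
    raise RuntimeError("could not calibrate reference similarity into band")


# ---------------------------------------------------------------------------
# reads


def simulate_reads(genome: str, params: SimParams) -> list[ReadPair]:
    """Sample floor(G*C/(2R)) fragments of length L with uniform start
    positions and take an R-bp read from each end (forward-reverse
    orientation)."""
    G, L, R = len(genome), params.L, params.R
    if G < L:
        raise ValueError("genome shorter than fragment length")
    n = math.floor(G * params.C / (2 * R))
    rng = _rng(params.seed, 4)
    starts = rng.integers(0, G - L + 1, n)
    pairs = []
    for i, s in enumerate(starts):
        s = int(s)
        frag = genome[s : s + L]
        fwd, rev = frag[:R], reverse_complement(frag[L - R :])
        if params.sub_error > 0:
            fwd = _substitute(fwd, params.sub_error, rng)
            rev = _substitute(rev, params.sub_error, rng)
        pairs.append(ReadPair(f"read_{i}", fwd, rev, s))
    return pairs


def write_fastq(pairs: Sequence[ReadPair], prefix: str | Path) -> tuple[Path, Path]:
    """Write a pair of FASTQ files (constant quality; no quality model)."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_1.fastq")
    p2 = prefix.with_name(prefix.name + "_2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for rp in pairs:
            f1.write(f"@{rp.id}/1\n{rp.fwd}\n+\n{'I' * len(rp.fwd)}\n")
            f2.write(f"@{rp.id}/2\n{rp.rev}\n+\n{'I' * len(rp.rev)}\n")
    return p1, p2


# ---------------------------------------------------------------------------
# fixture contig sets


def tile_genome(
    genome: str,
    tile_len: int = 10000,
    step: int = 4000,
    label: str = "DBG",
) -> Assembly:
    """Deterministic overlapping tiling of the genome into bona fide
    contigs; every interior position is spanned with flanks on both
    sides, emulating a contiguous high-confidence contig set."""
    G = len(genome)
    if tile_len > G:
        return Assembly(label, [Contig(f"{label.lower()}_1", genome, label, "bona_fide")])
    starts = list(range(0, G - tile_len + 1, step))
    if starts[-1] + tile_len < G:
        starts.append(G - tile_len)
    contigs = [
        Contig(f"{label.lower()}_{i + 1}", genome[s : s + tile_len], label, "bona_fide")
        for i, s in enumerate(starts)
    ]
    return Assembly(label, contigs)


def make_fixture_assemblies(
    genome: str,
    n_assemblies: int = 3,
    mean_contig_len: int = 2000,
    chimera_rate: float = 0.0,
    seed: int = 0,
) -> list[Assembly]:
    """Emulate several de novo assemblies of the same genome.

    Each assembly independently tiles the genome with random-length,
    slightly overlapping substring contigs; with probability
    ``chimera_rate`` a contig is replaced by a chimeric join of two
    loci at least 10 * mean_contig_len apart. Chimeras are drawn
    independently per assembly, so no chimera is ever shared — the
    property consensus voting exploits.
    """
    if n_assemblies < 2:
        raise ValueError("need at least 2 assemblies for consensus selection")
    G = len(genome)
    if mean_contig_len >= G:
        raise ValueError("mean_contig_len must be smaller than the genome")
    lo, hi = max(200, int(0.3 * mean_contig_len)), int(1.7 * mean_contig_len)
    out = []
    for a in range(n_assemblies):
        rng = _rng(seed, 5, a)
        label = f"asm{a + 1}"
        contigs = []
        pos, k = 0, 0
        while pos < G:
            length = int(rng.integers(lo, hi + 1))
            end = min(pos + length, G)
            if G - end < lo:
                end = G
            piece = genome[pos:end]
            truth, meta = "bona_fide", {}
            if len(piece) >= 2 * lo and rng.random() < chimera_rate:
                half = len(piece) // 2
                min_d = 10 * mean_contig_len
                for _ in range(100):
                    d = int(rng.integers(0, G - (len(piece) - half)))
                    if abs(d - pos) >= min_d:
                        break
                piece = genome[pos : pos + half] + genome[d : d + len(piece) - half]
                truth, meta = "chimeric", {"join": (pos, pos + half, d)}
            k += 1
            contigs.append(Contig(f"{label}_c{k}", piece, label, truth, meta))
            if end >= G:
                break
            pos = end - int(rng.integers(10, 101))  # slight overlap
        out.append(Assembly(label, contigs))
    return out


def _chimera_for_event(
    genome: str, ev: dict, rng: np.random.Generator
) -> tuple[str, tuple[int, int]]:
    """Build the mis-assembled comparative contig a divergent event
    produces, plus its genome-coordinate footprint (the region genuine
    tiling must avoid)."""
    G = len(genome)
    f1 = int(rng.integers(700, 1101))
    f2 = int(rng.integers(700, 1101))
    kind = ev["kind"]
    if kind == "insertion":
        p = ev["g_pos"]
        seq = genome[max(0, p - f1) : p] + ev["seq"] + genome[p : min(G, p + f2)]
        return seq, (max(0, p - f1), min(G, p + f2))
    if kind == "deletion":
        g0, g1 = ev["g_start"], ev["g_end"]
        seq = genome[max(0, g0 - f1) : g0] + genome[g1 : min(G, g1 + f2)]
        return seq, (max(0, g0 - f1), min(G, g1 + f2))
    if kind == "inversion":
        g0, g1 = ev["g_start"], ev["g_end"]
        seq = (
            genome[max(0, g0 - f1) : g0]
            + reverse_complement(genome[g0:g1])
            + genome[g1 : min(G, g1 + f2)]
        )
        return seq, (max(0, g0 - f1), min(G, g1 + f2))
    if kind == "translocation":
        g0, g1, dest = ev["g_start"], ev["g_end"], ev["dest"]
        seq = (
            genome[max(0, dest - f1) : dest]
            + genome[g0:g1]
            + genome[dest : min(G, dest + f2)]
        )
        return seq, (max(0, dest - f1), min(G, dest + f2))
    raise ValueError(f"unknown event kind {kind!r}")


def make_fixture_acontigs(
    genome: str,
    references: Sequence[tuple[str, str, list[dict]]],
    miss_rate: float = 1.0,
    seed: int = 0,
    piece_len: tuple[int, int] = (1500, 3500),
) -> list[Assembly]:
    """Emulate comparative assemblies of the target against each
    reference.

    Away from the reference's logged divergent events, contigs are
    genuine genome substrings. At each structural event, with
    probability ``miss_rate``, the comparative assembler is assumed to
    have followed the reference: a chimeric contig carrying the
    reference's structure (novel insertion, deletion junction,
    inverted segment, or translocated segment) replaces the genuine
    tiling there. Chimeras are truth-labeled with their causal
    variant.
    """
    if not references:
        raise ValueError("need at least one reference")
    G = len(genome)
    out = []
    for r, (ref_id, _ref_seq, log) in enumerate(references):
        rng = _rng(seed, 6, r)
        contigs: list[Contig] = []
        blocked: list[tuple[int, int]] = []
        k = 0
        for ev in log:
            if ev["kind"] not in _EVENT_KINDS:
                continue
            if rng.random() >= miss_rate:
                continue
            seq, footprint = _chimera_for_event(genome, ev, rng)
            k += 1
            contigs.append(
                Contig(
                    f"{ref_id}_a{k}",
                    seq,
                    ref_id,
                    "chimeric",
                    {"variant": ev["kind"], "footprint": footprint},
                )
            )
            blocked.append(footprint)
        blocked.sort()
        # tile the unblocked genome with genuine substring contigs
        free: list[tuple[int, int]] = []
        cursor = 0
        for s, e in blocked:
            if s > cursor:
                free.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < G:
            free.append((cursor, G))
        for s, e in free:
            pos = s
            while e - pos >= 800:
                length = int(rng.integers(piece_len[0], piece_len[1] + 1))
                end = min(pos + length, e)
                if e - end < 800:
                    end = e
                k += 1
                contigs.append(
                    Contig(f"{ref_id}_a{k}", genome[pos:end], ref_id, "bona_fide")
                )
                pos = end
        out.append(Assembly(ref_id, contigs))
    return out


# ---------------------------------------------------------------------------
# complete fixtures


def build_fixture(
    seed: int,
    genome_len: int = 100_000,
    repeats: Sequence[tuple[int, int]] = ((800, 3), (500, 2)),
    n_refs: int = 3,
    n_rearrangements: int = 6,
    miss_rate: float = 1.0,
    n_assemblies: int = 3,
    mean_contig_len: int = 2000,
    chimera_rate: float = 0.1,
    dbg_tile_len: int = 10000,
    dbg_step: int = 4000,
    similarity_band: tuple[float, float] = (0.80, 0.92),
) -> GenomeFixture:
    """Generate the full study-condition fixture for one target genome:
    a repeat-bearing genome, ``n_refs`` diverged references inside the
    similarity band, de novo fixture assemblies with independent
    chimeras, comparative contig sets with reference-biased chimeras at
    every divergent event (``miss_rate=1``), and a bona fide DBG
    tiling."""
    genome, annotation = generate_genome(genome_len, repeats, seed)
    references = []
    for j in range(n_refs):
        ref, log, _sim = make_reference(
            genome,
            seed=seed * 101 + j,
            band=similarity_band,
            n_rearrangements=n_rearrangements,
        )
        references.append((f"ref{j + 1}", ref, log))
    assemblies = make_fixture_assemblies(
        genome, n_assemblies, mean_contig_len, chimera_rate, seed
    )
    acontig_sets = make_fixture_acontigs(genome, references, miss_rate, seed)
    dbg = tile_genome(genome, dbg_tile_len, dbg_step)
    return GenomeFixture(genome, annotation, references, assemblies, acontig_sets, dbg)


def write_manifest(fixture: GenomeFixture, path: str | Path) -> Path:
    """Sidecar TSV mirroring the truth labels of every fixture contig."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("contig_id\tsource\ttruth\tcausal_variant\n")
        for asm in list(fixture.assemblies) + list(fixture.acontig_sets) + [fixture.dbg]:
            for c in asm:
                fh.write(
                    f"{c.id}\t{c.source}\t{c.truth}\t{c.meta.get('variant', '')}\n"
                )
    return path
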