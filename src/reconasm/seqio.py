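"""Sequence containers and FASTA input/output.

The pipeline operates on contigs: assembled DNA sequences over the
alphabet {A, C, G, T, N}. Contigs carry a source label (the assembly or
reference they came from) and, for synthetic fixtures, a truth label
(``bona_fide`` or ``chimeric``) used by the evaluation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

VALID_TRUTH = ("bona_fide", "chimeric", "unknown")
_ALPHABET = frozenset("ACGTN")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string; N maps to N.

    Raises ``ValueError`` on characters outside {A, C, G, T, N}.
    """
    if not _ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"illegal characters in sequence: {bad}")
    return seq.translate(_RC_TABLE)[::-1]


def _validate_seq(seq: str, ident: str) -> None:
    if not seq:
        raise ValueError(f"contig {ident!r}: empty sequence")
    if not _ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"contig {ident!r}: illegal characters {bad}")


@dataclass
class Contig:
    """One assembled sequence.

    Attributes
    ----------
    id : str
        Non-empty identifier, unique within its assembly.
    seq : str
        Uppercase DNA over {A, C, G, T, N}; length >= 1.
    source : str
        Label of the assembly or reference of origin.
    truth : str
        ``bona_fide`` / ``chimeric`` for synthetic fixtures, else
        ``unknown`` (the default for real inputs).
    meta : dict
        Free-form annotations (e.g. the causal variant of a planted
        chimera); never consulted by the pipeline itself.
    """

    id: str
    seq: str
    source: str = ""
    truth: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        _validate_seq(self.seq, self.id)
        if self.truth not in VALID_TRUTH:
            raise ValueError(f"contig {self.id!r}: bad truth label {self.truth!r}")

    def __len__(self) -> int:
        return len(self.seq)


class Assembly:
    """An ordered, id-unique collection of contigs.

    Input order is preserved; use :meth:`sorted_output` for the
    canonical output ordering (descending length, then id), which keeps
    every pipeline stage byte-deterministic.
    """

    def __init__(self, label: str, contigs: Iterable[Contig] = ()):
        self.label = label
        self.contigs: list[Contig] = list(contigs)
        seen: set[str] = set()
        for c in self.contigs:
            if c.id in seen:
                raise ValueError(f"duplicate contig id {c.id!r} in assembly {label!r}")
            seen.add(c.id)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def __getitem__(self, i: int) -> Contig:
        return self.contigs[i]

    def get(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    def ids(self) -> list[str]:
        return [c.id for c in self.contigs]

    def sorted_output(self) -> "Assembly":
        """Canonical deterministic ordering: descending length, then id."""
        ordered = sorted(self.contigs, key=lambda c: (-len(c.seq), c.id))
        return Assembly(self.label, ordered)

    def __repr__(self) -> str:
        return f"Assembly({self.label!r}, n={len(self.contigs)})"


def read_fasta(path: str | Path, label: str | None = None) -> Assembly:
    """Read a FASTA file into an :class:`Assembly`.

    The header token before the first whitespace becomes the contig id;
    sequences are uppercased and U is mapped to T. Any other character
    outside {A, C, G, T, N} is an error, as are empty files and
    duplicate ids. Both single-line and wrapped FASTA are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label = label if label is not None else path.stem
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        contigs.append(Contig(id=rec.id, seq=seq, source=label))
    if not contigs:
        raise ValueError(f"{path}: no FASTA records")
    return Assembly(label, contigs)


def write_fasta(assembly: Assembly, path: str | Path, width: int = 70) -> Path:
    """Write an assembly as FASTA in canonical output order.

    Round-trip property: ``read_fasta(write_fasta(A))`` preserves every
    id and sequence. An empty assembly is an error.
    """
    if len(assembly) == 0:
        raise ValueError("refusing to write an empty assembly")
    if width < 1:
        raise ValueError("line width must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        for c in assembly.sorted_output():
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")
    return path
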