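"""Circular genome containers, FASTA I/O and rotation handling.

Smacovirus-like CRESS DNA genomes are small (~2.3-2.9 kb) circular
single-stranded DNA molecules.  Deposited records linearize the circle at
an arbitrary position, so two identical genomes may differ by a rotation
(and possibly a strand flip).  This module defines the circular coordinate
convention used throughout the package (0-based, half-open, features may
wrap the origin) and a canonical rotation so circular genomes compare
equal regardless of how they were linearized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide ambiguity codes other than N; coerced to N on input.
_AMBIGUITY = set("RYSWKMBDHV")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularGenome:
    """A circular nucleotide sequence with a stable identifier.

    ``seq`` is the + strand in the current linearization; position 0 is an
    arbitrary point on the circle unless the genome has been canonically
    rotated (see :func:`canonicalize_rotation`).
    """

    id: str
    seq: str
    topology: str = "circular"

    def __post_init__(self):
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: non-IUPAC characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, span: int, strand: str = "+") -> str:
        """Extract ``span`` nt starting at ``start`` walking clockwise,
        wrapping the origin as needed; for strand '-' the reverse
        complement of that stretch is returned."""
        L = self.length
        if span > L:
            raise ValueError("span exceeds genome length")
        start %= L
        doubled = self.seq + self.seq
        s = doubled[start : start + span]
        return revcomp(s) if strand == "-" else s

    def rotated(self, offset: int) -> "CircularGenome":
        """New genome whose position 0 is the old position ``offset``."""
        L = self.length
        offset %= L
        return CircularGenome(self.id, self.seq[offset:] + self.seq[:offset])


@dataclass(frozen=True)
class CircularInterval:
    """Half-open interval on a circle of given length.

    0-based; ``start`` inclusive, ``end`` exclusive.  ``wraps`` marks
    features running through the linearization origin, in which case
    start > end is permitted and the span is (length - start) + end.
    """

    start: int
    end: int
    strand: str = "+"
    wraps: bool = False

    def span(self, length: int) -> int:
        if self.wraps:
            return (length - self.start) + self.end
        return self.end - self.start

    def positions(self, length: int) -> list[int]:
        """All forward-strand positions covered, in clockwise order."""
        return [(self.start + k) % length for k in range(self.span(length))]

    def contains(self, pos: int, length: int) -> bool:
        off = (pos - self.start) % length
        return off < self.span(length)


def make_interval(start: int, span: int, length: int, strand: str = "+") -> CircularInterval:
    """Interval of ``span`` nt beginning at ``start`` (mod length)."""
    if not 1 <= span <= length:
        raise ValueError("span must be in [1, length]")
    start %= length
    end = start + span
    if end > length:
        return CircularInterval(start, end - length, strand, wraps=True)
    return CircularInterval(start, end, strand, wraps=False)


@dataclass(frozen=True)
class Rotation:
    """Record of a rotation (and optional strand flip) applied to a genome,
    so feature coordinates can be mapped between the two linearizations."""

    offset: int
    length: int
    flipped: bool = False

    def map_position(self, pos: int) -> int:
        """Old forward-strand position -> position in the rotated genome."""
        if self.flipped:
            # flip first (revcomp), then rotate
            pos = self.length - 1 - pos
        return (pos - self.offset) % self.length

    def unmap_position(self, pos: int) -> int:
        pos = (pos + self.offset) % self.length
        if self.flipped:
            pos = self.length - 1 - pos
        return pos

    def map_interval(self, iv: CircularInterval) -> CircularInterval:
        L = self.length
        span = iv.span(L)
        if not self.flipped:
            start = self.map_position(iv.start)
            strand = iv.strand
        else:
            # clockwise walk becomes counter-clockwise after a flip:
            # the old last base becomes the new first base
            start = self.map_position((iv.start + span - 1) % L)
            strand = "-" if iv.strand == "+" else "+"
        return make_interval(start, span, L, strand)

    def unmap_interval(self, iv: CircularInterval) -> CircularInterval:
        inv = Rotation(
            offset=(-self.offset) % self.length if not self.flipped else self.offset,
            length=self.length,
            flipped=self.flipped,
        )
        if not self.flipped:
            return inv.map_interval(iv)
        # flip is an involution combined with the same offset: verify by
        # composing map∘unmap = identity (property-tested)
        L = self.length
        span = iv.span(L)
        start_new = self.unmap_position((iv.start + span - 1) % L)
        strand = "-" if iv.strand == "+" else "+"
        return make_interval(start_new, span, L, strand)


def read_fasta(path) -> list[CircularGenome]:
    """Read circular genomes from FASTA.

    Lowercase is uppercased, U mapped to T, and IUPAC ambiguity codes
    other than N are coerced to N with a warning.  Duplicate ids are
    rejected.
    """
    genomes: list[CircularGenome] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        amb = set(seq) & _AMBIGUITY
        if amb:
            warnings.warn(
                f"{rec.id}: ambiguity codes {sorted(amb)} coerced to N",
                stacklevel=2,
            )
            seq = "".join("N" if c in _AMBIGUITY else c for c in seq)
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{rec.id}: invalid characters {sorted(bad)}")
        if not seq:
            raise ValueError(f"{rec.id}: empty sequence")
        genomes.append(CircularGenome(rec.id, seq))
    if not genomes:
        raise ValueError(f"no FASTA records found in {path}")
    return genomes


def write_fasta(genomes, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _lexicographically_minimal_offset(seq: str) -> int:
    """Booth's least-rotation algorithm (O(L))."""
    s = seq + seq
    n = len(seq)
    f = [-1] * len(s)
    k = 0
    for j in range(1, len(s)):
        sj = s[j]
        i = f[j - k - 1]
        while i != -1 and sj != s[k + i + 1]:
            if sj < s[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s[k + i + 1]:
            if sj < s[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
        if k >= n:
            break
    return k % n


def canonicalize_rotation(
    g: CircularGenome, anchor: CircularInterval | None = None
) -> tuple[CircularGenome, Rotation]:
    """Rotate a circular genome into a canonical linearization.

    With an ``anchor`` interval, the genome is rotated (and, for a minus
    strand anchor, strand-flipped) so the anchor starts at position 0 on
    the + strand — the convention used to place the replication-origin
    nonanucleotide first.  Without an anchor, the lexicographically
    minimal rotation of the + strand is used, which is invariant under
    any prior rotation of the input.

    Returns the rotated genome and the :class:`Rotation` needed to map
    coordinates between old and new linearizations.
    """
    L = g.length
    if anchor is None:
        off = _lexicographically_minimal_offset(g.seq)
        return g.rotated(off), Rotation(offset=off, length=L)
    if not (0 <= anchor.start < L and 0 <= anchor.end <= L):
        raise ValueError("anchor outside genome")
    if anchor.strand == "+":
        rot = Rotation(offset=anchor.start, length=L)
        return g.rotated(anchor.start), rot
    # minus-strand anchor: flip to put the motif on the + strand, then
    # rotate its (post-flip) start to 0
    flipped = CircularGenome(g.id, revcomp(g.seq))
    span = anchor.span(L)
    new_start = L - ((anchor.start + span - 1) % L) - 1
    rot = Rotation(offset=new_start, length=L, flipped=True)
    return flipped.rotated(new_start), rot
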