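"""SDT-style pairwise identity for genomes and Rep proteins.

Percent identity drives the smacovirus demarcation criteria (77%
genome-wide nucleotide identity for species, 40% Rep amino-acid identity
for genus), so the exact convention matters and is recorded with every
matrix.  Default convention: global affine-gap alignment; identity =
100 * matches / alignment columns, where terminal-gap columns are
excluded and internal gap columns count in the denominator.  An
alternative convention excluding every gap column is available.

Circular nucleotide inputs are rotation-normalized before alignment:
both genomes are anchored on their replication-origin nonanucleotide
candidates (all best-scoring hits on either strand), and the maximum
identity over the anchor candidates of the second genome is reported.
An exhaustive rotation search is available for verification on short
sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .annotate import NONANUCLEOTIDE, find_nonanucleotide
from .genomes import CircularGenome, canonicalize_rotation

CONVENTIONS = ("internal-gaps-count", "exclude-all-gap-columns")


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    protein_matrix: str = "BLOSUM62"


def _aligner(space: str, params: AlignmentParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    if space == "nucleotide":
        al.match_score = params.match
        al.mismatch_score = params.mismatch
    elif space == "protein":
        al.substitution_matrix = substitution_matrices.load(params.protein_matrix)
    else:
        raise ValueError(f"unknown space {space!r}")
    al.open_gap_score = -params.gap_open
    al.extend_gap_score = -params.gap_extend
    return al


def align_pair_global(
    a: str, b: str, space: str = "nucleotide", params: AlignmentParams | None = None
) -> tuple[str, str, float]:
    """Global affine-gap alignment of two sequences.

    Returns the two gapped rows (equal length) and the alignment score.
    Among co-optimal alignments the aligner's first traceback is taken,
    which is deterministic for fixed inputs and parameters.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    params = params or AlignmentParams()
    aln = _aligner(space, params).align(a, b)
    best = aln[0]
    return str(best[0]), str(best[1]), float(best.score)


def _identity_from_rows(r1: str, r2: str, convention: str) -> float:
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    both = [i for i in range(len(r1)) if r1[i] != "-" and r2[i] != "-"]
    if not both:
        return 0.0
    first, last = both[0], both[-1]
    matches = cols = 0
    for i in range(first, last + 1):
        g1, g2 = r1[i] == "-", r2[i] == "-"
        if convention == "exclude-all-gap-columns" and (g1 or g2):
            continue
        cols += 1
        if not g1 and not g2 and r1[i] == r2[i]:
            matches += 1
    return 100.0 * matches / cols if cols else 0.0


def _anchor_candidates(g: CircularGenome, pattern: str, max_mismatch: int) -> list[str]:
    """Rotations of ``g`` anchored at each best-scoring nonanucleotide hit
    (ties by mismatch count; both strands).  Falls back to the canonical
    lexicographic rotation when no hit exists."""
    hits = find_nonanucleotide(g, pattern, max_mismatch)
    if not hits:
        return [canonicalize_rotation(g)[0].seq]
    best_mm = hits[0].mismatches
    out = []
    for h in hits:
        if h.mismatches > best_mm:
            break
        out.append(canonicalize_rotation(g, anchor=h.position)[0].seq)
    return sorted(set(out))


def pairwise_identity(
    a,
    b,
    space: str = "nucleotide",
    circular: bool = False,
    convention: str = "internal-gaps-count",
    params: AlignmentParams | None = None,
    full_rotation: bool = False,
    pattern: str = NONANUCLEOTIDE,
    max_mismatch: int = 2,
) -> float:
    """Percent identity between two sequences (or circular genomes).

    Linear mode aligns the strings as given.  Circular mode (nucleotide
    only) accepts :class:`CircularGenome` inputs, anchors both on their
    origin-nonanucleotide candidates and reports the maximum identity
    over the second genome's candidates; ``full_rotation=True`` instead
    maximizes over every rotation of the second genome (O(L) alignments —
    verification only).
    """
    if not circular:
        sa = a.seq if isinstance(a, CircularGenome) else a
        sb = b.seq if isinstance(b, CircularGenome) else b
        r1, r2, _ = align_pair_global(sa, sb, space, params)
        return _identity_from_rows(r1, r2, convention)
    if space != "nucleotide":
        raise ValueError("circular mode applies to nucleotide space only")
    ga = a if isinstance(a, CircularGenome) else CircularGenome("a", a)
    gb = b if isinstance(b, CircularGenome) else CircularGenome("b", b)
    a_cands = _anchor_candidates(ga, pattern, max_mismatch)
    if full_rotation:
        a_cands = a_cands[:1]
        b_cands = [gb.rotated(k).seq for k in range(gb.length)]
    else:
        b_cands = _anchor_candidates(gb, pattern, max_mismatch)
    best = 0.0
    # maximum over both candidate sets keeps the value symmetric in (a, b)
    for sa in a_cands:
        for sb in b_cands:
            r1, r2, _ = align_pair_global(sa, sb, space, params)
            best = max(best, _identity_from_rows(r1, r2, convention))
    return best


@dataclass(frozen=True)
class PairwiseIdentityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray       # symmetric percent identities, diagonal 100
    space: str               # nucleotide | protein
    convention: str

    def __post_init__(self):
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# space=%s convention=%s\n" % (self.space, self.convention))
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.2f}" for x in row) + "\n")

    def write_long_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("a,b,identity,space,convention\n")
            for i, j in itertools.combinations(range(len(self.labels)), 2):
                fh.write(
                    f"{self.labels[i]},{self.labels[j]},"
                    f"{self.values[i, j]:.2f},{self.space},{self.convention}\n"
                )

    @classmethod
    def from_pairs(
        cls, labels, pair_values: dict, space: str, default: float = 0.0,
        convention: str = "reported",
    ) -> "PairwiseIdentityMatrix":
        """Build a matrix from reported pair identities (e.g. published
        closest-pair values); unreported pairs get ``default``."""
        labels = tuple(labels)
        n = len(labels)
        vals = np.full((n, n), default, dtype=float)
        np.fill_diagonal(vals, 100.0)
        idx = {lab: k for k, lab in enumerate(labels)}
        for (a, b), v in pair_values.items():
            i, j = idx[a], idx[b]
            vals[i, j] = vals[j, i] = v
        return cls(labels, vals, space, convention)


def identity_matrix(
    seqs,
    space: str = "nucleotide",
    circular: bool = False,
    convention: str = "internal-gaps-count",
    params: AlignmentParams | None = None,
) -> PairwiseIdentityMatrix:
    """All-against-all percent identity.

    ``seqs`` is a list of :class:`CircularGenome` or (label, sequence)
    pairs.  Symmetric by construction; duplicate labels rejected.
    """
    items = [
        (s.id, s) if isinstance(s, CircularGenome) else (s[0], s[1]) for s in seqs
    ]
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    if len(items) < 2:
        raise ValueError("need at least two sequences")
    n = len(items)
    vals = np.zeros((n, n))
    np.fill_diagonal(vals, 100.0)
    for i, j in itertools.combinations(range(n), 2):
        v = pairwise_identity(
            items[i][1], items[j][1], space, circular, convention, params
        )
        vals[i, j] = vals[j, i] = v
    return PairwiseIdentityMatrix(tuple(labels), vals, space, convention)
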