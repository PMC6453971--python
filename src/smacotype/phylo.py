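"""Distance-based phylogenetics: TN93 distances, neighbor-joining,
normalized Robinson-Foulds.

These are the building blocks of the sliding-window recombination scan:
per-window Tamura-Nei (TN93) distance matrices, Saitou-Nei neighbor
joining, and the normalized Robinson-Foulds (RF) distance between the
per-window trees.  TN93 distinguishes the two transition classes
(A<->G and C<->T) from transversions and allows unequal base
frequencies; the distance for a pair of aligned rows is the closed-form
estimator

    d = -k1 ln(1 - P1/k1 - Q/(2 gR)) - k2 ln(1 - P2/k2 - Q/(2 gY))
        - k3 ln(1 - Q/(2 gR gY))

with gR = gA + gG, gY = gC + gT, k1 = 2 gA gG / gR, k2 = 2 gT gC / gY,
k3 = 2 (gR gY - gA gG gY / gR - gT gC gR / gY), P1/P2 the proportions of
A<->G and C<->T transition sites and Q the transversion proportion.
Base frequencies are estimated from the pooled pair.  Columns with a gap
or N in either row are excluded pairwise (pairwise deletion), and a
non-positive logarithm argument marks the pair as saturated (distance set
to a configurable ceiling instead of failing).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

_PURINES = {"A": 0, "G": 1}
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# multiple alignment container


@dataclass(frozen=True)
class MultipleAlignment:
    """Rows of equal length over {A,C,G,T,N,-} with unique labels."""

    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("rows have unequal lengths")
        bad = set("".join(self.rows)) - set("ACGTN-")
        if bad:
            raise ValueError(f"invalid alignment characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n(self) -> int:
        return len(self.rows)

    def window(self, start: int, end: int) -> "MultipleAlignment":
        return MultipleAlignment(self.labels, tuple(r[start:end] for r in self.rows))

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq).upper().replace("U", "T"))
        return cls(tuple(labels), tuple(rows))

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for lab, row in zip(self.labels, self.rows):
                fh.write(f">{lab}\n{row}\n")


# ---------------------------------------------------------------------------
# TN93 distance


@dataclass(frozen=True)
class TN93Result:
    d: float
    saturated: bool
    n_sites: int          # comparable columns after pairwise deletion
    P1: float             # A<->G transition proportion
    P2: float             # C<->T transition proportion
    Q: float              # transversion proportion
    freqs: tuple[float, float, float, float]  # gA, gC, gG, gT (pooled)


def tn93_distance(row_i: str, row_j: str, ceiling: float = 5.0) -> TN93Result:
    """Tamura-Nei (1993) distance between two aligned rows.

    Pairwise deletion of gap/N columns; base frequencies pooled over the
    pair; saturation (non-positive log argument) returns the ceiling with
    ``saturated=True``.
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows not aligned (unequal lengths)")
    pairs = [
        (a, b) for a, b in zip(row_i, row_j) if a in _BASES and b in _BASES
    ]
    n = len(pairs)
    if n < 1:
        raise ValueError("no comparable columns after pairwise deletion")
    counts = {b: 0 for b in _BASES}
    p1 = p2 = q = 0
    for a, b in pairs:
        counts[a] += 1
        counts[b] += 1
        if a == b:
            continue
        pair = {a, b}
        if pair == {"A", "G"}:
            p1 += 1
        elif pair == {"C", "T"}:
            p2 += 1
        else:
            q += 1
    tot = 2 * n
    gA, gC, gG, gT = (counts[b] / tot for b in _BASES)
    P1, P2, Q = p1 / n, p2 / n, q / n
    freqs = (gA, gC, gG, gT)
    if p1 == p2 == q == 0:
        return TN93Result(0.0, False, n, P1, P2, Q, freqs)
    gR, gY = gA + gG, gC + gT
    k1 = 2 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2 * gT * gC / gY if gY > 0 else 0.0
    k3 = (
        2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
        if gR > 0 and gY > 0
        else 0.0
    )
    terms = []
    for k, w in (
        (k1, 1 - (P1 / k1 if k1 > 0 else 0.0) - (Q / (2 * gR) if gR > 0 else 0.0)),
        (k2, 1 - (P2 / k2 if k2 > 0 else 0.0) - (Q / (2 * gY) if gY > 0 else 0.0)),
        (k3, 1 - (Q / (2 * gR * gY) if gR * gY > 0 else 0.0)),
    ):
        if k == 0.0:
            continue
        if w <= 0:
            return TN93Result(ceiling, True, n, P1, P2, Q, freqs)
        terms.append(-k * math.log(w))
    return TN93Result(sum(terms), False, n, P1, P2, Q, freqs)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray                    # symmetric, zero diagonal
    saturated: np.ndarray | None = None  # boolean mask, same shape

    def __post_init__(self):
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def tn93_matrix(aln: MultipleAlignment, ceiling: float = 5.0) -> DistanceMatrix:
    n = aln.n
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        res = tn93_distance(aln.rows[i], aln.rows[j], ceiling)
        d[i, j] = d[j, i] = res.d
        sat[i, j] = sat[j, i] = res.saturated
    return DistanceMatrix(aln.labels, d, sat)


# ---------------------------------------------------------------------------
# unrooted trees


class _Node:
    __slots__ = ("label", "children", "sort_key")

    def __init__(self, label=None, children=None, sort_key=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)
        self.sort_key = sort_key if sort_key is not None else label


@dataclass
class UnrootedTree:
    """Unrooted tree stored with an arbitrary internal node as root.

    Neighbor-joining output is binary (internal degree 3); branch lengths
    are non-negative (negative NJ estimates are clamped to 0 and the
    originals kept in ``clamped``).
    """

    root: _Node
    clamped: list[tuple[str, float]] = field(default_factory=list)

    # -- basic queries ------------------------------------------------------

    def leaf_labels(self) -> frozenset[str]:
        out = []

        def walk(n):
            if not n.children:
                out.append(n.label)
            for c, _ in n.children:
                walk(c)

        walk(self.root)
        return frozenset(out)

    def nontrivial_splits(self, collapse_tol: float = 1e-9) -> frozenset[frozenset[str]]:
        """Bipartitions induced by internal edges, each canonicalized as
        the side containing the lexicographically smallest leaf.  Internal
        edges with length <= collapse_tol are treated as collapsed."""
        leaves = self.leaf_labels()
        anchor = min(leaves)
        splits = set()

        def walk(n) -> set[str]:
            if not n.children:
                return {n.label}
            below = set()
            for c, bl in n.children:
                sub = walk(c)
                # edge (n, c) is internal iff c is internal
                if c.children and bl > collapse_tol:
                    side = sub if anchor in sub else leaves - sub
                    if 1 < len(side) < len(leaves) - 0:
                        if len(side) >= 2 and len(leaves - side) >= 2:
                            splits.add(frozenset(side))
                below |= sub
            return below

        walk(self.root)
        return frozenset(splits)

    # -- serialization ------------------------------------------------------

    def to_newick(self, precision: int = 6) -> str:
        def fmt(n) -> str:
            if not n.children:
                return n.label
            inner = ",".join(
                f"{fmt(c)}:{bl:.{precision}f}" for c, bl in n.children
            )
            return f"({inner})"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "UnrootedTree":
        import dendropy

        t = dendropy.Tree.get(data=text, schema="newick")
        t.deroot()

        def conv(nd) -> _Node:
            if nd.is_leaf():
                return _Node(label=nd.taxon.label.replace(" ", "_"))
            node = _Node()
            for ch in nd.child_nodes():
                bl = ch.edge.length if ch.edge.length is not None else 0.0
                node.children.append((conv(ch), bl))
            return node

        return cls(root=conv(t.seed_node))


def normalized_rf(t1: UnrootedTree, t2: UnrootedTree, collapse_tol: float = 1e-9) -> float:
    """Normalized Robinson-Foulds distance in [0, 1].

    The symmetric difference of the two non-trivial bipartition sets,
    divided by the total number of non-trivial bipartitions realized in
    both trees (2(n-3) for two binary unrooted trees); 0 for identical
    topologies, 1 for topologies sharing no internal split.  Trees with no
    internal splits at all compare as identical (0.0).
    """
    l1, l2 = t1.leaf_labels(), t2.leaf_labels()
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    s1 = t1.nontrivial_splits(collapse_tol)
    s2 = t2.nontrivial_splits(collapse_tol)
    denom = len(s1) + len(s2)
    if denom == 0:
        return 0.0
    return len(s1 ^ s2) / denom


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(D: DistanceMatrix, allow_saturated: bool = True) -> UnrootedTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The standard Q criterion is minimized; ties go to the pair whose
    (lexicographically smallest contained leaf label of i, of j) pair is
    smallest.  Negative branch-length estimates are clamped to zero and
    recorded.  Exactly recovers any additive distance matrix.
    """
    n0 = len(D.labels)
    if n0 < 3:
        raise ValueError("need at least 3 taxa for neighbor joining")
    if not np.all(np.isfinite(D.d)):
        raise ValueError("non-finite distances")
    if not allow_saturated and D.saturated is not None and D.saturated.any():
        raise ValueError("saturated distances present")

    nodes: list[_Node] = [_Node(label=lab) for lab in D.labels]
    d = {
        (i, j): float(D.d[i, j])
        for i in range(n0)
        for j in range(n0)
        if i != j
    }
    active = list(range(n0))
    clamped: list[tuple[str, float]] = []
    next_id = n0

    def dist(i, j):
        return 0.0 if i == j else d[(i, j) if i < j else (j, i)]

    def clamp(node_key, x):
        if x < 0:
            clamped.append((node_key, x))
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                qv = (m - 2) * dist(i, j) - r[i] - r[j]
                key_pair = tuple(sorted((nodes[i].sort_key, nodes[j].sort_key)))
                if best is None or qv < best[0] - 1e-12 or (
                    abs(qv - best[0]) <= 1e-12 and key_pair < best[1]
                ):
                    best = (qv, key_pair, i, j)
        _, _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li = clamp(nodes[i].sort_key, li)
        lj = clamp(nodes[j].sort_key, lj)
        u = _Node(
            children=[(nodes[i], li), (nodes[j], lj)],
            sort_key=min(nodes[i].sort_key, nodes[j].sort_key),
        )
        nodes.append(u)
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            d[(k, next_id) if k < next_id else (next_id, k)] = duk
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = clamp(nodes[a].sort_key, 0.5 * (dist(a, b) + dist(a, c) - dist(b, c)))
    lb = clamp(nodes[b].sort_key, 0.5 * (dist(a, b) + dist(b, c) - dist(a, c)))
    lc = clamp(nodes[c].sort_key, 0.5 * (dist(a, c) + dist(b, c) - dist(a, b)))
    root = _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return UnrootedTree(root=root, clamped=clamped)
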