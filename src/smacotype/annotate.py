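"""Genome annotation for smacovirus-like CRESS DNA circles.

A smacovirus genome carries two major ORFs — the rolling-circle
replication initiator (Rep) and the capsid protein (CP) — plus a
replication origin marked by a degenerate nonanucleotide (NAGTNTTAC) at
the apex of a stem-loop near the 3' end of Rep.  Genomes are typed by ORF
orientation: ambisense (Rep and CP on opposite strands, organization
type IV) or unisense (same strand, type V).

Rep proteins are expected to carry, in order along the protein, the
rolling-circle replication endonuclease motifs I-III and the superfamily-3
helicase Walker A/B/C motifs; the scanner uses configurable degenerate
patterns for these.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

from .genomes import CircularGenome, CircularInterval, make_interval, revcomp

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

NONANUCLEOTIDE = "NAGTNTTAC"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class OrfAnnotation:
    """An open reading frame: ATG through the first in-frame stop.

    ``interval`` is the forward-strand footprint including the stop codon,
    so interval span == 3*(length_aa + 1).  ``protein`` excludes the stop.
    """

    interval: CircularInterval
    length_aa: int
    protein: str
    product: str = "unknown"  # Rep | CP | unknown


@dataclass(frozen=True)
class NonanucleotideHit:
    position: CircularInterval  # 9 nt footprint
    matched: str                # 9-mer as read on position.strand
    mismatches: int


@dataclass(frozen=True)
class StemLoop:
    left_arm: CircularInterval
    right_arm: CircularInterval
    loop: CircularInterval
    stem_len: int
    loop_len: int


@dataclass(frozen=True)
class MotifHit:
    name: str       # RCR-I | RCR-II | RCR-III | Walker-A | Walker-B | Walker-C
    aa_start: int   # 0-based within the Rep protein
    matched: str


@dataclass
class GenomeAnnotation:
    genome_id: str
    genome_length: int
    orfs: list[OrfAnnotation] = field(default_factory=list)
    organization: str = "unclassified"  # IV | V | unclassified
    rep: OrfAnnotation | None = None
    cp: OrfAnnotation | None = None
    nonanucleotide: NonanucleotideHit | None = None
    stem_loop: StemLoop | None = None
    rep_motifs: list[MotifHit] = field(default_factory=list)


# ---------------------------------------------------------------------------
# configuration


#: Degenerate Rep motif patterns (python regex over amino acids).  RCR-I is
#: handled by a positional rule (see :func:`scan_rep_motifs`) because it is
#: defined relative to RCR-II rather than by its own consensus.
DEFAULT_MOTIF_PATTERNS: dict[str, str] = {
    "RCR-II": "H[WFY]Q",
    "RCR-III": "...Y..K",
    "Walker-A": "G..[GH]K[TS]",
    "Walker-B": "[ILVW][ILV]D[ILMTV]P",
    "Walker-C": "[ILV][ILMT][CT]N",
}

MOTIF_ORDER = ["RCR-I", "RCR-II", "RCR-III", "Walker-A", "Walker-B", "Walker-C"]


@dataclass
class AnnotationConfig:
    min_aa: int = 150
    nonanucleotide: str = NONANUCLEOTIDE
    max_mismatch: int = 2
    min_stem: int = 5
    max_stem: int = 12
    max_loop: int = 14
    arm_mismatch: int = 1
    stem_search_flank: int = 150   # nt around the Rep 3' end for origin search
    motif_patterns: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIF_PATTERNS))


# ---------------------------------------------------------------------------
# ORF discovery


def _orfs_on_strand(s: str, L: int, strand: str, min_aa: int) -> list[OrfAnnotation]:
    doubled = s + s
    # maximal ORFs: keep, per physical stop codon, the farthest upstream ATG
    # (the stop position on the circle already fixes strand and frame)
    best: dict[int, tuple[int, int]] = {}  # stop%L -> (span, start)
    for p in range(L):
        if doubled[p : p + 3] != "ATG":
            continue
        q = p + 3
        limit = p + L  # span including stop may not exceed genome length
        while q + 3 <= limit + 3 and q + 3 <= 2 * L:
            if doubled[q : q + 3] in STOP_CODONS:
                break
            q += 3
        else:
            continue
        if q + 3 - p > L:
            continue  # would overlap itself on the circle
        span = q + 3 - p
        n_aa = span // 3 - 1
        if n_aa < min_aa:
            continue
        key = q % L
        if key not in best or span > best[key][0]:
            best[key] = (span, p)
    out = []
    for _stop, (span, p) in best.items():
        cds = doubled[p : p + span - 3]
        protein = str(Seq(cds).translate())
        if strand == "+":
            iv = make_interval(p, span, L, "+")
        else:
            iv = make_interval((L - p - span) % L, span, L, "-")
        out.append(OrfAnnotation(iv, span // 3 - 1, protein))
    return out


def find_orfs(g: CircularGenome, min_aa: int = 150) -> list[OrfAnnotation]:
    """All maximal ORFs (ATG .. first in-frame stop) on both strands of a
    circular genome, wrapping the origin where needed.

    Maximal means one ORF per (strand, frame, stop codon): the earliest
    usable ATG.  ORFs never span more than one full circle.  Sorted by
    protein length, longest first.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if g.length < 3:
        raise ValueError("genome shorter than one codon")
    orfs = _orfs_on_strand(g.seq, g.length, "+", min_aa)
    orfs += _orfs_on_strand(revcomp(g.seq), g.length, "-", min_aa)
    orfs.sort(key=lambda o: (-o.length_aa, o.interval.strand, o.interval.start))
    return orfs


# ---------------------------------------------------------------------------
# Rep motif scanning


def _rcr_i_rule(protein: str, rcr_ii_start: int) -> MotifHit | None:
    """RCR motif I: the short segment ending just before RCR-II, anchored
    on its conserved threonine at position 2 — 5 residues when the T sits
    4 before RCR-II, else 6 residues when it sits 5 before."""
    ii = rcr_ii_start
    if ii >= 5 and protein[ii - 4] == "T":
        return MotifHit("RCR-I", ii - 5, protein[ii - 5 : ii])
    if ii >= 6 and protein[ii - 5] == "T":
        return MotifHit("RCR-I", ii - 6, protein[ii - 6 : ii])
    return None


def scan_rep_motifs(
    protein: str, patterns: dict[str, str] | None = None
) -> list[MotifHit]:
    """Scan a Rep protein for RCR I-III and Walker A-C motifs.

    Motifs are located sequentially left to right (each search starts
    after the previous hit), which enforces the canonical ordering
    RCR-I < RCR-II < RCR-III < Walker-A < Walker-B < Walker-C.  At most
    one hit per motif (leftmost).  Missing motifs are simply absent.
    """
    if not protein:
        raise ValueError("empty protein")
    pats = patterns or DEFAULT_MOTIF_PATTERNS
    hits: list[MotifHit] = []
    m2 = re.search(pats["RCR-II"], protein)
    if m2 is None:
        return hits
    hit_i = _rcr_i_rule(protein, m2.start())
    if hit_i is not None:
        hits.append(hit_i)
    hits.append(MotifHit("RCR-II", m2.start(), m2.group()))
    cursor = m2.end()
    for name in ("RCR-III", "Walker-A", "Walker-B", "Walker-C"):
        m = re.search(pats[name], protein[cursor:])
        if m is None:
            continue
        hits.append(MotifHit(name, cursor + m.start(), m.group()))
        cursor = cursor + m.end()
    return hits


def designate_rep_cp(
    orfs: list[OrfAnnotation], patterns: dict[str, str] | None = None
) -> tuple[OrfAnnotation, OrfAnnotation]:
    """Pick Rep and CP among candidate ORFs.

    Rep is the ORF with the most Rep-motif hits, ties broken by presence
    of a Walker-A hit, then by longer protein; CP is the longest remaining
    ORF.
    """
    if len(orfs) < 2:
        raise ValueError("need at least two ORFs to designate Rep and CP")

    def rep_key(o: OrfAnnotation):
        hits = scan_rep_motifs(o.protein, patterns)
        return (
            len(hits),
            int(any(h.name == "Walker-A" for h in hits)),
            o.length_aa,
        )

    rep = max(orfs, key=rep_key)
    rest = [o for o in orfs if o is not rep]
    cp = max(rest, key=lambda o: o.length_aa)
    return replace(rep, product="Rep"), replace(cp, product="CP")


def classify_organization(rep: OrfAnnotation, cp: OrfAnnotation) -> str:
    """Type IV (ambisense) when Rep and CP sit on opposite strands, type V
    (unisense) when on the same strand."""
    return "V" if rep.interval.strand == cp.interval.strand else "IV"


# ---------------------------------------------------------------------------
# replication origin


def _count_mismatches(word: str, pattern: str) -> int:
    return sum(
        1 for w, p in zip(word, pattern) if p != "N" and w != p
    )


def _circular_distance(a: int, b: int, L: int) -> int:
    d = (a - b) % L
    return min(d, L - d)


def _rep_3prime_end(rep: OrfAnnotation, L: int) -> int:
    iv = rep.interval
    if iv.strand == "+":
        return (iv.start + iv.span(L) - 1) % L
    return iv.start


def find_nonanucleotide(
    g: CircularGenome,
    pattern: str = NONANUCLEOTIDE,
    max_mismatch: int = 2,
    rep: OrfAnnotation | None = None,
) -> list[NonanucleotideHit]:
    """Scan both strands of the circle for the degenerate replication
    origin nonanucleotide (default NAGTNTTAC; N matches anything).

    Hits with at most ``max_mismatch`` mismatches at non-N positions are
    returned, best first: fewest mismatches, then (when Rep is known)
    closest to the Rep 3' end, then position.
    """
    if len(pattern) != 9:
        raise ValueError("pattern must be 9 nt")
    L = g.length
    hits = []
    for strand, s in (("+", g.seq), ("-", revcomp(g.seq))):
        doubled = s + s
        for p in range(L):
            word = doubled[p : p + 9]
            mm = _count_mismatches(word, pattern)
            if mm <= max_mismatch:
                if strand == "+":
                    iv = make_interval(p, 9, L, "+")
                else:
                    iv = make_interval((L - p - 9) % L, 9, L, "-")
                hits.append(NonanucleotideHit(iv, word, mm))
    if rep is not None:
        end3 = _rep_3prime_end(rep, L)
        keyfn = lambda h: (
            h.mismatches,
            _circular_distance(h.position.start, end3, L),
            h.position.strand,
            h.position.start,
        )
    else:
        keyfn = lambda h: (h.mismatches, h.position.strand, h.position.start)
    hits.sort(key=keyfn)
    return hits


def predict_stem_loop(
    g: CircularGenome,
    hit: NonanucleotideHit,
    min_stem: int = 5,
    max_stem: int = 12,
    max_loop: int = 14,
    arm_mismatch: int = 1,
) -> StemLoop | None:
    """Look for an inverted repeat (hairpin stem) whose loop contains the
    nonanucleotide.

    Pure sequence search — no thermodynamics.  Among candidates the
    longest stem wins, then the shortest loop.  Returns None when no arms
    of at least ``min_stem`` bp exist within the mismatch budget.
    """
    L = g.length
    strand = hit.position.strand
    # work in the orientation where the motif reads 5'->3'
    if strand == "+":
        s = g.seq
        m = hit.position.start
    else:
        s = revcomp(g.seq)
        iv = hit.position
        m = (L - iv.start - iv.span(L)) % L
    doubled = s + s
    best: tuple[int, int, int, int] | None = None  # (stem, -loop) best; store (stem, loop, ls, le)
    for loop_len in range(9, max_loop + 1):
        # loop window [ls, le) must contain [m, m+9)
        for ls in range(m + 9 - loop_len, m + 1):
            le = ls + loop_len
            for stem in range(max_stem, min_stem - 1, -1):
                left = doubled[(ls - stem) % L : (ls - stem) % L + stem]
                right = doubled[le % L : le % L + stem]
                mm = sum(1 for a, b in zip(left, revcomp(right)) if a != b)
                if mm <= arm_mismatch:
                    cand = (stem, loop_len, ls, le)
                    if (
                        best is None
                        or stem > best[0]
                        or (stem == best[0] and loop_len < best[1])
                    ):
                        best = cand
                    break  # longer stems tried first for this loop
    if best is None:
        return None
    stem, loop_len, ls, le = best

    def oriented(start: int, span: int) -> CircularInterval:
        start %= L
        if strand == "+":
            return make_interval(start, span, L, "+")
        return make_interval((L - start - span) % L, span, L, "-")

    return StemLoop(
        left_arm=oriented(ls - stem, stem),
        right_arm=oriented(le, stem),
        loop=oriented(ls, loop_len),
        stem_len=stem,
        loop_len=loop_len,
    )


# ---------------------------------------------------------------------------
# full annotation


def annotate_genome(
    g: CircularGenome, config: AnnotationConfig | None = None
) -> GenomeAnnotation:
    """Run the full annotation cascade on one circular genome.

    ORFs -> Rep/CP designation -> organization typing -> nonanucleotide ->
    stem-loop -> Rep motif scan.  Optional steps that fail leave their
    fields empty (logged) rather than aborting.
    """
    cfg = config or AnnotationConfig()
    ann = GenomeAnnotation(genome_id=g.id, genome_length=g.length)
    ann.orfs = find_orfs(g, cfg.min_aa)
    try:
        rep, cp = designate_rep_cp(ann.orfs, cfg.motif_patterns)
        ann.rep, ann.cp = rep, cp
        ann.organization = classify_organization(rep, cp)
    except ValueError:
        log.warning("%s: fewer than two ORFs >= %d aa; organization unclassified",
                    g.id, cfg.min_aa)
    hits = find_nonanucleotide(g, cfg.nonanucleotide, cfg.max_mismatch, rep=ann.rep)
    if ann.rep is not None and hits:
        # restrict to the flank around the Rep 3' end when possible
        end3 = _rep_3prime_end(ann.rep, g.length)
        near = [
            h for h in hits
            if _circular_distance(h.position.start, end3, g.length) <= cfg.stem_search_flank
        ]
        if near:
            hits = near
    if hits:
        ann.nonanucleotide = hits[0]
        ann.stem_loop = predict_stem_loop(
            g, hits[0], cfg.min_stem, cfg.max_stem, cfg.max_loop, cfg.arm_mismatch
        )
        if ann.stem_loop is None:
            log.info("%s: no stem-loop found around nonanucleotide", g.id)
    else:
        log.info("%s: no nonanucleotide hit", g.id)
    if ann.rep is not None:
        ann.rep_motifs = scan_rep_motifs(ann.rep.protein, cfg.motif_patterns)
    return ann


# ---------------------------------------------------------------------------
# annotation output (GFF3 / table)


def _gff3_lines(ann: GenomeAnnotation) -> list[str]:
    L = ann.genome_length
    lines = [f"##sequence-region {ann.genome_id} 1 {L}"]

    def emit(iv: CircularInterval, ftype: str, fid: str, attrs: str = ""):
        extra = ";" + attrs if attrs else ""
        if not iv.wraps:
            lines.append(
                f"{ann.genome_id}\tsmacotype\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={fid}{extra}"
            )
        else:
            # wrapping feature: two joined parts sharing one ID
            lines.append(
                f"{ann.genome_id}\tsmacotype\t{ftype}\t{iv.start + 1}\t{L}\t.\t{iv.strand}\t.\tID={fid}{extra}"
            )
            lines.append(
                f"{ann.genome_id}\tsmacotype\t{ftype}\t1\t{iv.end}\t.\t{iv.strand}\t.\tID={fid}{extra}"
            )

    for k, orf in enumerate(ann.orfs):
        name = orf.product if orf.product != "unknown" else f"orf{k + 1}"
        emit(orf.interval, "CDS", f"{ann.genome_id}.{name}",
             f"product={name};length_aa={orf.length_aa}")
    if ann.nonanucleotide:
        emit(ann.nonanucleotide.position, "origin_of_replication",
             f"{ann.genome_id}.nona",
             f"motif={ann.nonanucleotide.matched};mismatches={ann.nonanucleotide.mismatches}")
    if ann.stem_loop:
        sl = ann.stem_loop
        emit(sl.left_arm, "stem_loop", f"{ann.genome_id}.stem5")
        emit(sl.right_arm, "stem_loop", f"{ann.genome_id}.stem3")
    return lines


def write_annotation_table(
    annotations: list[GenomeAnnotation], path, format: str = "tsv"
) -> None:
    """Write annotations as GFF3 (1-based inclusive; wrapping features as
    two parts with a shared ID) or as a per-genome feature table (genome
    length, Rep/CP protein lengths, nonanucleotide and Rep motif strings).
    """
    if format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for ann in annotations:
                fh.write("\n".join(_gff3_lines(ann)) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    cols = [
        "genome", "genome_length_nt", "organization", "rep_aa", "cp_aa",
        "nonanucleotide", "RCR-I", "RCR-II", "RCR-III",
        "Walker-A", "Walker-B", "Walker-C",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ann in annotations:
            motifs = {h.name: h.matched for h in ann.rep_motifs}
            row = [
                ann.genome_id,
                str(ann.genome_length),
                ann.organization,
                str(ann.rep.length_aa) if ann.rep else "",
                str(ann.cp.length_aa) if ann.cp else "",
                ann.nonanucleotide.matched if ann.nonanucleotide else "",
            ] + [motifs.get(n, "") for n in MOTIF_ORDER]
            fh.write("\t".join(row) + "\n")
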