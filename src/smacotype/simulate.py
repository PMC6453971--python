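"""Synthetic smacovirus-like datasets with known ground truth.

The generator emulates the features of real smacovirus genomes so every
pipeline stage can be exercised without downloads: 2.4-2.8 kb circular
genomes with a Rep ORF (230-290 codons, carrying RCR I-III and Walker
A-C motif strings in order), a CP ORF (270-370 codons) in ambisense
(type IV) or unisense (type V) orientation, a stem-loop whose loop holds
a nonanucleotide within 150 nt of the Rep 3' end, lineage divergence
under the TN93 substitution model, and optional inter-lineage
recombination events with exact recorded breakpoints.

Truth is self-checked at generation time: a scaffold is rejection-sampled
until the package's own annotator recovers every planted feature, so the
emitted truth record is consistent with the sequences by construction.
No indel process is simulated — the true alignment is gap-free, which
keeps TN93/RF arithmetic exact for tests.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm

from .annotate import (
    AnnotationConfig,
    annotate_genome,
    designate_rep_cp,
    find_nonanucleotide,
    find_orfs,
    predict_stem_loop,
)
from .genomes import CircularGenome, CircularInterval, make_interval, revcomp, write_fasta
from .phylo import MultipleAlignment

_BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(_BASES)}

#: codons per amino acid (standard code), deterministic order
_CODONS: dict[str, list[str]] = {}
for _c in (
    a + b + c for a in _BASES for b in _BASES for c in _BASES
):
    from Bio.Seq import Seq as _Seq

    _aa = str(_Seq(_c).translate())
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_c)

#: stops every reading frame on both strands (own reverse complement)
_STOP_CASSETTE = "TTAATTAATTAA"

#: filler amino acids that cannot create spurious motif-pattern matches:
#: every default motif pattern requires at least one of K, N, P or Q, so a
#: filler alphabet excluding those four can never complete a match.  The
#: T/I/L/V/F/Y-rich remainder keeps shifted reading frames full of stop
#: codons, so frame-shifted read-through ORFs stay short.
_FILLER_AA = "ADEFGHILMRSTVWY"


@dataclass(frozen=True)
class ScaffoldSpec:
    """Planted feature strings; defaults follow a typical ambisense
    smacovirus feature set."""

    nonanucleotide: str = "TAGTATTAC"
    stem_len: int = 7
    loop_len: int = 11
    rcr_i: str = "MTAPR"      # positional rule: conserved T at index 1
    rcr_ii: str = "HWQ"
    rcr_iii: str = "CRIYEAK"
    walker_a: str = "GNVGKS"
    walker_b: str = "IIDVP"
    walker_c: str = "VMTN"

    def motifs_in_order(self) -> list[tuple[str, str]]:
        return [
            ("RCR-I", self.rcr_i),
            ("RCR-II", self.rcr_ii),
            ("RCR-III", self.rcr_iii),
            ("Walker-A", self.walker_a),
            ("Walker-B", self.walker_b),
            ("Walker-C", self.walker_c),
        ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the real genomes the package targets: genome length
    sampled in 2400-2800 nt, Rep 230-290 aa, CP 270-370 aa, ambisense
    organization, equal base frequencies with transition/transversion
    rate ratio 2, and a root-to-tip divergence of 0.15 substitutions per
    site (pairwise identities roughly 75-95% within a clade).
    """

    n_lineages: int = 8
    genome_length: int | None = None
    organization: str = "IV"            # IV (ambisense) | V (unisense)
    rep_len_aa: int | None = None
    cp_len_aa: int | None = None
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa_ag: float = 2.0               # A<->G rate multiplier vs transversions
    kappa_ct: float = 2.0               # C<->T rate multiplier
    tree_height: float = 0.15           # root-to-tip, subst/site
    tree: str | None = None             # newick override for the lineage tree
    scaffold: ScaffoldSpec = field(default_factory=ScaffoldSpec)
    min_aa: int = 150                   # stray-ORF rejection threshold
    events: list[tuple[str, str, int, int]] = field(default_factory=list)
    n_unisense: int = 0                 # extra independent type-V scaffolds
    seed: int = 1


# ---------------------------------------------------------------------------
# scaffold construction


def _random_partition(total: int, parts: int, rng) -> list[int]:
    if total < 0:
        raise ValueError("negative filler budget")
    cuts = sorted(rng.integers(0, total + 1, size=parts - 1).tolist())
    edges = [0] + cuts + [total]
    return [edges[k + 1] - edges[k] for k in range(parts)]


def _reverse_translate(protein: str, rng) -> str:
    return "".join(
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein
    )


def _random_nt(n: int, rng, freqs) -> str:
    idx = rng.choice(4, size=n, p=list(freqs))
    return "".join(_BASES[i] for i in idx)


def _spacer(n: int, rng, freqs) -> str:
    """Random spacer; long spacers get an all-frame stop cassette at both
    ends to discourage ORFs extending across them."""
    if n >= 2 * len(_STOP_CASSETTE) + 2:
        mid = _random_nt(n - 2 * len(_STOP_CASSETTE), rng, freqs)
        return _STOP_CASSETTE + mid + _STOP_CASSETTE
    return _random_nt(n, rng, freqs)


def _build_rep_protein(spec: ScaffoldSpec, rep_len_aa: int, rng) -> tuple[str, dict[str, int]]:
    motifs = spec.motifs_in_order()
    # RCR-I is defined as the residues immediately preceding RCR-II, so the
    # two are planted as one fused block with no filler between them
    blocks = [(("RCR-I", "RCR-II"), spec.rcr_i + spec.rcr_ii)] + [
        ((name,), s) for name, s in motifs[2:]
    ]
    budget = rep_len_aa - 1 - sum(len(s) for _, s in blocks)
    if budget < 6:
        raise ValueError("Rep too short for the planted motifs")
    fillers = _random_partition(budget, len(blocks) + 1, rng)
    # keep a few residues between blocks so motif context windows
    # cannot collide
    while any(f < 3 for f in fillers[1:-1]):
        fillers = _random_partition(budget, len(blocks) + 1, rng)
    protein = "M"
    positions: dict[str, int] = {}
    for k, (names, s) in enumerate(blocks):
        protein += "".join(rng.choice(list(_FILLER_AA), size=fillers[k]))
        off = len(protein)
        widths = [len(dict(motifs)[n]) for n in names]
        for n, w in zip(names, widths):
            positions[n] = off
            off += w
        protein += s
    protein += "".join(rng.choice(list(_FILLER_AA), size=fillers[-1]))
    assert len(protein) == rep_len_aa
    return protein, positions


def _interval_dict(iv: CircularInterval) -> dict:
    return {"start": iv.start, "end": iv.end, "strand": iv.strand, "wraps": iv.wraps}


def build_scaffold(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CircularGenome, dict]:
    """Construct one ancestor genome with planted features and its truth
    record; rejection-sampled until annotation recovers the truth.

    Raises when the requested geometry is infeasible (ORFs plus origin
    longer than the genome) or when rejection sampling fails repeatedly.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    spec = cfg.scaffold
    L = int(cfg.genome_length or rng.integers(2400, 2801))
    rep_aa = int(cfg.rep_len_aa or rng.integers(230, 291))
    cp_aa = int(cfg.cp_len_aa or rng.integers(270, 371))
    rep_span = 3 * (rep_aa + 1)
    cp_span = 3 * (cp_aa + 1)
    block_len = 2 * spec.stem_len + spec.loop_len
    fixed = rep_span + cp_span + block_len
    if fixed + 60 > L:
        raise ValueError(
            f"infeasible geometry: features need {fixed}+spacers nt, genome is {L} nt"
        )
    last_err = "unknown"
    for _attempt in range(300):
        rep_protein, motif_pos = _build_rep_protein(spec, rep_aa, rng)
        rep_cds = "ATG" + _reverse_translate(rep_protein[1:], rng) + "TAA"
        cp_protein = "M" + "".join(
            rng.choice(list(_FILLER_AA), size=cp_aa - 1)
        )
        cp_cds = "ATG" + _reverse_translate(cp_protein[1:], rng) + "TAA"
        left = _random_nt(spec.stem_len, rng, cfg.base_freqs)
        pre = (spec.loop_len - 9) // 2
        post = spec.loop_len - 9 - pre
        loop = (
            _random_nt(pre, rng, cfg.base_freqs)
            + spec.nonanucleotide
            + _random_nt(post, rng, cfg.base_freqs)
        )
        block = left + loop + revcomp(left)
        s1 = int(rng.integers(14, min(41, 150 - spec.stem_len)))
        rest = L - rep_span - block_len - cp_span - s1
        if rest < 28:
            raise ValueError("infeasible geometry: no room for spacers")
        s2 = int(rng.integers(14, rest - 13))
        s3 = rest - s2
        seq = (
            rep_cds
            + _spacer(s1, rng, cfg.base_freqs)
            + block
            + _spacer(s2, rng, cfg.base_freqs)
            + (cp_cds if cfg.organization == "V" else revcomp(cp_cds))
            + _spacer(s3, rng, cfg.base_freqs)
        )
        assert len(seq) == L
        g = CircularGenome("ancestor", seq)
        rep_iv = make_interval(0, rep_span, L, "+")
        cp_start = rep_span + s1 + block_len + s2
        cp_strand = "+" if cfg.organization == "V" else "-"
        cp_iv = make_interval(cp_start, cp_span, L, cp_strand)
        nona_start = rep_span + s1 + spec.stem_len + pre
        nona_iv = make_interval(nona_start, 9, L, "+")
        stem_left = make_interval(rep_span + s1, spec.stem_len, L, "+")
        stem_right = make_interval(
            rep_span + s1 + spec.stem_len + spec.loop_len, spec.stem_len, L, "+"
        )

        # --- self-check: the annotator must recover exactly the truth
        orfs = find_orfs(g, cfg.min_aa)
        found = {
            (o.interval.start, o.interval.end, o.interval.strand) for o in orfs
        }
        want = {
            (rep_iv.start, rep_iv.end, rep_iv.strand),
            (cp_iv.start, cp_iv.end, cp_iv.strand),
        }
        if found != want:
            last_err = f"ORF set mismatch ({len(orfs)} ORFs)"
            continue
        rep_orf, cp_orf = designate_rep_cp(orfs)
        if (rep_orf.interval.start, rep_orf.interval.strand) != (0, "+"):
            last_err = "Rep designation mismatch"
            continue
        hits = find_nonanucleotide(g, rep=rep_orf)
        if not hits or (hits[0].position.start, hits[0].position.strand) != (
            nona_iv.start, "+",
        ) or hits[0].mismatches != 0:
            last_err = "nonanucleotide not uniquely recovered"
            continue
        sl = predict_stem_loop(g, hits[0])
        if sl is None or sl.stem_len < spec.stem_len:
            last_err = "stem-loop not recovered"
            continue

        truth = {
            "length": L,
            "organization": cfg.organization,
            "rep": _interval_dict(rep_iv),
            "cp": _interval_dict(cp_iv),
            "rep_len_aa": rep_aa,
            "cp_len_aa": cp_aa,
            "nonanucleotide": _interval_dict(nona_iv),
            "nonanucleotide_seq": spec.nonanucleotide,
            "stem_left": _interval_dict(stem_left),
            "stem_right": _interval_dict(stem_right),
            "stem_len": spec.stem_len,
            "loop_len": spec.loop_len,
            "rep_motif_aa_positions": motif_pos,
            "rep_motif_strings": {n: s for n, s in spec.motifs_in_order()},
            "rep_protein": rep_protein,
        }
        return g, truth
    raise RuntimeError(f"scaffold rejection sampling failed: {last_err}")


# ---------------------------------------------------------------------------
# substitution process (TN93)


def tn93_rate_matrix(
    base_freqs, kappa_ag: float, kappa_ct: float
) -> np.ndarray:
    """TN93 instantaneous rate matrix (order A,C,G,T), normalized so the
    expected substitution rate at stationarity is 1 per unit branch
    length."""
    pi = np.asarray(base_freqs, dtype=float)
    if not np.isclose(pi.sum(), 1.0):
        raise ValueError("base frequencies must sum to 1")
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            pair = {_BASES[i], _BASES[j]}
            rate = 1.0
            if pair == {"A", "G"}:
                rate = kappa_ag
            elif pair == {"C", "T"}:
                rate = kappa_ct
            Q[i, j] = rate * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def _mutate(
    states: np.ndarray, t: float, Q: np.ndarray, rng, protected: np.ndarray | None
) -> np.ndarray:
    P = expm(Q * t)
    cum = np.cumsum(P, axis=1)
    u = rng.random(states.size)
    child = (u[:, None] > cum[states]).sum(axis=1).astype(np.int8)
    if protected is not None:
        child[protected] = states[protected]
    return child


_STOPS_SET = {"TAA", "TAG", "TGA"}


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _repair_nonsense(
    child: np.ndarray, parent: np.ndarray, orf_specs, L: int
) -> int:
    """Revert codons that mutated into in-frame stops inside planted ORFs
    (interior codons only) so ORFs stay annotatable at high divergence."""
    repaired = 0
    for start, span, strand in orf_specs:
        ncod = span // 3
        for c in range(1, ncod - 1):  # skip start and terminal stop
            if strand == "+":
                idx = [(start + 3 * c + k) % L for k in range(3)]
                codon = "".join(_BASES[child[i]] for i in idx)
            else:
                # codon c of a minus-strand ORF, read 5'->3' on '-':
                # walk backwards from the footprint's last base, complementing
                last = (start + span - 1) % L
                idx = [(last - 3 * c - k) % L for k in range(3)]
                codon = "".join(_COMP[_BASES[child[i]]] for i in idx)
            if codon in _STOPS_SET:
                for i in idx:
                    child[i] = parent[i]
                repaired += 1
    return repaired


def random_ultrametric_tree(
    labels: list[str], height: float, rng: np.random.Generator
) -> dendropy.Tree:
    """Random coalescent-style ultrametric tree: random join order with
    join depths evenly spaced up to ``height`` (root-to-tip)."""
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two lineages")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nd.depth = 0.0
        nodes.append(nd)
    k = 1
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        b = nodes.pop(j)
        a = nodes.pop(i)
        depth = height * k / (n - 1)
        parent = dendropy.Node()
        parent.depth = depth
        for ch in (a, b):
            parent.add_child(ch)
            ch.edge.length = depth - ch.depth
        nodes.append(parent)
        k += 1
    tree.seed_node = nodes[0]
    return tree


def paired_clades_tree(n_pairs: int, within_d: float, between_d: float) -> str:
    """Newick for ``n_pairs`` two-lineage clades with within-pair distance
    ``within_d`` and between-pair distance ``between_d`` (ultrametric)."""
    w, b = within_d / 2.0, between_d / 2.0
    clades = [
        f"(P{k + 1}a:{w:.6f},P{k + 1}b:{w:.6f}):{b - w:.6f}"
        for k in range(n_pairs)
    ]
    return "(" + ",".join(clades) + ");"


def evolve_lineages(
    ancestor: CircularGenome | str,
    tree: dendropy.Tree | str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    protected: np.ndarray | None = None,
    orf_specs: list[tuple[int, int, str]] | None = None,
) -> tuple[MultipleAlignment, dict[str, CircularGenome], int]:
    """Evolve the ancestor down the tree under TN93.

    Sites are independent; branch lengths are expected substitutions per
    site.  ``protected`` positions (motif anchors, start/stop codons) are
    never mutated, and codons that mutate into premature stops inside
    ``orf_specs`` ORFs are reverted (counted).  Returns the gap-free true
    alignment, per-lineage circular genomes, and the number of reverted
    codons.
    """
    seq = ancestor.seq if isinstance(ancestor, CircularGenome) else ancestor
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    L = len(seq)
    Q = tn93_rate_matrix(cfg.base_freqs, cfg.kappa_ag, cfg.kappa_ct)
    root_states = np.array([_B2I[b] for b in seq], dtype=np.int8)
    repairs = 0
    states = {id(tree.seed_node): root_states}
    leaves: dict[str, np.ndarray] = {}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            parent_states = root_states
        else:
            parent_states = states[id(nd.parent_node)]
            t = nd.edge.length or 0.0
            child = (
                parent_states.copy()
                if t == 0
                else _mutate(parent_states, t, Q, rng, protected)
            )
            if orf_specs:
                repairs += _repair_nonsense(child, parent_states, orf_specs, L)
            states[id(nd)] = child
            parent_states = child
        if nd.is_leaf():
            leaves[nd.taxon.label.replace(" ", "_")] = parent_states
    labels = tuple(leaves)
    rows = tuple("".join(_BASES[i] for i in leaves[lab]) for lab in labels)
    aln = MultipleAlignment(labels, rows)
    genomes = {lab: CircularGenome(lab, row) for lab, row in zip(labels, rows)}
    return aln, genomes, repairs


# ---------------------------------------------------------------------------
# recombination events


def apply_recombination(
    rows: dict[str, CircularGenome],
    events: list[tuple[str, str, int, int]],
    truth: dict,
) -> dict[str, CircularGenome]:
    """Replace, for each (donor, acceptor, start, end) event, the
    acceptor's segment [start, end) by the donor's homologous segment
    (true-alignment coordinates; no indels so coordinates coincide).
    Events are applied in listed order; exact breakpoints are recorded in
    ``truth['events']``."""
    out = dict(rows)
    recorded = truth.setdefault("events", [])
    for donor, acceptor, start, end in events:
        if donor not in out or acceptor not in out:
            raise ValueError(f"unknown lineage in event {donor}->{acceptor}")
        L = out[acceptor].length
        if not (0 <= start < end <= L):
            raise ValueError(f"breakpoints out of range: {start}, {end}")
        dseq, aseq = out[donor].seq, out[acceptor].seq
        new = aseq[:start] + dseq[start:end] + aseq[end:]
        out[acceptor] = CircularGenome(acceptor, new)
        recorded.append(
            {"donor": donor, "acceptor": acceptor, "start": int(start), "end": int(end)}
        )
    return out


def true_breakpoints(truth: dict, L: int | None = None) -> list[int]:
    """Flat list of planted breakpoint coordinates (both edges of every
    recombined segment).  When the sequence length ``L`` is given, edges
    coinciding with the sequence ends (0 or L) are dropped — a transferred
    segment that runs to the end of the alignment has no crossover there."""
    out = []
    for ev in truth.get("events", []):
        out.extend([ev["start"], ev["end"]])
    if L is not None:
        out = [b for b in out if 0 < b < L]
    return out


# ---------------------------------------------------------------------------
# dataset emission


def _protected_mask(truth: dict, L: int) -> np.ndarray:
    """Boolean mask of sites exempt from substitution: ORF start/stop
    codons, motif-coding codons, the nonanucleotide and the stem arms."""
    mask = np.zeros(L, dtype=bool)

    def cover(start, span, strand="+"):
        for k in range(span):
            mask[(start + k) % L] = True

    for key, n_aa in (("rep", truth["rep_len_aa"]), ("cp", truth["cp_len_aa"])):
        iv = truth[key]
        span = 3 * (n_aa + 1)
        cover(iv["start"], 3)                      # first footprint codon
        cover((iv["start"] + span - 3) % L, 3)     # last footprint codon
    rep = truth["rep"]
    for name, aa_pos in truth["rep_motif_aa_positions"].items():
        width = len(truth["rep_motif_strings"][name])
        cover(rep["start"] + 3 * aa_pos, 3 * width)
    nona = truth["nonanucleotide"]
    cover(nona["start"], 9)
    for key in ("stem_left", "stem_right"):
        iv = truth[key]
        cover(iv["start"], truth["stem_len"])
    return mask


def emit_dataset(cfg: SimulationConfig, out_dir) -> dict:
    """Generate and write a full synthetic dataset.

    Writes genomes.fasta (all lineages plus any extra unisense scaffolds),
    alignment.fasta (the gap-free true alignment of the main lineage set),
    truth.json and breakpoints.tsv.  Deterministic for a fixed config and
    seed.  Returns a dict with the file paths and in-memory objects.
    """
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(out_dir, exist_ok=True)
    ancestor, truth = build_scaffold(cfg, rng)
    labels = [f"L{k + 1:02d}" for k in range(cfg.n_lineages)]
    if cfg.tree is not None:
        tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
        labels = [lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()]
    else:
        tree = random_ultrametric_tree(labels, cfg.tree_height, rng)
    mask = _protected_mask(truth, ancestor.length)
    rep_iv, cp_iv = truth["rep"], truth["cp"]
    L = ancestor.length
    orf_specs = [
        (rep_iv["start"], truth["rep_len_aa"] * 3 + 3, rep_iv["strand"]),
        (cp_iv["start"], truth["cp_len_aa"] * 3 + 3, cp_iv["strand"]),
    ]
    aln, genomes, repairs = evolve_lineages(
        ancestor, tree, cfg, rng, protected=np.flatnonzero(mask), orf_specs=orf_specs
    )
    genomes = apply_recombination(genomes, cfg.events, truth)
    aln = MultipleAlignment(
        tuple(genomes), tuple(genomes[lab].seq for lab in genomes)
    )
    dataset_truth = {
        "seed": cfg.seed,
        "tree": tree.as_string(schema="newick").strip(),
        "protected_sites": int(mask.sum()),
        "repaired_codons": int(repairs),
        "scaffold": truth,
        "genomes": {lab: dict(truth, id=lab) for lab in genomes},
        "events": truth.get("events", []),
    }
    extra: dict[str, CircularGenome] = {}
    for k in range(cfg.n_unisense):
        ucfg = SimulationConfig(
            n_lineages=1,
            genome_length=cfg.genome_length,
            organization="V",
            scaffold=cfg.scaffold,
            base_freqs=cfg.base_freqs,
            seed=cfg.seed,
        )
        ug, utruth = build_scaffold(ucfg, rng)
        lab = f"U{k + 1:02d}"
        extra[lab] = CircularGenome(lab, ug.seq)
        dataset_truth["genomes"][lab] = dict(utruth, id=lab)
    paths = {
        "genomes": os.path.join(out_dir, "genomes.fasta"),
        "alignment": os.path.join(out_dir, "alignment.fasta"),
        "truth": os.path.join(out_dir, "truth.json"),
        "breakpoints": os.path.join(out_dir, "breakpoints.tsv"),
    }
    write_fasta(list(genomes.values()) + list(extra.values()), paths["genomes"])
    aln.to_fasta(paths["alignment"])
    with open(paths["truth"], "w") as fh:
        json.dump(dataset_truth, fh, indent=1, sort_keys=True)
    with open(paths["breakpoints"], "w") as fh:
        fh.write("position\tprovenance\n")
        for ev in truth.get("events", []):
            fh.write(f"{ev['start']}\t{ev['donor']}>{ev['acceptor']}\n")
            fh.write(f"{ev['end']}\t{ev['donor']}>{ev['acceptor']}\n")
    return {
        "paths": paths,
        "alignment": aln,
        "genomes": {**genomes, **extra},
        "truth": dataset_truth,
    }
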