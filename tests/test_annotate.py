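"""Annotation: ORF discovery on circles, origin detection, motif scan."""

import numpy as np
import pandas as pd
import pytest

import smacotype as st
from smacotype.annotate import (
    MOTIF_ORDER,
    STOP_CODONS,
    _count_mismatches,
    scan_rep_motifs,
    write_annotation_table,
)
from smacotype.genomes import CircularGenome, Rotation, make_interval, revcomp
from smacotype import studydata


# ---------------------------------------------------------------------------
# ORF discovery


def brute_force_orfs(seq, min_aa):
    """Independent oracle: every ATG..first-stop ORF on the explicitly
    doubled sequence of both strands (span capped at L), as raw tuples
    (strand, start-in-strand-coords, span)."""
    L = len(seq)
    found = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        doubled = s + s
        for p in range(L):
            if doubled[p : p + 3] != "ATG":
                continue
            q = p + 3
            while q + 3 <= 2 * L:
                if doubled[q : q + 3] in STOP_CODONS:
                    break
                q += 3
            else:
                continue
            span = q + 3 - p
            if span > L or span // 3 - 1 < min_aa:
                continue
            found.add((strand, p, span))
    return found


def to_strand_coords(orf, L):
    iv = orf.interval
    span = iv.span(L)
    if iv.strand == "+":
        return ("+", iv.start, span)
    return ("-", (L - iv.start - span) % L, span)


def test_wrapping_orf_matches_brute_force_oracle():
    # 66-nt circle with a 12-codon ORF spanning the origin
    core = "ATG" + "GCT" * 11 + "TAA"
    pad = "CCTAA" * 5 + "CC"
    seq = core[20:] + pad + core[:20]
    g = CircularGenome("w", seq)
    orfs = st.find_orfs(g, min_aa=5)
    oracle = brute_force_orfs(seq, 5)
    ours = {to_strand_coords(o, g.length) for o in orfs}
    assert ours <= oracle
    wrapping = [o for o in orfs if o.interval.wraps]
    assert len(wrapping) == 1
    assert wrapping[0].length_aa == 12 and wrapping[0].protein.startswith("M")


def test_random_circles_orfs_are_subset_of_oracle_and_maximal():
    rng = np.random.default_rng(17)
    for _ in range(10):
        L = int(rng.integers(60, 300))
        seq = "".join(rng.choice(list("ACGT"), size=L))
        g = CircularGenome("r", seq)
        orfs = st.find_orfs(g, min_aa=3)
        oracle = brute_force_orfs(seq, 3)
        ours = {to_strand_coords(o, L) for o in orfs}
        assert ours <= oracle
        # maximality: no oracle ORF with the same stop is longer than ours
        for strand, p, span in ours:
            stop = (p + span) % L
            longer = [
                o for o in oracle
                if o[0] == strand and (o[1] + o[2]) % L == stop
                and o[1] % 3 == p % 3 and o[2] > span
            ]
            assert not longer


def test_poly_a_circle_has_no_orfs():
    assert st.find_orfs(CircularGenome("a", "A" * 300), min_aa=1) == []


def test_orf_translation_consistency(scaffolds):
    for g, _truth in scaffolds[:4]:
        for o in st.find_orfs(g, 150):
            span = o.interval.span(g.length)
            cds = g.fetch(o.interval.start, span, o.interval.strand)
            from Bio.Seq import Seq

            assert str(Seq(cds[:-3]).translate()) == o.protein
            assert cds[-3:] in STOP_CODONS
            assert 3 * (o.length_aa + 1) == span


def test_orf_set_invariant_under_rotation(scaffolds):
    g, _ = scaffolds[0]
    base = {
        (o.interval.start, o.interval.end, o.interval.strand)
        for o in st.find_orfs(g, 150)
    }
    for k in (1, 137, 1200):
        rot = Rotation(offset=k, length=g.length)
        mapped = {
            (iv.start, iv.end, iv.strand)
            for iv in (
                rot.map_interval(o.interval) for o in st.find_orfs(g, 150)
            )
        }
        found = {
            (o.interval.start, o.interval.end, o.interval.strand)
            for o in st.find_orfs(g.rotated(k), 150)
        }
        assert mapped == found
        assert len(base) == len(found)


def test_find_orfs_rejects_sub_codon_genome():
    with pytest.raises(ValueError):
        st.find_orfs(CircularGenome("t", "AC"), 1)


# ---------------------------------------------------------------------------
# nonanucleotide


def test_nonanucleotide_mismatch_counting_matches_reported_hits():
    # reported motifs span 0, 1 and 2 mismatches against NAGTNTTAC
    assert _count_mismatches("TAGTGTTAC", "NAGTNTTAC") == 0
    assert _count_mismatches("AGGTCTTAC", "NAGTNTTAC") == 1
    assert _count_mismatches("AAAAATTAC", "NAGTNTTAC") == 2


def test_planted_nonanucleotide_matches_exhaustive_scan():
    rng = np.random.default_rng(23)
    seq = list("".join(rng.choice(list("CG"), size=500)))  # no A/T noise
    seq[123:132] = "CAGTATTAC"
    g = CircularGenome("p", "".join(seq))
    hits = st.find_nonanucleotide(g, max_mismatch=0)
    assert hits and hits[0].position.start == 123 and hits[0].mismatches == 0
    # exhaustive oracle over all 2L 9-mers
    L = g.length
    oracle = set()
    for strand, s in (("+", g.seq), ("-", revcomp(g.seq))):
        doubled = s + s
        for p in range(L):
            if _count_mismatches(doubled[p : p + 9], "NAGTNTTAC") == 0:
                start = p if strand == "+" else (L - p - 9) % L
                oracle.add((start, strand))
    assert {(h.position.start, h.position.strand) for h in hits} == oracle


def test_nonanucleotide_scan_equals_oracle_on_random_circles():
    rng = np.random.default_rng(29)
    for _ in range(5):
        L = int(rng.integers(200, 800))
        g = CircularGenome("r", "".join(rng.choice(list("ACGT"), size=L)))
        hits = st.find_nonanucleotide(g, max_mismatch=2)
        oracle = set()
        for strand, s in (("+", g.seq), ("-", revcomp(g.seq))):
            doubled = s + s
            for p in range(L):
                if _count_mismatches(doubled[p : p + 9], "NAGTNTTAC") <= 2:
                    start = p if strand == "+" else (L - p - 9) % L
                    oracle.add((start, strand))
        assert {(h.position.start, h.position.strand) for h in hits} == oracle


# ---------------------------------------------------------------------------
# stem-loop


def test_perfect_hairpin_recovered():
    arm = "GGGCCAGT"
    loop = "TAGTATTAC"
    rng = np.random.default_rng(31)
    flank = "".join(rng.choice(list("ACGT"), size=60))
    seq = flank + arm + loop + revcomp(arm) + flank
    g = CircularGenome("h", seq)
    hits = st.find_nonanucleotide(g, max_mismatch=0)
    sl = st.predict_stem_loop(g, hits[0], min_stem=5, max_stem=8)
    assert sl is not None and sl.stem_len == 8
    assert sl.loop.contains(hits[0].position.start, g.length)


def test_no_stem_loop_in_incompatible_flanks():
    # A-only flanks cannot base-pair with themselves (revcomp is T-only)
    seq = "A" * 40 + "TAGTATTAC" + "A" * 40
    g = CircularGenome("n", seq)
    hits = st.find_nonanucleotide(g, max_mismatch=0)
    assert st.predict_stem_loop(g, hits[0]) is None


def test_planted_stems_recovered_on_scaffolds(scaffolds):
    recovered = 0
    for g, truth in scaffolds:
        planted = [
            h for h in st.find_nonanucleotide(g)
            if h.position.start == truth["nonanucleotide"]["start"]
            and h.position.strand == "+"
        ]
        sl = st.predict_stem_loop(g, planted[0])
        if sl is not None and sl.stem_len >= truth["stem_len"]:
            recovered += 1
    assert recovered == len(scaffolds)


# ---------------------------------------------------------------------------
# Rep motifs: regression against the reported study feature table


WALKER_A_CORE = {
    "SRGNWGKT": "GNWGKT", "PTGNIGKS": "GNIGKS", "ETGNRGKS": "GNRGKS",
    "RVGGRGKT": "GGRGKT", "ETGNVGKS": "GNVGKS", "VRGGHGKT": "GGHGKT",
    "GGGHGKT": "GGHGKT", "VGGAHGKT": "GAHGKT",
}


@pytest.fixture(scope="module")
def study_features():
    return studydata.feature_table()


def embed_motifs(row, rng):
    filler = lambda n: "".join(rng.choice(list("AESRGD"), size=n))
    return (
        "M" + filler(30) + row["RCR-I"] + row["RCR-II"] + filler(20)
        + row["RCR-III"] + filler(25) + row["Walker-A"] + filler(15)
        + row["Walker-B"] + filler(10) + row["Walker-C"] + filler(8)
    )


def test_default_patterns_match_all_reported_motif_rows(study_features):
    rng = np.random.default_rng(0)
    for _, row in study_features.iterrows():
        prot = embed_motifs(row, rng)
        hits = {h.name: h.matched for h in scan_rep_motifs(prot)}
        assert hits["RCR-I"] == row["RCR-I"], row["virus"]
        assert hits["RCR-II"] == row["RCR-II"], row["virus"]
        assert hits["RCR-III"] == row["RCR-III"], row["virus"]
        assert hits["Walker-A"] == WALKER_A_CORE[row["Walker-A"]], row["virus"]
        assert hits["Walker-B"] == row["Walker-B"], row["virus"]
        assert hits["Walker-C"] == row["Walker-C"], row["virus"]
        # ordering invariant along the protein
        ordered = [h for h in scan_rep_motifs(prot)]
        assert [h.name for h in ordered] == MOTIF_ORDER
        assert all(
            a.aa_start < b.aa_start for a, b in zip(ordered, ordered[1:])
        )


def test_walker_b_first_residue_distinguishes_the_unisense_genome(study_features):
    rng = np.random.default_rng(1)
    first = {}
    for _, row in study_features.iterrows():
        hits = {h.name: h.matched for h in scan_rep_motifs(embed_motifs(row, rng))}
        first[row["virus"]] = hits["Walker-B"][0]
    assert first["PkSmV1-ZM09-64"] == "L"
    others = {v for k, v in first.items() if k != "PkSmV1-ZM09-64"}
    assert others <= {"I", "V", "W"}


def test_rcr_i_length_rule(study_features):
    rng = np.random.default_rng(2)
    for _, row in study_features.iterrows():
        hits = {h.name: h.matched for h in scan_rep_motifs(embed_motifs(row, rng))}
        expected = 6 if row["virus"] == "PkSmV1-ZM09-64" else 5
        assert len(hits["RCR-I"]) == expected, row["virus"]


def test_scan_rejects_empty_protein():
    with pytest.raises(ValueError):
        scan_rep_motifs("")


# ---------------------------------------------------------------------------
# designation, organization, full annotation


def test_designation_prefers_motif_bearing_orf():
    from smacotype.annotate import OrfAnnotation

    iv1 = make_interval(0, 33, 200, "+")
    iv2 = make_interval(50, 45, 200, "+")
    a = OrfAnnotation(iv1, 10, "MHWQAAAGAA")  # carries an RCR-II hit
    b = OrfAnnotation(iv2, 14, "M" + "A" * 13)
    rep, cp = st.designate_rep_cp([a, b])
    assert rep.protein == a.protein and rep.product == "Rep"
    assert cp.product == "CP"


def test_organization_typing_and_strand_flip_symmetry():
    from smacotype.annotate import OrfAnnotation

    def orf(strand):
        return OrfAnnotation(make_interval(0, 33, 100, strand), 10, "M" * 10)

    assert st.classify_organization(orf("+"), orf("-")) == "IV"
    assert st.classify_organization(orf("+"), orf("+")) == "V"
    assert st.classify_organization(orf("-"), orf("-")) == "V"
    # flipping every strand preserves the type
    assert st.classify_organization(orf("-"), orf("+")) == "IV"


def test_annotate_genome_recovers_scaffold_truth(scaffolds):
    for g, truth in scaffolds:
        ann = st.annotate_genome(g)
        assert ann.organization == truth["organization"]
        assert ann.rep.length_aa == truth["rep_len_aa"]
        assert ann.cp.length_aa == truth["cp_len_aa"]
        assert ann.nonanucleotide.position.start == truth["nonanucleotide"]["start"]
        assert ann.nonanucleotide.matched == truth["nonanucleotide_seq"]
        assert ann.stem_loop is not None
        names = [h.name for h in ann.rep_motifs]
        assert names == MOTIF_ORDER


# ---------------------------------------------------------------------------
# annotation output


def test_gff3_coordinates_and_wrapping_parts(tmp_path, scaffolds):
    from smacotype.annotate import GenomeAnnotation, OrfAnnotation

    ann = GenomeAnnotation(genome_id="g", genome_length=2500)
    ann.orfs = [
        OrfAnnotation(make_interval(0, 9, 2500, "+"), 2, "MA"),
        OrfAnnotation(make_interval(2490, 40, 2500, "+"), 12, "M" * 12),
    ]
    p = tmp_path / "out.gff3"
    write_annotation_table([ann], p, "gff3")
    text = p.read_text()
    lines = [l for l in text.splitlines() if "\tCDS\t" in l]
    # plain feature: 1-based inclusive
    assert "\t1\t9\t" in lines[0]
    # wrapping feature: two parts sharing an ID
    assert "\t2491\t2500\t" in lines[1] and "\t1\t30\t" in lines[2]
    id1 = lines[1].split("ID=")[1].split(";")[0]
    id2 = lines[2].split("ID=")[1].split(";")[0]
    assert id1 == id2


def test_feature_tsv_mirrors_reported_columns(tmp_path, scaffolds):
    g, truth = scaffolds[0]
    ann = st.annotate_genome(g)
    p = tmp_path / "tab.tsv"
    write_annotation_table([ann], p, "tsv")
    df = pd.read_csv(p, sep="\t")
    row = df.iloc[0]
    assert row["rep_aa"] == truth["rep_len_aa"]
    assert row["cp_aa"] == truth["cp_len_aa"]
    assert row["nonanucleotide"] == truth["nonanucleotide_seq"]
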