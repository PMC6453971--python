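"""TN93 distances, neighbor joining, normalized Robinson-Foulds."""

import math
import random

import dendropy
import numpy as np
import pytest

import smacotype as st
from smacotype.phylo import DistanceMatrix, MultipleAlignment, UnrootedTree


# ---------------------------------------------------------------------------
# TN93


def test_identical_rows_have_zero_distance():
    res = st.tn93_distance("ACGTACGT", "ACGTACGT")
    assert res.d == 0.0 and not res.saturated


def build_jc_pair(p=0.30, L=1000):
    """Two rows with exactly P1=P2=p/6 and Q=2p/3, symmetric substitutions
    so pooled base frequencies stay equal — the JC69 limit of TN93."""
    base = "ACGT" * (L // 4)
    r2 = list(base)
    used = {b: [i for i, c in enumerate(base) if c == b] for b in "ACGT"}
    n = int(p * L) // 12  # 25 per directed substitution type at defaults

    def sub(frm, to, k):
        for i in used[frm][:k]:
            r2[i] = to
        used[frm] = used[frm][k:]

    for frm, to in [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                    ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
                    ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]:
        sub(frm, to, n)
    return base, "".join(r2)


def test_tn93_reduces_to_jc69_in_the_equal_rate_limit():
    p = 0.30
    r1, r2 = build_jc_pair(p)
    res = st.tn93_distance(r1, r2)
    jc = -0.75 * math.log(1 - 4 * p / 3)
    assert abs(res.d - jc) < 1e-9
    assert res.P1 == pytest.approx(p / 6) and res.Q == pytest.approx(2 * p / 3)


def test_tn93_pure_transition_pair_matches_direct_formula():
    # 100 nt with exactly 10 A<->G transitions and nothing else
    r1 = ("ACGT" * 25)
    r2 = list(r1)
    a_sites = [i for i, c in enumerate(r1) if c == "A"][:5]
    g_sites = [i for i, c in enumerate(r1) if c == "G"][:5]
    for i in a_sites:
        r2[i] = "G"
    for i in g_sites:
        r2[i] = "A"
    r2 = "".join(r2)
    res = st.tn93_distance(r1, r2)
    # independent evaluation with hand-counted proportions
    P1, Q = 0.10, 0.0
    gA = gC = gG = gT = 0.25
    gR, gY = 0.5, 0.5
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    expected = -k1 * math.log(1 - P1 / k1) - 0.0 - 0.0
    assert res.P1 == pytest.approx(P1) and res.Q == 0.0
    assert res.d == pytest.approx(expected, abs=1e-12)


def test_pairwise_deletion_of_gap_and_n_columns():
    full = st.tn93_distance("ACGTACGT", "ACGAACGT")
    padded = st.tn93_distance("ACGTACGTNN--", "ACGAACGTAC-T")
    assert padded.d == pytest.approx(full.d)
    assert padded.n_sites == 8


def test_saturation_returns_ceiling_with_flag():
    res = st.tn93_distance("A" * 50 + "C" * 50, "G" * 50 + "T" * 50, ceiling=5.0)
    assert res.saturated and res.d == 5.0


def test_no_comparable_columns_raises():
    with pytest.raises(ValueError):
        st.tn93_distance("NNNN", "ACGT")


def test_tn93_nondecreasing_in_planted_substitutions():
    rng = np.random.default_rng(2)
    base = "".join(rng.choice(list("ACGT"), size=2000))
    row = list(base)
    prev = 0.0
    order = rng.permutation(2000)
    k = 0
    for step in range(10):
        for _ in range(30):
            p = order[k]; k += 1
            row[p] = rng.choice([c for c in "ACGT" if c != row[p]])
        d = st.tn93_distance(base, "".join(row)).d
        assert d >= prev - 1e-9
        prev = d


# ---------------------------------------------------------------------------
# neighbor joining


def test_three_taxon_closed_form():
    D = DistanceMatrix(("A", "B", "C"),
                       np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]))
    t = st.nj_tree(D)
    lengths = {c.label: bl for c, bl in t.root.children}
    assert lengths == {
        "A": pytest.approx(0.05), "B": pytest.approx(0.15),
        "C": pytest.approx(0.25),
    }


def test_four_taxon_additive_matrix_recovered_exactly():
    # tree ((A:1,B:2):1,(C:3,D:4))
    d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
    t = st.nj_tree(DistanceMatrix(("A", "B", "C", "D"), d))
    assert t.nontrivial_splits() == frozenset({frozenset({"A", "B"})})
    ref = UnrootedTree.from_newick("((A:1,B:2):1,(C:3,D:4):0);")
    assert st.normalized_rf(t, ref) == 0.0
    # leaf branch lengths recovered
    def leaf_lengths(node, acc):
        for c, bl in node.children:
            if c.children:
                leaf_lengths(c, acc)
            else:
                acc[c.label] = bl
        return acc

    ll = leaf_lengths(t.root, {})
    assert ll["A"] == pytest.approx(1.0) and ll["B"] == pytest.approx(2.0)
    assert ll["C"] == pytest.approx(3.0) and ll["D"] == pytest.approx(4.0)


def test_tie_case_is_deterministic():
    d = np.ones((5, 5)) - np.eye(5)
    labels = tuple("ABCDE")
    t1 = st.nj_tree(DistanceMatrix(labels, d))
    t2 = st.nj_tree(DistanceMatrix(labels, d))
    assert t1.to_newick() == t2.to_newick()


def random_additive_case(n, seed):
    r = random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        1.0, 0.2, num_extant_tips=n, rng=r
    )
    labels = [f"T{i}" for i in range(n)]
    for i, lf in enumerate(tree.leaf_node_iter()):
        lf.taxon.label = labels[i]
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = pdm.distance(tx[labels[i]], tx[labels[j]])
    return tree, DistanceMatrix(tuple(labels), d)


def test_nj_recovers_random_additive_trees():
    rng = np.random.default_rng(33)
    for k in range(20):
        n = int(rng.integers(5, 9))
        ref_tree, D = random_additive_case(n, 1000 + k)
        nj = st.nj_tree(D)
        ref = UnrootedTree.from_newick(
            ref_tree.as_string(schema="newick").replace("[&R] ", "")
        )
        assert st.normalized_rf(nj, ref) == 0.0


def test_nj_topology_agrees_with_dendropy_on_noisy_matrices():
    """Independent oracle: dendropy's NJ on generic (tie-free) matrices."""
    rng = np.random.default_rng(44)
    for _ in range(10):
        n = int(rng.integers(5, 8))
        _, D = random_additive_case(n, int(rng.integers(1 << 30)))
        d = D.d + rng.uniform(0, 0.05, size=D.d.shape)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        mine = st.nj_tree(DistanceMatrix(D.labels, d))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_pdm_csv(D.labels, d), delimiter=","
        )
        ref = UnrootedTree.from_newick(
            pdm.nj_tree().as_string(schema="newick").replace("[&U] ", "")
        )
        assert st.normalized_rf(mine, ref) == 0.0


def _pdm_csv(labels, d):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for lab, row in zip(labels, d):
        buf.write(lab + "," + ",".join(str(x) for x in row) + "\n")
    buf.seek(0)
    return buf


def test_nj_requires_three_taxa_and_finite_distances():
    with pytest.raises(ValueError):
        st.nj_tree(DistanceMatrix(("A", "B"), np.zeros((2, 2))))
    bad = np.array([[0, np.inf], [np.inf, 0]])
    with pytest.raises(ValueError):
        st.nj_tree(DistanceMatrix(("A", "B"), bad))


# ---------------------------------------------------------------------------
# normalized RF


def _random_binary_tree(labels, rng):
    r = random.Random(int(rng.integers(1 << 30)))
    t = dendropy.simulate.treesim.birth_death_tree(
        1.0, 0.0, num_extant_tips=len(labels), rng=r
    )
    for i, lf in enumerate(t.leaf_node_iter()):
        lf.taxon.label = labels[i]
    return t


def test_identical_topologies_have_rf_zero():
    rng = np.random.default_rng(55)
    labels = [f"T{i}" for i in range(6)]
    t = _random_binary_tree(labels, rng)
    nwk = t.as_string(schema="newick").replace("[&R] ", "")
    assert st.normalized_rf(
        UnrootedTree.from_newick(nwk), UnrootedTree.from_newick(nwk)
    ) == 0.0


def test_conflicting_quartets_have_rf_one():
    t1 = UnrootedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = UnrootedTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
    assert st.normalized_rf(t1, t2) == 1.0


def test_leaf_set_mismatch_rejected():
    t1 = UnrootedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = UnrootedTree.from_newick("((A:1,B:1):1,(C:1,E:1):1);")
    with pytest.raises(ValueError):
        st.normalized_rf(t1, t2)


def test_normalized_rf_matches_dendropy_split_oracle():
    rng = np.random.default_rng(66)
    labels = [f"T{i}" for i in range(6)]
    tns = dendropy.TaxonNamespace(labels)
    for _ in range(50):
        d1 = _random_binary_tree(labels, rng)
        d2 = _random_binary_tree(labels, rng)
        n1 = d1.as_string(schema="newick").replace("[&R] ", "")
        n2 = d2.as_string(schema="newick").replace("[&R] ", "")
        mine = st.normalized_rf(
            UnrootedTree.from_newick(n1), UnrootedTree.from_newick(n2)
        )
        e1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=tns)
        e2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=tns)
        e1.encode_bipartitions(); e2.encode_bipartitions()
        sd = dendropy.calculate.treecompare.symmetric_difference(e1, e2)
        assert mine == pytest.approx(sd / (2 * (6 - 3)))


def test_normalized_rf_is_a_metric_on_seeded_triples():
    rng = np.random.default_rng(77)
    labels = [f"T{i}" for i in range(7)]
    for _ in range(25):
        trees = [
            UnrootedTree.from_newick(
                _random_binary_tree(labels, rng).as_string(schema="newick").replace("[&R] ", "")
            )
            for _ in range(3)
        ]
        a, b, c = trees
        dab, dba = st.normalized_rf(a, b), st.normalized_rf(b, a)
        assert dab == dba
        assert 0.0 <= dab <= 1.0
        assert st.normalized_rf(a, c) <= dab + st.normalized_rf(b, c) + 1e-12


def test_zero_length_internal_edges_collapse():
    collapsed = UnrootedTree.from_newick("((A:1,B:1):0.0,(C:1,D:1):1,E:1);")
    resolved = UnrootedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
    # splits are canonicalized as the side holding the smallest leaf label
    assert collapsed.nontrivial_splits() == frozenset({frozenset({"A", "B", "E"})})
    assert len(resolved.nontrivial_splits()) == 2
    # realized-split normalization: symmetric difference {A,B} over 1+2
    assert st.normalized_rf(collapsed, resolved) == pytest.approx(1 / 3)


def test_alignment_container_validation():
    with pytest.raises(ValueError):
        MultipleAlignment(("a", "b"), ("ACGT", "ACG"))
    with pytest.raises(ValueError):
        MultipleAlignment(("a", "a"), ("ACGT", "ACGT"))
    aln = MultipleAlignment(("a", "b"), ("ACGT-", "ACGTN"))
    assert aln.length == 5 and aln.window(1, 3).rows == ("CG", "CG")
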