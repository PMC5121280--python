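import dendropy
import numpy as np
import pytest

from famsynt.msa import align_pair, progressive_align
from famsynt.phylogeny import (
    DistanceMatrix,
    assign_subfamilies,
    bootstrap,
    build_nj,
    pairwise_distance,
    poisson_correct,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def splits(tree):
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(leaves) - 1:
            out.add(min(side, leaves - side, key=lambda s: (len(s), sorted(s))))
    return out


# ---------------------------------------------------------------------------
# distances


@pytest.mark.parametrize("p,expected", [(0.0, 0.0), (0.1, 0.105360516), (0.5, 0.693147181)])
def test_poisson_correction_closed_form(p, expected):
    assert poisson_correct(p) == pytest.approx(expected, abs=1e-9)


def test_identical_sequences_have_zero_distance():
    dm = pairwise_distance({"a": "MKLV", "b": "MKLV"})
    assert dm.p[0, 1] == 0.0 and dm.d[0, 1] == 0.0


def test_pairwise_deletion_hand_count():
    # compared sites are {1, 4}; both match, so p = 0
    dm = pairwise_distance({"x": "AC-A", "y": "A-GA"})
    assert dm.p[0, 1] == 0.0
    # one mismatch out of two compared sites
    dm2 = pairwise_distance({"x": "AC-A", "y": "T-GA"})
    assert dm2.p[0, 1] == pytest.approx(0.5)
    assert dm2.d[0, 1] == pytest.approx(-np.log(0.5))


def test_no_comparable_sites_is_error_in_strict_mode():
    aln = {"x": "AA--", "y": "--TT"}
    with pytest.raises(ValueError, match="comparable"):
        pairwise_distance(aln, strict=True)
    dm = pairwise_distance(aln, strict=False)
    assert not np.isfinite(dm.d[0, 1])
    assert dm.undefined_pairs() == [("x", "y")]


def test_distances_are_permutation_equivariant():
    rng = np.random.default_rng(3)
    seqs = {
        f"s{i}": "".join(AA[j] for j in rng.integers(0, 20, 80)) for i in range(5)
    }
    dm = pairwise_distance(seqs)
    order = ["s3", "s0", "s4", "s2", "s1"]
    dm2 = pairwise_distance({k: seqs[k] for k in order})
    perm = [dm.taxa.index(t) for t in order]
    assert np.allclose(dm2.d, dm.d[np.ix_(perm, perm)])


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_three_taxa_closed_form_branch_lengths():
    D = np.array([[0, 5, 7], [5, 0, 8], [7, 8, 0]], dtype=float)
    dm = DistanceMatrix(taxa=["A", "B", "C"], p=D, d=D)
    tree = build_nj(dm)
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx(2.0)
    assert lengths["B"] == pytest.approx(3.0)
    assert lengths["C"] == pytest.approx(5.0)


def test_nj_ultrametric_tie_broken_lexicographically():
    # ((A,B),(C,D)) pattern with symmetric distances: Q ties between the two
    # cherries; the lexicographically smallest pair (A,B) must join first,
    # and the resulting split set is the correct one either way
    D = np.array(
        [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], dtype=float
    )
    dm = DistanceMatrix(taxa=["A", "B", "C", "D"], p=D, d=D)
    tree = build_nj(dm)
    assert splits(tree) == {frozenset({"A", "B"})} or splits(tree) == {frozenset({"C", "D"})}
    # the first join is (A, B): its pendant edges carry length 1 each
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx(1.0)


def test_nj_recovers_random_additive_trees_exactly():
    rng = np.random.default_rng(12)
    for _ in range(10):
        n = int(rng.integers(4, 7))
        taxa = [chr(65 + i) for i in range(n)]
        tns = dendropy.TaxonNamespace(taxa)
        import random as pyrandom

        true = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n, taxon_namespace=tns,
            rng=pyrandom.Random(int(rng.integers(1e6))),
        )
        for edge in true.preorder_edge_iter():
            edge.length = float(rng.uniform(0.1, 1.0))
        pdm = true.phylogenetic_distance_matrix()
        D = np.zeros((n, n))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i != j:
                    D[i, j] = pdm.distance(tns.get_taxon(a), tns.get_taxon(b))
        nj = build_nj(DistanceMatrix(taxa=taxa, p=D.copy(), d=D.copy()))
        true.is_rooted = False
        assert splits(nj) == splits(true)


def test_nj_missing_distance_errors_with_pair_name():
    D = np.zeros((3, 3))
    D[0, 1] = D[1, 0] = np.inf
    dm = DistanceMatrix(taxa=["A", "B", "C"], p=D, d=D)
    with pytest.raises(ValueError, match="A.*B"):
        build_nj(dm)


# ---------------------------------------------------------------------------
# bootstrap and subfamilies


def _two_clade_alignment(seed=0, n_per=4, L=200, clade_div=0.5, noise=0.03):
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 20, L)
    other = base.copy()
    flip = rng.random(L) < clade_div
    other[flip] = rng.integers(0, 20, flip.sum())
    aln = {}
    for name, anc in (("a", base), ("b", other)):
        for i in range(n_per):
            s = anc.copy()
            mut = rng.random(L) < noise
            s[mut] = rng.integers(0, 20, mut.sum())
            aln[f"{name}{i}"] = "".join(AA[x] for x in s)
    return aln


def test_bootstrap_deterministic_given_seed():
    aln = _two_clade_alignment()
    t1 = bootstrap(aln, n_reps=50, seed=9)
    t2 = bootstrap(aln, n_reps=50, seed=9)
    s1 = sorted(e.support for e in t1.preorder_edge_iter() if hasattr(e, "support"))
    s2 = sorted(e.support for e in t2.preorder_edge_iter() if hasattr(e, "support"))
    assert s1 == s2 and len(s1) > 0


def test_clear_two_clade_split_gets_high_support():
    aln = _two_clade_alignment(seed=1)
    tree = bootstrap(aln, n_reps=200, seed=0)
    clade_a = frozenset({"a0", "a1", "a2", "a3"})
    supports = {
        frozenset(l.taxon.label for l in e.head_node.leaf_iter()): e.support
        for e in tree.preorder_edge_iter()
        if hasattr(e, "support")
    }
    matching = [s for side, s in supports.items() if side in (clade_a, frozenset(aln) - clade_a)]
    assert matching and matching[0] >= 190


def test_identical_sequences_give_full_support_everywhere():
    aln = {f"s{i}": "MKLVWAAR" * 10 for i in range(5)}
    tree = bootstrap(aln, n_reps=25, seed=0)
    supports = [e.support for e in tree.preorder_edge_iter() if hasattr(e, "support")]
    assert all(s == 25 for s in supports)


def test_bootstrap_support_distribution_stable_under_column_shuffle():
    aln = _two_clade_alignment(seed=2)
    tree1 = bootstrap(aln, n_reps=100, seed=5)
    rng = np.random.default_rng(7)
    order = rng.permutation(len(next(iter(aln.values()))))
    shuffled = {k: "".join(v[i] for i in order) for k, v in aln.items()}
    tree2 = bootstrap(shuffled, n_reps=100, seed=5)
    s1 = sorted(e.support for e in tree1.preorder_edge_iter() if hasattr(e, "support"))
    s2 = sorted(e.support for e in tree2.preorder_edge_iter() if hasattr(e, "support"))
    assert np.abs(np.array(s1) - np.array(s2)).max() <= 15  # sampling noise only


def test_assign_subfamilies_k1_and_k2():
    aln = _two_clade_alignment(seed=3)
    tree = bootstrap(aln, n_reps=100, seed=1)
    assert set(assign_subfamilies(tree, k=1).values()) == {"I"}
    sub = assign_subfamilies(tree, k=2, min_support=50)
    groups = {}
    for m, s in sub.items():
        groups.setdefault(s, set()).add(m)
    assert {frozenset(g) for g in groups.values()} == {
        frozenset({"a0", "a1", "a2", "a3"}), frozenset({"b0", "b1", "b2", "b3"})
    }


def test_assign_subfamilies_errors_when_supports_insufficient():
    aln = _two_clade_alignment(seed=4)
    tree = bootstrap(aln, n_reps=10, seed=1)
    with pytest.raises(ValueError, match="min_support"):
        assign_subfamilies(tree, k=8, min_support=11)


# ---------------------------------------------------------------------------
# the progressive aligner that feeds the distances


def test_align_pair_recovers_single_indel():
    a, b = align_pair("MKLVINSPQR", "MKLINSPQR")
    assert a == "MKLVINSPQR"
    assert b == "MKL-INSPQR"


def test_progressive_alignment_ungaps_back_to_inputs():
    rng = np.random.default_rng(5)
    seqs = {}
    base = rng.integers(0, 20, 120)
    for i in range(6):
        s = base.copy()
        mut = rng.random(120) < 0.1
        s[mut] = rng.integers(0, 20, mut.sum())
        seq = "".join(AA[x] for x in s)
        if i % 2:
            seq = seq[:50] + seq[55:]  # deletion in half the sequences
        seqs[f"s{i}"] = seq
    aln = progressive_align(seqs)
    L = {len(v) for v in aln.values()}
    assert len(L) == 1
    for k, v in aln.items():
        assert v.replace("-", "") == seqs[k]
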