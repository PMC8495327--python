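import numpy as np
import pytest

from skimploid._seq import decode, mutate_jc, random_seq_arr
from skimploid.kmers import KmerProfile, profile_from_sequence
from skimploid.phylo import (
    aaf_distance,
    bootstrap_supports,
    classify_polyploid_topology,
    distance_matrix,
    global_identity,
    identity_tree,
    infer_maternal_parent,
    neighbor_joining,
    scale_tree_ages,
)
from skimploid.trees import Tree, robinson_foulds


def random_profile(rng, n=500, k=21, label=""):
    codes = np.unique(rng.integers(0, 4 ** k, n).astype(np.uint64))
    return KmerProfile(k=k, codes=np.sort(codes),
                       counts=np.ones(codes.size, dtype=np.int64), label=label)


# -------------------------------------------------------------- aaf_distance

def test_identical_profiles_distance_zero(rng):
    p = random_profile(rng)
    assert aaf_distance(p, p) == 0.0


def test_disjoint_profiles_capped(rng):
    a = KmerProfile(21, np.array([1, 2, 3], dtype=np.uint64),
                    np.ones(3, dtype=np.int64))
    b = KmerProfile(21, np.array([10, 11], dtype=np.uint64),
                    np.ones(2, dtype=np.int64))
    assert aaf_distance(a, b) == 1.0
    assert aaf_distance(a, b, d_cap=0.5) == 0.5


def test_k_mismatch_and_empty_profile_errors(rng):
    a = random_profile(rng, k=21)
    b = random_profile(rng, k=19)
    with pytest.raises(ValueError, match="k mismatch"):
        aaf_distance(a, b)
    empty = KmerProfile(21, np.empty(0, dtype=np.uint64),
                        np.empty(0, dtype=np.int64))
    with pytest.raises(ValueError, match="empty"):
        aaf_distance(a, empty)


def test_symmetric_premetric(rng):
    a, b = random_profile(rng, 400), random_profile(rng, 600)
    assert aaf_distance(a, b) == aaf_distance(b, a) >= 0


def test_distance_recovers_jc_divergence(rng):
    # oracle: the realized per-site substitution fraction
    root = random_seq_arr(rng, 50_000)
    other = mutate_jc(root, 0.05, rng)
    observed = float(np.mean(root != other))
    pa = profile_from_sequence(root, k=21)
    pb = profile_from_sequence(other, k=21)
    d = aaf_distance(pa, pb)
    assert d == pytest.approx(observed, rel=0.12)
    assert 0.045 <= d <= 0.055


def test_monotonicity_in_divergence(rng):
    root = random_seq_arr(rng, 50_000)
    pa = profile_from_sequence(root, k=21)
    dists = []
    for d in (0.01, 0.02, 0.05, 0.1):
        pb = profile_from_sequence(mutate_jc(root, d, rng), k=21)
        dists.append(aaf_distance(pa, pb))
    assert dists == sorted(dists)
    assert len(set(dists)) == len(dists)


# ---------------------------------------------------------- neighbor joining

def test_nj_three_taxa_closed_form():
    D = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
    t = neighbor_joining(D, ["A", "B", "C"])
    dists = t.leaf_distances()
    # branch to A = (dAB + dAC - dBC)/2 = 1; B = 2; C = 3
    assert dists["A"]["B"] == pytest.approx(3.0)
    assert dists["A"]["C"] == pytest.approx(4.0)
    assert dists["B"]["C"] == pytest.approx(5.0)


def test_nj_recovers_quartet_with_exact_lengths():
    # ((A,B),(C,D)) with all branches 1: D_AB = D_CD = 2, others 3
    D = np.array([
        [0, 2, 3, 3],
        [2, 0, 3, 3],
        [3, 3, 0, 2],
        [3, 3, 2, 0],
    ], dtype=float)
    t = neighbor_joining(D, ["A", "B", "C", "D"])
    assert t.bipartitions() == {frozenset({"C", "D"})}
    dists = t.leaf_distances()
    for (a, b), expect in {("A", "B"): 2, ("C", "D"): 2, ("A", "C"): 3,
                           ("A", "D"): 3, ("B", "C"): 3, ("B", "D"): 3}.items():
        assert dists[a][b] == pytest.approx(expect)


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError, match=">= 3"):
        neighbor_joining(np.zeros((2, 2)), ["A", "B"])


def random_additive_tree(rng, n):
    """Random topology + branch lengths; returns (tree, D, labels)."""
    labels = [chr(ord("A") + i) for i in range(n)]
    nwk = f"({labels[0]}:1,{labels[1]}:1,{labels[2]}:1);"
    t = Tree.from_newick(nwk)
    from skimploid.trees import Node

    for lab in labels[3:]:
        edges = [x for x in t.root.preorder() if x.parent is not None]
        target = edges[rng.integers(0, len(edges))]
        parent = target.parent
        mid = Node(length=float(rng.uniform(0.1, 1)))
        leaf = Node(label=lab, length=float(rng.uniform(0.1, 1)))
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        target.length = float(rng.uniform(0.1, 1))
        mid.add(target)
        mid.add(leaf)
    for node in t.root.preorder():
        if node.parent is not None and node.length == 1:
            node.length = float(rng.uniform(0.1, 1))
    dd = t.leaf_distances()
    D = np.array([[dd[a][b] for b in labels] for a in labels])
    return t, D, labels


def test_nj_consistent_on_additive_matrices(rng):
    for _ in range(20):
        true, D, labels = random_additive_tree(rng, 8)
        est = neighbor_joining(D, labels)
        assert robinson_foulds(true, est) == 0


# ------------------------------------------------------------- bootstrapping

def test_bootstrap_identical_replicates_full_support(rng):
    root = random_seq_arr(rng, 5000)
    anc2 = mutate_jc(root, 0.06, rng)
    profiles = {}
    for lab, anc, d in [("A", root, 0.002), ("B", root, 0.003),
                        ("C", anc2, 0.002), ("D", anc2, 0.003)]:
        profiles[lab] = profile_from_sequence(mutate_jc(anc, d, rng), k=21,
                                              label=lab)
    t1 = bootstrap_supports(profiles, B=20, seed=5)
    t2 = bootstrap_supports(profiles, B=20, seed=5)
    sup1 = sorted(n.support for n in t1.root.preorder()
                  if n.support is not None)
    sup2 = sorted(n.support for n in t2.root.preorder()
                  if n.support is not None)
    assert sup1 == sup2  # determinism under the same seed
    assert all(s >= 95 for s in sup1)  # well-separated clades


# -------------------------------------------------------- identity distances

def test_global_identity_identical():
    assert global_identity("ACGT" * 250, "ACGT" * 250) == 100.0


def test_global_identity_single_substitution(rng):
    s = "".join(rng.choice(list("ACGT"), 1000))
    s2 = s[:500] + ("A" if s[500] != "A" else "C") + s[501:]
    assert global_identity(s, s2) == pytest.approx(99.9, abs=1e-6)


def test_global_identity_five_bp_deletion(rng):
    s = "".join(rng.choice(list("ACGT"), 1000))
    s2 = s[:400] + s[405:]
    assert global_identity(s, s2) == pytest.approx(99.5, abs=0.05)


def test_identity_tree_star_for_identical(rng):
    s = "".join(rng.choice(list("ACGT"), 500))
    t = identity_tree({"A": s, "B": s, "C": s})
    for node in t.root.preorder():
        assert node.length == 0


def test_identity_tree_recovers_topology(rng):
    nwk = "((A:0.02,B:0.02)ab:0.02,(C:0.02,D:0.02)cd:0.02,E:0.05);"
    true = Tree.from_newick(nwk)
    root = random_seq_arr(rng, 8000)

    seqs = {}

    def walk(node, arr):
        child_arr = mutate_jc(arr, node.length, rng)
        if node.is_leaf:
            seqs[node.label] = decode(child_arr)
        for c in node.children:
            walk(c, child_arr)

    for c in Tree.from_newick(nwk).root.children:
        walk(c, root)
    t = identity_tree(seqs)
    assert robinson_foulds(true, t) == 0


def test_identity_tree_matches_aaf_topology(rng):
    # cross-method congruence on the same hierarchically evolved sequences
    root = random_seq_arr(rng, 8000)
    anc_ab = mutate_jc(root, 0.02, rng)
    anc_cd = mutate_jc(root, 0.025, rng)
    seqs = {
        "A": decode(mutate_jc(anc_ab, 0.008, rng)),
        "B": decode(mutate_jc(anc_ab, 0.01, rng)),
        "C": decode(mutate_jc(anc_cd, 0.009, rng)),
        "D": decode(mutate_jc(anc_cd, 0.012, rng)),
        "E": decode(mutate_jc(root, 0.06, rng)),
    }
    profiles = {lab: profile_from_sequence(s, k=21, label=lab)
                for lab, s in seqs.items()}
    D, labels = distance_matrix(profiles)
    aaf_tree = neighbor_joining(D, labels)
    ident_tree = identity_tree(seqs)
    assert robinson_foulds(aaf_tree, ident_tree) == 0


# ------------------------------------------------- polyploid classification

CLADE_I = {"H", "S"}
CLADE_II = {"P", "M", "V"}


def test_polyploid_sister_to_clade_i():
    t = Tree.from_newick("(O:1,((X:1,(H:1,S:1):1):1,((P:1,M:1):1,V:1):1):1);")
    assert classify_polyploid_topology(t, "X", CLADE_I, CLADE_II) == "cladeI_like"


def test_polyploid_sister_to_clade_ii():
    t = Tree.from_newick("(O:1,((H:1,S:1):1,(X:1,((P:1,M:1):1,V:1):1):1):1);")
    assert classify_polyploid_topology(t, "X", CLADE_I, CLADE_II) == "cladeII_like"


def test_polyploid_between_clades_unresolved():
    t = Tree.from_newick("((H:1,S:1):1,X:1,((P:1,M:1):1,V:1):1);")
    assert classify_polyploid_topology(t, "X", CLADE_I, CLADE_II) == "unresolved"


def test_polyploid_missing_raises():
    t = Tree.from_newick("((H:1,S:1):1,(P:1,(M:1,V:1):1):1);")
    with pytest.raises(ValueError, match="not in tree"):
        classify_polyploid_topology(t, "X", CLADE_I, CLADE_II)


# ------------------------------------------------------- maternal inference

def test_maternal_argmin():
    D = np.array([[0, 0.001, 0.05], [0.001, 0, 0.05], [0.05, 0.05, 0]])
    best, ties = infer_maternal_parent(D, ["X", "A", "B"], "X", ["A", "B"])
    assert best == "A" and ties == ["A"]


def test_maternal_tie_set():
    D = np.array([
        [0, 0.0100, 0.0102, 0.09],
        [0.0100, 0, 0.01, 0.09],
        [0.0102, 0.01, 0, 0.09],
        [0.09, 0.09, 0.09, 0],
    ])
    best, ties = infer_maternal_parent(D, ["X", "A", "A2", "B"], "X",
                                       ["A", "A2", "B"], rel_tolerance=0.05)
    assert best == "A"
    assert ties == ["A", "A2"]


def test_maternal_recovery_on_simulated_polyploids(study):
    readsets, truth, genomes = study
    from skimploid.kmers import build_profile

    profs = {}
    for s, rs in readsets.items():
        tr = truth.read_truth[s]
        idx = np.nonzero((tr["compartment"] == "chloroplast").values)[0]
        profs[s] = build_profile(rs.block().subset(idx), k=21, min_count=2,
                                 label=s)
    D, labels = distance_matrix(profs)
    diploids = [s for s in labels if s != "X1"]
    best, _ = infer_maternal_parent(D, labels, "X1", diploids)
    assert best == truth.parentage["X1"][0]


# ----------------------------------------------------------------- dating

def test_scale_tree_ages_exact_arithmetic():
    t = Tree.from_newick("((A:1,B:1)ab:1,(C:1.5,D:1.5)cd:0.5);")
    dated = scale_tree_ages(t, root_age=12.4)
    ages = {n.label: n.age for n in dated.root.preorder()}
    assert dated.root.age == pytest.approx(12.4)
    assert ages["ab"] == pytest.approx(6.2)
    assert ages["cd"] == pytest.approx(9.3)
    for leaf in "ABCD":
        assert ages[leaf] == 0.0


def test_scale_tree_ages_zero_height_rejected():
    t = Tree.from_newick("((A:0,B:0):0,(C:0,D:0):0);")
    with pytest.raises(ValueError):
        scale_tree_ages(t)


def test_scaled_relative_heights_recovered(rng):
    # distances from a known ultrametric tree -> NJ -> scaled ages
    nwk = "((A:1,B:1)ab:3,((C:2,D:2)cd:1,E:3)cde:1);"
    true = Tree.from_newick(nwk)
    dd = true.leaf_distances()
    labels = ["A", "B", "C", "D", "E"]
    D = np.array([[dd[a][b] for b in labels] for a in labels])
    est = neighbor_joining(D, labels)
    dated = scale_tree_ages(est, root_age=12.4)
    # true relative heights: root 4, ab 1, cd 2, cde 3
    got = {}
    for node in dated.root.preorder():
        if node.is_leaf:
            continue
        leaves = frozenset(n.label for n in node.leaves())
        got[leaves] = node.age
    assert got[frozenset("AB")] == pytest.approx(12.4 / 4, rel=0.1)
    assert got[frozenset("CD")] == pytest.approx(12.4 / 2, rel=0.1)
    assert got[frozenset("CDE")] == pytest.approx(12.4 * 3 / 4, rel=0.1)
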