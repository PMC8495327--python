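"""Alignment-free and alignment-based distances, neighbor-joining trees,
bootstrap supports, tree comparison, polyploid topology classification,
maternal-parent inference, and calibration-based age scaling.

The alignment-free distance between two k-mer profiles is
d = -(1/k) ln(n_s / min(n_A, n_B)) where n_s is the number of shared
distinct canonical k-mers; zero overlap is capped at d_cap.
"""

from __future__ import annotations

import numpy as np

from .kmers import KmerProfile
from .trees import Node, Tree, robinson_foulds  # noqa: F401 (re-export)

DEFAULT_D_CAP = 1.0


def aaf_distance(profile_a: KmerProfile, profile_b: KmerProfile,
                 d_cap: float = DEFAULT_D_CAP) -> float:
    """Shared-k-mer distance between two profiles (symmetric premetric)."""
    if profile_a.k != profile_b.k:
        raise ValueError(f"k mismatch: {profile_a.k} != {profile_b.k}")
    na, nb = profile_a.n_distinct, profile_b.n_distinct
    if na == 0 or nb == 0:
        raise ValueError("empty profile")
    ns = np.intersect1d(profile_a.codes, profile_b.codes,
                        assume_unique=True).size
    if ns == 0:
        return d_cap
    p = ns / min(na, nb)
    return min(float(-np.log(p) / profile_a.k), d_cap)


def distance_matrix(profiles: dict, d_cap: float = DEFAULT_D_CAP,
                    ) -> tuple[np.ndarray, list]:
    """Pairwise AAF distance matrix over labelled profiles."""
    labels = sorted(profiles)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = aaf_distance(
                profiles[labels[i]], profiles[labels[j]], d_cap=d_cap)
    return D, labels


# --------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(D: np.ndarray, labels: list) -> Tree:
    """Classical NJ with deterministic label-order tie-breaking.

    Negative branch-length estimates are clamped to zero.  The returned
    tree is unrooted, represented with a trifurcating root.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")

    nodes = [Node(label=lab) for lab in labels]
    keys = [str(lab) for lab in labels]  # smallest leaf label under node
    D = D.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = []
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    ka, kb = keys[active[a]], keys[active[b]]
                    cands.append((min(ka, kb), max(ka, kb), a, b))
        cands.sort()
        _, _, a, b = cands[0]
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        new = Node()
        nodes[i].length = li
        nodes[j].length = lj
        new.add(nodes[i])
        new.add(nodes[j])
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        newD = np.zeros((D.shape[0] + 1, D.shape[0] + 1))
        newD[:-1, :-1] = D
        for x in active:
            if x in (i, j):
                continue
            dx = 0.5 * (D[i, x] + D[j, x] - dij)
            newD[-1, x] = newD[x, -1] = max(dx, 0.0)
        D = newD
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    if len(active) == 2:
        i, j = active
        d = D[i, j]
        root = Node()
        if nodes[i].is_leaf and nodes[j].is_leaf:
            nodes[i].length = nodes[j].length = max(d / 2, 0.0)
            root.add(nodes[i])
            root.add(nodes[j])
        else:
            # hang the remaining edge below the internal node: trifurcation
            internal = nodes[j] if not nodes[j].is_leaf else nodes[i]
            other = nodes[i] if internal is nodes[j] else nodes[j]
            other.length = max(d, 0.0)
            internal.add(other)
            root = internal
        return Tree(root)
    raise AssertionError("unreachable")


def nj_three_taxa_lengths(D: np.ndarray) -> np.ndarray:
    """Closed-form branch lengths for three taxa (used as an oracle hook)."""
    a = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    b = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    c = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    return np.maximum([a, b, c], 0.0)


# --------------------------------------------------------------------------
# bootstrap


def bootstrap_supports(profiles: dict, B: int = 100, seed: int = 0,
                       d_cap: float = DEFAULT_D_CAP) -> Tree:
    """NJ tree with bipartition supports from k-mer resampling.

    Each replicate resamples every profile's distinct k-mer set with
    replacement to its original size; supports are percentages of
    replicates containing each bipartition of the full-data tree.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    D, labels = distance_matrix(profiles, d_cap=d_cap)
    main = neighbor_joining(D, labels)
    target = {bp: 0 for bp in main.bipartitions()}

    rng = np.random.default_rng(seed)
    order = sorted(profiles)
    for _ in range(B):
        rep = {}
        for lab in order:
            p = profiles[lab]
            idx = rng.integers(0, p.n_distinct, p.n_distinct)
            codes = np.unique(p.codes[idx])
            rep[lab] = KmerProfile(k=p.k, codes=codes,
                                   counts=np.ones(codes.size, dtype=np.int64),
                                   label=p.label)
        Dr, labr = distance_matrix(rep, d_cap=d_cap)
        bps = neighbor_joining(Dr, labr).bipartitions()
        for bp in target:
            if bp in bps:
                target[bp] += 1

    leaves = set(main.leaf_labels())
    ref = min(leaves)
    for node in main.root.preorder():
        if node.is_leaf or node is main.root:
            continue
        side = frozenset(n.label for n in node.leaves())
        if ref in side:
            side = frozenset(leaves - side)
        if side in target:
            node.support = 100.0 * target[side] / B
    return main


# --------------------------------------------------------------------------
# alignment-based identity


def global_identity(seq_a: str, seq_b: str, match: float = 1.0,
                    mismatch: float = -1.0, gap: float = -2.0) -> float:
    """Needleman-Wunsch global alignment identity in percent
    (matched columns / alignment length)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    if len(seq_a) == len(seq_b) and seq_a == seq_b:
        return 100.0
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / length


def _circular_identity(seq_a: str, seq_b: str) -> float:
    """Identity between two circular sequences after anchor-based rotation.

    Chooses the rotation/strand of b maximising shared 21-mer offsets,
    then scores column identity directly (global alignment fallback if
    lengths differ after rotation)."""
    from ._seq import revcomp
    from .satellites import _best_rotations

    best = 0.0
    for cand in (seq_b, revcomp(seq_b)):
        for shift in _best_rotations(seq_a, cand, k=21, n_candidates=2):
            rot = cand[shift:] + cand[:shift]
            if len(rot) == len(seq_a):
                ident = 100.0 * float(np.mean(
                    np.frombuffer(seq_a.encode(), dtype=np.uint8)
                    == np.frombuffer(rot.encode(), dtype=np.uint8)))
            else:
                ident = global_identity(seq_a, rot)
            best = max(best, ident)
    return best


def identity_distance_matrix(sequences: dict, circular: bool = False,
                             ) -> tuple[np.ndarray, list]:
    """Pairwise distances d = 1 - identity/100 from global alignment."""
    labels = sorted(sequences)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if circular:
                ident = _circular_identity(sequences[labels[i]],
                                           sequences[labels[j]])
            else:
                ident = global_identity(sequences[labels[i]],
                                        sequences[labels[j]])
            D[i, j] = D[j, i] = 1.0 - ident / 100.0
    return D, labels


def identity_tree(sequences: dict, circular: bool = False) -> Tree:
    """NJ tree on pairwise global-identity distances (d = 1 - identity/100)."""
    if len(sequences) < 3:
        raise ValueError("identity_tree requires >= 3 sequences")
    D, labels = identity_distance_matrix(sequences, circular=circular)
    return neighbor_joining(D, labels)


# --------------------------------------------------------------------------
# polyploid placement


def classify_polyploid_topology(tree: Tree, polyploid: str, clade_i, clade_ii,
                                labels: tuple = ("cladeI_like", "cladeII_like"),
                                ) -> str:
    """Label a polyploid's placement by its sister-group clade membership.

    Each neighbour subtree around the polyploid's attachment node
    implicates a clade when its clade-member content is non-empty and
    drawn from that clade only (taxa outside both clades, e.g. outgroups,
    are disregarded).  A single implication decides the label; when both
    clades are implicated (the polyploid sits on the path between them)
    the strictly shorter tree-path distance to the nearest member of
    either clade breaks the tie, and an exact tie is 'unresolved'.
    """
    clade_i, clade_ii = set(clade_i), set(clade_ii)
    if clade_i & clade_ii:
        raise ValueError("clades must be disjoint")
    if polyploid in clade_i | clade_ii:
        raise ValueError("polyploid cannot be a clade member")
    if not tree.has_leaf(polyploid):
        raise ValueError(f"polyploid {polyploid!r} not in tree")

    node = tree.find(polyploid)
    parent = node.parent
    if parent is None:
        return "unresolved"
    all_leaves = set(tree.leaf_labels())
    neighbour_sets = []
    for child in parent.children:
        if child is node:
            continue
        neighbour_sets.append({n.label for n in child.leaves()})
    below_parent = {n.label for n in parent.leaves()}
    up = all_leaves - below_parent
    if up:
        neighbour_sets.append(up)

    implicated = set()
    for s in neighbour_sets:
        members = (s - {polyploid}) & (clade_i | clade_ii)
        if not members:
            continue
        if members <= clade_i:
            implicated.add(labels[0])
        elif members <= clade_ii:
            implicated.add(labels[1])
    if len(implicated) == 1:
        return implicated.pop()
    if implicated == {labels[0], labels[1]}:
        dists = tree.leaf_distances()[polyploid]
        d_i = min(dists[t] for t in clade_i if t in dists)
        d_ii = min(dists[t] for t in clade_ii if t in dists)
        if d_i < d_ii - 1e-12:
            return labels[0]
        if d_ii < d_i - 1e-12:
            return labels[1]
    return "unresolved"


def infer_maternal_parent(D: np.ndarray, labels: list, polyploid: str,
                          diploids, rel_tolerance: float = 0.05):
    """Closest diploid to the polyploid in an organelle distance matrix.

    Returns (best, tie_set): all diploids within ``rel_tolerance``
    (relative) of the minimum distance form the tie set.
    """
    diploids = [d for d in diploids]
    if polyploid not in labels:
        raise ValueError(f"{polyploid!r} not in matrix")
    if len(diploids) < 2:
        raise ValueError("need >= 2 diploid candidates")
    pi = labels.index(polyploid)
    dists = {d: D[pi, labels.index(d)] for d in diploids}
    best = min(dists, key=lambda d: (dists[d], d))
    dmin = dists[best]
    ties = sorted(d for d, v in dists.items()
                  if v <= dmin * (1 + rel_tolerance) + 1e-15)
    return best, ties


# --------------------------------------------------------------------------
# dating


def scale_tree_ages(tree: Tree, root_age: float = 12.4) -> Tree:
    """Midpoint-root, average node heights, and scale so the root sits at
    ``root_age`` (leaves at age 0).  Branch lengths become age differences."""
    t = tree.copy()
    # midpoint rooting
    dists = t.leaf_distances()
    pair = max(
        ((a, b) for a in dists for b in dists[a] if a < b),
        key=lambda p: (dists[p[0]][p[1]], p))
    diameter = dists[pair[0]][pair[1]]
    if diameter <= 0:
        raise ValueError("tree has zero height; cannot scale ages")
    half = diameter / 2.0

    # walk from leaf pair[0] towards pair[1] until we pass the midpoint
    a_node = t.find(pair[0])
    # path from a to b via parents: collect both root paths
    def path_to_root(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    pa = path_to_root(a_node)
    pb = path_to_root(t.find(pair[1]))
    lca = next(x for x in pa if x in pb)
    path = pa[:pa.index(lca)] + [lca] + pb[:pb.index(lca)][::-1]
    walked = 0.0
    root_edge_child, below = None, 0.0
    for idx in range(len(path) - 1):
        cur, nxt = path[idx], path[idx + 1]
        edge_child = cur if cur.parent is nxt else nxt
        elen = edge_child.length
        if walked + elen >= half - 1e-12:
            offset = half - walked  # distance from 'cur' end of the edge
            if cur is edge_child:
                below = elen - offset
            else:
                below = offset
            root_edge_child = edge_child
            break
        walked += elen
    if root_edge_child is None:  # numerical corner: root on last edge
        root_edge_child = path[-1]
        below = 0.0
    t.reroot_on_edge(root_edge_child, below)

    # UPGMA-style height averaging
    heights: dict[int, float] = {}
    for node in t.root.postorder():
        if node.is_leaf:
            heights[id(node)] = 0.0
        else:
            means = [heights[id(c)] + c.length for c in node.children]
            h = float(np.mean(means))
            h = max(h, max(heights[id(c)] for c in node.children))
            heights[id(node)] = h
    root_h = heights[id(t.root)]
    if root_h <= 0:
        raise ValueError("zero root height")
    for node in t.root.preorder():
        node.age = 0.0 if node.is_leaf else heights[id(node)] * root_age / root_h
    for node in t.root.preorder():
        if node.parent is not None:
            node.length = max(node.parent.age - node.age, 0.0)
    return t
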