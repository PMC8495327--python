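import numpy as np
import pandas as pd
import pytest

from skimploid._seq import decode, encode, min_rotation, revcomp
from skimploid.reads import ReadBlock
from skimploid.repeats import (
    ReadCluster,
    classify_by_library,
    cluster_consensus,
    cluster_reads,
    comparative_abundance_table,
    detect_tandem,
    sample_reads_scaled,
)


def tandem_array(monomer, copies):
    return monomer * copies


def reads_from(seq, n, read_len=100, seed=0, circular=False, sample="r"):
    r = np.random.default_rng(seed)
    src = seq + seq[:read_len] if circular else seq
    hi = len(seq) if circular else len(seq) - read_len + 1
    starts = r.integers(0, hi, n)
    mat = np.vstack([encode(src[s:s + read_len]) for s in starts])
    return ReadBlock(sample, mat, [f"{sample}:{i}" for i in range(n)])


def mutate_reads(block, rate, seed=1):
    r = np.random.default_rng(seed)
    mat = block.matrix.copy()
    hit = r.random(mat.shape) < rate
    mat[hit] = (mat[hit] + r.integers(1, 4, hit.sum())) % 4
    return ReadBlock(block.sample, mat, block.ids)


@pytest.fixture
def monomer():
    r = np.random.default_rng(5)
    return "".join(r.choice(list("ACGT"), 165))


# ------------------------------------------------------------- scaled sampling

def make_readset_block(n, seed, sample):
    r = np.random.default_rng(seed)
    mat = r.integers(0, 4, size=(n, 60)).astype(np.uint8)
    return ReadBlock(sample, mat, [f"{sample}:{i}" for i in range(n)])


def test_equal_diploids_get_equal_samples():
    blocks = {"a": make_readset_block(1000, 1, "a"),
              "b": make_readset_block(1000, 2, "b")}
    out = sample_reads_scaled(blocks, 300, {"a": 2, "b": 2},
                              {"a": 1e6, "b": 1e6}, seed=0)
    assert out["a"].n_reads == out["b"].n_reads == 300


def test_tetraploid_sampled_double():
    blocks = {"dip": make_readset_block(1000, 1, "dip"),
              "tet": make_readset_block(1000, 2, "tet")}
    out = sample_reads_scaled(blocks, 300, {"dip": 2, "tet": 4},
                              {"dip": 1e6, "tet": 1e6}, seed=0)
    assert out["dip"].n_reads == 300
    assert out["tet"].n_reads == 600


def test_oversampling_names_the_species():
    blocks = {"a": make_readset_block(100, 1, "a")}
    with pytest.raises(ValueError, match="'a'"):
        sample_reads_scaled(blocks, 200, {"a": 2}, {"a": 1e6}, seed=0)


def test_sampling_without_replacement():
    blocks = {"a": make_readset_block(400, 1, "a")}
    out = sample_reads_scaled(blocks, 400, {"a": 2}, {"a": 1e6}, seed=0)
    assert len(set(out["a"].ids)) == 400


# ---------------------------------------------------------------- clustering

def test_two_disjoint_families_two_pure_clusters(monomer):
    r = np.random.default_rng(9)
    other = "".join(r.choice(list("ACGT"), 165))
    b1 = reads_from(tandem_array(monomer, 8), 60, circular=True, seed=1,
                    sample="f1")
    b2 = reads_from(tandem_array(other, 8), 40, circular=True, seed=2,
                    sample="f2")
    block = ReadBlock("mix", np.vstack([b1.matrix, b2.matrix]),
                      b1.ids + b2.ids)
    clusters = cluster_reads(block, k=17)
    assert len(clusters) == 2
    for c in clusters:
        families = {i.split(":")[0] for i in c.member_ids}
        assert len(families) == 1  # purity vs truth labels
    assert {c.size for c in clusters} == {60, 40}


def test_single_tandem_array_single_cluster(monomer):
    block = reads_from(tandem_array(monomer, 10), 50, circular=True, seed=3)
    clusters = cluster_reads(block, k=17)
    assert len(clusters) == 1
    assert clusters[0].abundance == pytest.approx(1.0)


def test_single_copy_reads_unclustered():
    r = np.random.default_rng(11)
    genome = "".join(r.choice(list("ACGT"), 100_000))
    block = reads_from(genome, 80, seed=4)  # sparse: no k-mer sharing
    assert cluster_reads(block, k=17) == []


def test_clusters_disjoint_and_bounded(monomer):
    b1 = reads_from(tandem_array(monomer, 8), 60, circular=True, seed=1)
    clusters = cluster_reads(b1, k=17)
    seen = set()
    total = 0
    for c in clusters:
        ids = set(c.member_idx.tolist())
        assert not ids & seen
        seen |= ids
        total += c.size
    assert total <= b1.n_reads


# ----------------------------------------------------------------- consensus

def test_identical_reads_consensus_is_the_read():
    r = np.random.default_rng(13)
    read = "".join(r.choice(list("ACGT"), 120))
    mat = np.vstack([encode(read)] * 6)
    block = ReadBlock("x", mat, [f"x:{i}" for i in range(6)])
    cluster = ReadCluster("CL1", np.arange(6), block.ids, 1.0)
    cons, circular = cluster_consensus(block, cluster, k=17)
    assert cons in (read, revcomp(read))  # strand of the walk is arbitrary
    assert not circular


def test_monomer_tiling_reads_give_rotation_of_monomer(monomer):
    block = reads_from(tandem_array(monomer, 10), 80, circular=True, seed=5)
    cluster = ReadCluster("CL1", np.arange(block.n_reads), block.ids, 1.0)
    cons, circular = cluster_consensus(block, cluster, k=17)
    assert circular
    assert len(cons) == len(monomer)
    assert min_rotation(cons) == min_rotation(monomer)


def test_noisy_reads_consensus_within_one_mismatch(monomer):
    clean = reads_from(tandem_array(monomer, 10), 300, circular=True, seed=6)
    noisy = mutate_reads(clean, 0.01)
    cluster = ReadCluster("CL1", np.arange(noisy.n_reads), noisy.ids, 1.0)
    cons, circular = cluster_consensus(noisy, cluster, k=17)
    assert circular and len(cons) == len(monomer)
    rot = min_rotation(cons)
    ref = min_rotation(monomer)
    assert sum(a != b for a, b in zip(rot, ref)) <= 1


# ------------------------------------------------------------ tandem calling

def test_exact_tandem_period(monomer):
    res = detect_tandem(tandem_array(monomer, 10))
    assert res.is_tandem and res.period == 165


def test_random_sequence_not_tandem():
    r = np.random.default_rng(15)
    seq = "".join(r.choice(list("ACGT"), 1000))
    res = detect_tandem(seq)
    assert not res.is_tandem and res.period is None


def test_higher_order_variants_smallest_period_with_secondary(monomer):
    r = np.random.default_rng(19)
    variant = list(monomer)
    for p in r.choice(165, size=8, replace=False):  # ~5% diverged copy
        variant[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[variant[p]]
    unit = monomer + "".join(variant)
    res = detect_tandem(unit * 5)
    assert res.is_tandem
    assert res.period == 165
    assert 330 in res.secondary_periods


def test_single_monomer_needs_reads_for_circularity(monomer):
    block = reads_from(tandem_array(monomer, 10), 60, circular=True, seed=7)
    res = detect_tandem(monomer, member_block=block, k=17)
    assert res.is_tandem and res.period == 165
    # without reads there is no evidence of closure
    assert not detect_tandem(monomer).is_tandem


# ------------------------------------------------------- library annotation

def test_library_exact_match(monomer):
    label = classify_by_library(monomer, {"StyloSat1": monomer, "other": "ACGT" * 50})
    assert label == "StyloSat1"


def test_library_below_score_non_classified(monomer):
    r = np.random.default_rng(21)
    junk = "".join(r.choice(list("ACGT"), 400))
    assert classify_by_library(junk, {"fam": monomer}) == "non-classified"


def test_library_tie_ambiguous(monomer):
    assert classify_by_library(monomer, {"a": monomer, "b": monomer}) == "ambiguous"


def test_library_empty_rejected(monomer):
    with pytest.raises(ValueError):
        classify_by_library(monomer, {})


# ------------------------------------------------------------ abundance table

def make_cluster(cid, size, total, annotation):
    return ReadCluster(cid, np.arange(size), [f"r{i}" for i in range(size)],
                       size / total, annotation=annotation)


def test_abundance_table_cells_and_zeros():
    clusters = {
        "sp1": [make_cluster("CL1", 50, 1000, "famA"),
                make_cluster("CL2", 30, 1000, "famA"),
                make_cluster("CL3", 10, 1000, "non-classified")],
        "sp2": [make_cluster("CL1", 20, 1000, "famB")],
    }
    table = comparative_abundance_table(clusters)
    assert table.loc["famA", "sp1"] == pytest.approx(8.0)
    assert table.loc["famA", "sp2"] == 0.0
    assert table.loc["famB", "sp2"] == pytest.approx(2.0)
    assert (table.sum(axis=0) <= 100.0 + 1e-9).all()
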