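import numpy as np
import pandas as pd
import pytest

from skimploid._seq import decode, jc_substitution_probability, revcomp
from skimploid.simulate import (
    GenomeBlueprint,
    PolyploidSpec,
    SatFamilySpec,
    SpeciesTreeSpec,
    evolve_satellitome,
    evolve_sequences,
    make_allopolyploid,
    simulate_reads,
    simulate_study,
)

from conftest import small_blueprint


# ----------------------------------------------------------------- JC model

def test_zero_branch_child_identical():
    spec = SpeciesTreeSpec("(A:0.0,B:0.05);")
    bp = small_blueprint(sat_families=[SatFamilySpec("satA", 0.03)])
    genomes = evolve_sequences(spec, bp, seed=3)
    # regenerate the root by evolving with both branches zero
    spec0 = SpeciesTreeSpec("(A:0.0,B:0.0);")
    g0 = evolve_sequences(spec0, bp, seed=3)
    assert np.array_equal(g0["A"].nuclear, g0["B"].nuclear)
    assert np.array_equal(g0["A"].plastome, g0["B"].plastome)
    # and A (zero branch) is that same root state
    assert np.array_equal(genomes["A"].nuclear, g0["A"].nuclear)


def test_jc_substitution_fraction_matches_closed_form():
    # L = 10 kb at d = 0.05: observed fraction within 3 binomial sd of 0.0484
    L, d = 10_000, 0.05
    spec = SpeciesTreeSpec(f"(A:0.0,B:{d});")
    bp = GenomeBlueprint(nuclear_len=L, plastome_len=1000, mitogenome_len=1000,
                         organelle_copy_boost=10, rdna_copies=0,
                         rdna_unit_len=100)
    g = evolve_sequences(spec, bp, seed=5)
    frac = np.mean(g["A"].nuclear != g["B"].nuclear)
    p = jc_substitution_probability(d)
    sd = np.sqrt(p * (1 - p) / L)
    assert abs(frac - p) <= 3 * sd


def test_pairwise_difference_at_total_path_point_one():
    spec = SpeciesTreeSpec("(A:0.05,B:0.05);")
    bp = GenomeBlueprint(nuclear_len=20_000, plastome_len=1000,
                         mitogenome_len=1000, organelle_copy_boost=10,
                         rdna_copies=0, rdna_unit_len=100)
    g = evolve_sequences(spec, bp, seed=6)
    frac = np.mean(g["A"].nuclear != g["B"].nuclear)
    # two independent JC branches of 0.05: P(differ) = p2 + 2 p1 (1 - p1) - ...
    # equivalently the closed form at d = 0.1
    p = jc_substitution_probability(0.1)
    sd = np.sqrt(p * (1 - p) / 20_000)
    assert abs(frac - p) <= 3.5 * sd


def test_negative_branch_rejected():
    with pytest.raises(ValueError, match="negative branch"):
        SpeciesTreeSpec("(A:-0.1,B:0.1);")


# ------------------------------------------------------------- satellitome

def test_no_dynamics_all_species_share_targets(tree_spec):
    specs = [SatFamilySpec("f1", 0.02), SatFamilySpec("f2", 0.01)]
    ab = evolve_satellitome(tree_spec, specs, seed=1)
    for sp, fams in ab.items():
        assert fams == {"f1": 0.02, "f2": 0.01}


def test_loss_removes_family_in_exactly_that_clade(tree_spec):
    specs = [SatFamilySpec("f1", 0.02, loss_branches=("cII",))]
    ab = evolve_satellitome(tree_spec, specs, seed=1)
    for sp in ("P", "M", "V"):
        assert ab[sp]["f1"] == 0.0
    for sp in ("O", "H", "S"):
        assert ab[sp]["f1"] == 0.02


def test_gain_restricts_family_to_subtree(tree_spec):
    specs = [SatFamilySpec("f1", 0.02, gain_branch="cI")]
    ab = evolve_satellitome(tree_spec, specs, seed=1)
    present = {sp for sp, fams in ab.items() if fams["f1"] > 0}
    assert present == {"H", "S"}


def test_drift_sd_composes_along_path():
    # two branches below the gain point: log-abundance sd ~ sigma*sqrt(2)
    sigma = 0.3
    spec = SpeciesTreeSpec("((A:1.0)m:1.0)r;")  # chain: r -> m -> A
    vals = []
    for seed in range(1000):
        ab = evolve_satellitome(
            spec, [SatFamilySpec("f", 0.02, drift_sigma=sigma)], seed=seed)
        vals.append(np.log(ab["A"]["f"]))
    sd = np.std(vals)
    expected = sigma * np.sqrt(2)
    assert abs(sd - expected) < 0.1 * expected


def test_loss_not_below_gain_rejected(tree_spec):
    with pytest.raises(ValueError, match="not a proper descendant"):
        evolve_satellitome(
            tree_spec,
            [SatFamilySpec("f", 0.01, gain_branch="cI", loss_branches=("V",))],
            seed=0)


def test_sat_spec_validation():
    with pytest.raises(ValueError, match="monomer length"):
        SatFamilySpec("f", 0.01, monomer_len=30)
    with pytest.raises(ValueError, match="target_abundance"):
        SatFamilySpec("f", 0.2)


# --------------------------------------------------------- allopolyploidy

def test_allopolyploid_composition(genomes):
    poly = make_allopolyploid(genomes["H"], genomes["V"], "X")
    assert poly.ploidy == 4
    assert np.array_equal(poly.plastome, genomes["H"].plastome)
    assert np.array_equal(poly.mitogenome, genomes["H"].mitogenome)
    assert poly.nuclear.shape[0] == (genomes["H"].nuclear.shape[0]
                                     + genomes["V"].nuclear.shape[0])
    assert poly.parents == ("H", "V")
    # satellite family set is the union of the parents'
    assert poly.present_families() == (genomes["H"].present_families()
                                       | genomes["V"].present_families())


def test_maternal_only_family_present(genomes):
    # satB gained on cI: present in H, absent in V
    assert genomes["H"].sat_copies["satB"] > 0
    assert genomes["V"].sat_copies["satB"] == 0
    poly = make_allopolyploid(genomes["H"], genomes["V"], "X")
    assert poly.sat_copies["satB"] == genomes["H"].sat_copies["satB"]


def test_paternal_family_loss(genomes):
    poly = make_allopolyploid(genomes["H"], genomes["V"], "X",
                              paternal_family_loss=("satC",))
    assert poly.sat_copies["satC"] == 0  # satC was paternal(V)-only


def test_autopolyploid_warns(genomes):
    with pytest.warns(UserWarning, match="autopolyploid"):
        poly = make_allopolyploid(genomes["H"], genomes["H"], "auto")
    assert poly.is_autopolyploid


def test_non_diploid_parent_rejected(genomes):
    poly = make_allopolyploid(genomes["H"], genomes["V"], "X")
    with pytest.raises(ValueError, match="diploid"):
        make_allopolyploid(poly, genomes["V"], "Y")


# ------------------------------------------------------------------ reads

def test_error_free_reads_are_exact_substrings(genomes):
    g = genomes["H"]
    rs, truth = simulate_reads(g, coverage=0.5, error_rate=0.0, seed=9)
    pt = decode(g.plastome)
    mt = decode(g.mitogenome)
    nuc = decode(g.nuclear)
    haystack = nuc + "#" + pt + pt + "#" + mt + mt  # organelles circular
    for i in range(0, rs.n_pairs, 37):
        for mat in (rs.r1, rs.r2):
            read = decode(mat[i])
            assert read in haystack or revcomp(read) in haystack


def test_pair_count_formula():
    bp = GenomeBlueprint(nuclear_len=30_000, plastome_len=1000,
                         mitogenome_len=1000, organelle_copy_boost=10,
                         rdna_copies=0, rdna_unit_len=100)
    spec = SpeciesTreeSpec("(A:0.0,B:0.0);")
    g = evolve_sequences(spec, bp, seed=1)["A"]
    rs, _ = simulate_reads(g, coverage=10, read_len=150, seed=2)
    # nuclear: 10 * 30000 / 300 = 1000 pairs; organelles 10x boost on 1 kb
    truthcounts = {
        "nuclear": round(10 * 30_000 / 300),
        "plastome": round(100 * 1000 / 300),
        "mitogenome": round(100 * 1000 / 300),
    }
    assert rs.n_pairs == sum(truthcounts.values())


def test_error_rate_gives_expected_mismatches(genomes):
    g = genomes["H"]
    err = 0.01
    rs, truth = simulate_reads(g, coverage=2, error_rate=err, seed=4)
    clean, _ = simulate_reads(g, coverage=2, error_rate=0.0, seed=4)
    # identical rng draws up to the error step make reads comparable per
    # compartment; compare the first (nuclear) segment only
    n = 100
    mism = (rs.r1[:n] != clean.r1[:n]).mean()
    expected = err * 3 / 4 * 4 / 3  # a hit always changes the base
    assert abs(mism - err) <= 3 * np.sqrt(err / (n * 150))


def test_read_counts_proportional_to_length_times_copy(genomes):
    g = genomes["H"]
    rs, truth = simulate_reads(g, coverage=5, error_rate=0.0, seed=8)
    counts = truth["compartment"].value_counts()
    bp = g.blueprint
    total_reads = rs.n_reads
    eff = (g.nuclear.shape[0]
           + bp.organelle_copy_boost * (g.plastome.shape[0]
                                        + g.mitogenome.shape[0]))
    for comp, L in (("chloroplast", bp.organelle_copy_boost * g.plastome.shape[0]),
                    ("mitochondrial", bp.organelle_copy_boost * g.mitogenome.shape[0])):
        expected = total_reads * L / eff
        assert abs(counts[comp] - expected) <= 3 * np.sqrt(expected) + 2


def test_same_seed_byte_identical_fastq(genomes, tmp_path):
    g = genomes["S"]
    out = []
    for run in (1, 2):
        rs, _ = simulate_reads(g, coverage=1, error_rate=0.01, seed=42)
        p1, p2 = tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq"
        rs.write_fastq(p1, p2)
        out.append(p1.read_bytes() + p2.read_bytes())
    assert out[0] == out[1]


def test_precondition_errors(genomes):
    with pytest.raises(ValueError, match="coverage"):
        simulate_reads(genomes["H"], coverage=0)
    with pytest.raises(ValueError, match="read_len"):
        simulate_reads(genomes["H"], coverage=1, read_len=400, insert_mean=350)


def test_truth_ids_unique_and_paired(study):
    readsets, truth, _ = study
    for s, rs in readsets.items():
        tr = truth.read_truth[s]
        assert tr["read_id"].is_unique
        ids = set(tr["read_id"])
        for pid in rs.pair_ids()[:50]:
            assert f"{pid}/1" in ids and f"{pid}/2" in ids


def test_organelle_maternal_identity_invariant(tree_spec):
    # polyploid organelle reads are AAF-closest to the maternal parent
    from skimploid.kmers import build_profile
    from skimploid.phylo import aaf_distance

    bp = small_blueprint()
    for seed in range(3):
        readsets, truth, genomes = simulate_study(
            tree_spec, bp, polyploids=[PolyploidSpec("X", "M", "S")],
            coverage=4.0, error_rate=0.01, seed=seed)
        profs = {}
        for s, rs in readsets.items():
            tr = truth.read_truth[s]
            idx = np.nonzero((tr["compartment"] == "chloroplast").values)[0]
            profs[s] = build_profile(rs.block().subset(idx), k=21, min_count=2)
        d_mat = aaf_distance(profs["X"], profs["M"])
        others = [aaf_distance(profs["X"], profs[s])
                  for s in ("O", "H", "S", "P", "V")]
        assert d_mat <= min(others)
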