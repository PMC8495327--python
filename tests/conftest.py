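import numpy as np
import pytest

from skimploid.simulate import (
    GenomeBlueprint,
    SatFamilySpec,
    SpeciesTreeSpec,
    evolve_sequences,
    simulate_study,
)

BALANCED_NEWICK = ("(O:0.045,((H:0.008,S:0.01)cI:0.03,"
                   "((P:0.012,M:0.01)cIIa:0.008,V:0.018)cII:0.025)stem:0.012);")


@pytest.fixture(scope="session")
def tree_spec():
    return SpeciesTreeSpec(BALANCED_NEWICK)


def small_blueprint(**kw):
    base = dict(
        nuclear_len=30_000, plastome_len=8_000, mitogenome_len=10_000,
        organelle_copy_boost=10, rdna_unit_len=1_000, rdna_copies=5,
        sat_families=[
            SatFamilySpec("satA", 0.03, monomer_len=165, drift_sigma=0.1),
            SatFamilySpec("satB", 0.02, monomer_len=165, gain_branch="cI"),
            SatFamilySpec("satC", 0.02, monomer_len=170, gain_branch="cII"),
        ],
        te_families=[(500, 4)],
    )
    base.update(kw)
    return GenomeBlueprint(**base)


@pytest.fixture(scope="session")
def blueprint():
    return small_blueprint()


@pytest.fixture(scope="session")
def genomes(tree_spec, blueprint):
    return evolve_sequences(tree_spec, blueprint, seed=11)


@pytest.fixture(scope="session")
def study(tree_spec, blueprint):
    """One simulated study shared by read-level tests."""
    from skimploid.simulate import PolyploidSpec

    readsets, truth, genomes = simulate_study(
        tree_spec, blueprint,
        polyploids=[PolyploidSpec("X1", "H", "V", ("satC",))],
        coverage=5.0, error_rate=0.01, seed=7)
    return readsets, truth, genomes


@pytest.fixture
def rng():
    return np.random.default_rng(0)
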