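"""Synthetic diploid and allopolyploid genome and read-set simulator.

Generates genomes on a known species tree under a Jukes-Cantor model,
with nuclear satellite arrays, a tandem rDNA array, dispersed repeats,
and high-copy circular organelles; forms allopolyploids by uniting two
diploid nuclear genomes while organelles are copied from the maternal
parent only; and simulates paired-end reads with known per-read truth.

Per-branch substitution: each site substitutes independently with
probability p = (3/4)(1 - exp(-4d/3)) for branch length d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import (
    add_sequencing_errors,
    decode,
    mutate_jc,
    random_seq_arr,
)
from .reads import ReadSet
from .trees import Tree

# annotation codes over nuclear positions
ANN_SINGLE = 0
ANN_RDNA = 1
ANN_SAT_BASE = 2       # satellite family i -> 2 + i
ANN_TE_BASE = 1000     # dispersed repeat family j -> 1000 + j

COMPARTMENTS = ("single_copy", "rDNA", "satellite", "repeat_clustered",
                "chloroplast", "mitochondrial")


@dataclass
class SpeciesTreeSpec:
    """Rooted species tree with branch lengths in substitutions/site."""

    newick: str
    root_age_mya: float = 12.4

    def __post_init__(self):
        self.tree = Tree.from_newick(self.newick)
        self.tree.label_internal()
        labels = self.tree.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        for node in self.tree.root.preorder():
            if node.length < 0:
                raise ValueError(f"negative branch length on {node.label!r}")


@dataclass
class SatFamilySpec:
    """A satellite family: monomer, target genomic abundance, tree dynamics."""

    family_id: str
    target_abundance: float
    monomer: str | None = None
    monomer_len: int = 165
    gain_branch: str | None = None      # child-node label of the gain edge; None = root
    loss_branches: tuple = ()
    drift_sigma: float = 0.0
    #: concerted evolution: keep array copies identical within a genome by
    #: re-tiling from the (evolving) lead monomer on every branch.  Off by
    #: default, so copies diverge by independent branch substitutions.
    homogenize: bool = False

    def __post_init__(self):
        m = len(self.monomer) if self.monomer else self.monomer_len
        if not (50 <= m <= 2000):
            raise ValueError(f"monomer length must be in [50, 2000], got {m}")
        if not (0 <= self.target_abundance <= 0.05):
            raise ValueError("target_abundance must be in [0, 0.05]")

    @property
    def m(self) -> int:
        return len(self.monomer) if self.monomer else self.monomer_len


@dataclass
class GenomeBlueprint:
    """Desk-scale genome composition shared by all simulated species."""

    nuclear_len: int = 200_000
    plastome_len: int = 20_000
    mitogenome_len: int = 35_000
    organelle_copy_boost: int = 50
    rdna_unit_len: int = 2_000
    rdna_copies: int = 10
    sat_families: list = field(default_factory=list)
    te_families: list = field(default_factory=list)  # (length, copy_number)
    gc_content: float = 0.5

    def __post_init__(self):
        for L in (self.nuclear_len, self.plastome_len, self.mitogenome_len):
            if L <= 0:
                raise ValueError("all genome lengths must be > 0")
        if self.organelle_copy_boost < 10:
            raise ValueError("organelle_copy_boost must be an integer >= 10")
        reserved = self.rdna_unit_len * self.rdna_copies
        reserved += sum(self._sat_capacity(f) * f.m for f in self.sat_families)
        reserved += sum(l * c for l, c in self.te_families)
        if reserved > self.nuclear_len:
            raise ValueError(
                f"repeat arrays ({reserved} bp) exceed nuclear length {self.nuclear_len}")
        self._reserved = reserved

    def _sat_capacity(self, fam: SatFamilySpec) -> int:
        """Monomer slots reserved for a family (headroom for drift)."""
        base = max(1, round(fam.target_abundance * self.nuclear_len / fam.m))
        return int(np.ceil(base * 3)) + 1


@dataclass
class SimulatedGenome:
    species: str
    ploidy: int
    nuclear: np.ndarray
    annotation: np.ndarray  # int16 per nuclear position
    plastome: np.ndarray
    mitogenome: np.ndarray
    sat_copies: dict
    blueprint: GenomeBlueprint
    parents: tuple | None = None  # (maternal, paternal) labels for polyploids
    subgenome_boundary: int | None = None
    is_autopolyploid: bool = False
    sat_regions: dict | None = None  # family index -> (start, capacity)

    def sat_consensus(self, family_id: str) -> str | None:
        """First realized monomer of the family's array (maternal subgenome
        first for polyploids); None if absent."""
        if self.sat_regions is None:
            return None
        idx = next(i for i, f in enumerate(self.blueprint.sat_families)
                   if f.family_id == family_id)
        fam = self.blueprint.sat_families[idx]
        start, _cap = self.sat_regions[idx]
        offsets = [0]
        if self.subgenome_boundary is not None:
            offsets.append(self.subgenome_boundary)
        for off in offsets:
            lo = off + start
            if (self.annotation[lo:lo + fam.m] == ANN_SAT_BASE + idx).all():
                return decode(self.nuclear[lo:lo + fam.m])
        return None

    def sat_abundance(self, family_id: str) -> float:
        """Realized abundance as a fraction of the nuclear genome."""
        fam = next(f for f in self.blueprint.sat_families if f.family_id == family_id)
        return self.sat_copies.get(family_id, 0) * fam.m / self.nuclear.shape[0]

    def present_families(self) -> set:
        return {f for f, c in self.sat_copies.items() if c > 0}

    def compartment_sequences(self) -> dict:
        return {"nuclear": self.nuclear, "plastome": self.plastome,
                "mitogenome": self.mitogenome}


# --------------------------------------------------------------------------
# satellite presence / abundance trajectories along the tree


def _validate_sat_specs(tree: Tree, sat_specs) -> None:
    labels = {n.label for n in tree.root.preorder()}
    for fam in sat_specs:
        if fam.gain_branch is not None and fam.gain_branch not in labels:
            raise ValueError(f"gain branch {fam.gain_branch!r} not in tree")
        for loss in fam.loss_branches:
            if loss not in labels:
                raise ValueError(f"loss branch {loss!r} not in tree")
            anchor = fam.gain_branch or tree.root.label
            if not tree.is_descendant(loss, anchor) or loss == anchor:
                raise ValueError(
                    f"loss branch {loss!r} of {fam.family_id} is not a proper "
                    f"descendant of its gain branch {anchor!r}")


def _satellite_trajectories(tree: Tree, sat_specs, seed) -> dict:
    """Per-node satellite state: {node_label: {family_id: abundance_fraction}}.

    Abundance at a node = target x product of per-branch lognormal drift
    multipliers along the path from the gain edge; zero where absent.
    """
    _validate_sat_specs(tree, sat_specs)
    rng = np.random.default_rng([int(seed), 7])
    state: dict[str, dict[str, float]] = {}

    def visit(node, parent_state):
        st = {}
        for fam in sat_specs:
            prev = parent_state.get(fam.family_id, 0.0) if parent_state is not None else 0.0
            gained_here = fam.gain_branch == node.label or (
                fam.gain_branch is None and parent_state is None)
            if node.label in fam.loss_branches:
                val = 0.0
            elif gained_here:
                val = fam.target_abundance
            else:
                val = prev
            # drift applies on every branch below (and including) the gain edge
            if val > 0 and fam.drift_sigma > 0 and not (
                    fam.gain_branch is None and parent_state is None):
                val *= rng.lognormal(0.0, fam.drift_sigma)
            elif fam.drift_sigma > 0:
                rng.lognormal(0.0, fam.drift_sigma)  # keep the stream aligned
            st[fam.family_id] = val
        state[node.label] = st
        for child in node.children:
            visit(child, st)

    visit(tree.root, None)
    return state


def evolve_satellitome(tree_spec: SpeciesTreeSpec, sat_specs, seed: int = 0) -> dict:
    """Realized satellite family sets and abundances per leaf species.

    Returns {species: {family_id: abundance_fraction}} with absent
    families at 0.0.
    """
    state = _satellite_trajectories(tree_spec.tree, sat_specs, seed)
    return {leaf: state[leaf] for leaf in tree_spec.tree.leaf_labels()}


# --------------------------------------------------------------------------
# genome evolution


def _build_root_genome(blueprint: GenomeBlueprint, monomers: dict,
                       root_state: dict, rng: np.random.Generator):
    """Construct the root genome and its layout.

    Layout: reserved features are placed consecutively from offset 1000
    with 500 bp single-copy spacers; the rest is random single-copy
    background.  Returns (nuclear, annotation, plastome, mitogenome,
    sat_regions) where sat_regions maps family index -> (start, capacity).
    """
    L = blueprint.nuclear_len
    nuclear = random_seq_arr(rng, L, blueprint.gc_content)
    ann = np.zeros(L, dtype=np.int16)
    pos = 1000
    if pos + blueprint._reserved > L:
        pos = 0

    # rDNA tandem array (homogenised: copies stay identical within a genome,
    # mimicking concerted evolution so the unit is assemblable)
    rdna_unit, rdna_start = None, None
    if blueprint.rdna_copies > 0:
        rdna_unit = random_seq_arr(rng, blueprint.rdna_unit_len, blueprint.gc_content)
        rdna_start = pos
        arr = np.tile(rdna_unit, blueprint.rdna_copies)
        nuclear[pos:pos + arr.size] = arr
        ann[pos:pos + arr.size] = ANN_RDNA
        pos += arr.size + 500

    # satellite regions (capacity reserved; filled per root presence)
    sat_regions = {}
    for i, fam in enumerate(blueprint.sat_families):
        cap = blueprint._sat_capacity(fam)
        sat_regions[i] = (pos, cap)
        pos += cap * fam.m + 500

    # dispersed repeat families: copies scattered over the free tail of the
    # genome (one copy per equal slot at a random offset)
    for j, (te_len, copies) in enumerate(blueprint.te_families):
        te = random_seq_arr(rng, te_len, blueprint.gc_content)
        free = L - pos
        slot = free // copies if copies else 0
        if slot < te_len + 200:
            raise ValueError("dispersed repeats exceed nuclear length")
        for c in range(copies):
            start = pos + c * slot + int(rng.integers(0, slot - te_len - 100))
            nuclear[start:start + te_len] = mutate_jc(te, 0.01, rng)
            ann[start:start + te_len] = ANN_TE_BASE + j

    plastome = random_seq_arr(rng, blueprint.plastome_len, blueprint.gc_content)
    mitogenome = random_seq_arr(rng, blueprint.mitogenome_len, blueprint.gc_content)

    genome = {
        "nuclear": nuclear, "annotation": ann,
        "plastome": plastome, "mitogenome": mitogenome,
        "rdna_unit": rdna_unit,
    }
    _apply_sat_state(genome, blueprint, monomers, sat_regions, {}, root_state, rng)
    return genome, sat_regions, rdna_start


def _abundance_to_copies(abundance: float, blueprint: GenomeBlueprint,
                         fam: SatFamilySpec, cap: int) -> int:
    if abundance <= 0:
        return 0
    return int(np.clip(round(abundance * blueprint.nuclear_len / fam.m), 1, cap))


def _apply_sat_state(genome, blueprint, monomers, sat_regions,
                     old_copies: dict, node_state: dict, rng) -> dict:
    """Materialise satellite copy-number changes in the nuclear sequence."""
    nuclear, ann = genome["nuclear"], genome["annotation"]
    new_copies = {}
    for i, fam in enumerate(blueprint.sat_families):
        start, cap = sat_regions[i]
        m = fam.m
        old = old_copies.get(fam.family_id, 0)
        new = _abundance_to_copies(node_state.get(fam.family_id, 0.0), blueprint, fam, cap)
        new_copies[fam.family_id] = new
        if fam.homogenize and new > 0 and old > 0:
            # concerted evolution: re-tile every copy from the lead monomer
            template = nuclear[start:start + m].copy()
            nuclear[start:start + new * m] = np.tile(template, new)[: new * m]
            ann[start:start + new * m] = ANN_SAT_BASE + i
            if new < old:
                lo, hi = start + new * m, start + old * m
                nuclear[lo:hi] = random_seq_arr(rng, hi - lo, blueprint.gc_content)
                ann[lo:hi] = ANN_SINGLE
            continue
        if new == old:
            continue
        if new > old:
            template = (monomers[fam.family_id] if old == 0
                        else nuclear[start:start + m].copy())
            for c in range(old, new):
                nuclear[start + c * m:start + (c + 1) * m] = template
            ann[start:start + new * m] = ANN_SAT_BASE + i
        else:
            lo, hi = start + new * m, start + old * m
            nuclear[lo:hi] = random_seq_arr(rng, hi - lo, blueprint.gc_content)
            ann[lo:hi] = ANN_SINGLE
            if new == 0:
                ann[start:start + old * m] = ANN_SINGLE
    return new_copies


def evolve_sequences(tree_spec: SpeciesTreeSpec, blueprint: GenomeBlueprint,
                     seed: int = 0) -> dict:
    """Evolve genomes down the species tree; returns {species: SimulatedGenome}."""
    tree = tree_spec.tree
    sat_state = _satellite_trajectories(tree, blueprint.sat_families, seed)

    rng_root = np.random.default_rng([int(seed), 0])
    monomers = {}
    for i, fam in enumerate(blueprint.sat_families):
        if fam.monomer is not None:
            from ._seq import encode
            monomers[fam.family_id] = encode(fam.monomer)
        else:
            monomers[fam.family_id] = random_seq_arr(
                np.random.default_rng([int(seed), 5, i]), fam.monomer_len,
                blueprint.gc_content)

    root_genome, sat_regions, rdna_start = _build_root_genome(
        blueprint, monomers, sat_state[tree.root.label], rng_root)
    root_copies = {
        fam.family_id: _abundance_to_copies(
            sat_state[tree.root.label][fam.family_id], blueprint, fam,
            sat_regions[i][1])
        for i, fam in enumerate(blueprint.sat_families)
    }

    out: dict[str, SimulatedGenome] = {}
    edge_counter = [0]

    def visit(node, genome, copies):
        if node.is_leaf:
            out[node.label] = SimulatedGenome(
                species=node.label, ploidy=2,
                nuclear=genome["nuclear"], annotation=genome["annotation"],
                plastome=genome["plastome"], mitogenome=genome["mitogenome"],
                sat_copies=dict(copies), blueprint=blueprint,
                sat_regions=dict(sat_regions))
            return
        for child in node.children:
            edge_counter[0] += 1
            rng = np.random.default_rng([int(seed), 1, edge_counter[0]])
            child_genome = {
                "nuclear": mutate_jc(genome["nuclear"], child.length, rng),
                "annotation": genome["annotation"].copy(),
                "plastome": mutate_jc(genome["plastome"], child.length, rng),
                "mitogenome": mutate_jc(genome["mitogenome"], child.length, rng),
                "rdna_unit": (mutate_jc(genome["rdna_unit"], child.length, rng)
                              if genome["rdna_unit"] is not None else None),
            }
            if child_genome["rdna_unit"] is not None:
                # concerted evolution: re-tile identical units
                unit = child_genome["rdna_unit"]
                arr = np.tile(unit, blueprint.rdna_copies)
                child_genome["nuclear"][rdna_start:rdna_start + arr.size] = arr
            child_copies = _apply_sat_state(
                child_genome, blueprint, monomers, sat_regions,
                copies, sat_state[child.label], rng)
            visit(child, child_genome, child_copies)

    visit(tree.root, root_genome, root_copies)
    return out


def make_allopolyploid(maternal: SimulatedGenome, paternal: SimulatedGenome,
                       label: str, paternal_family_loss=(), seed: int = 0,
                       post_formation_divergence: float = 0.0,
                       ) -> SimulatedGenome:
    """Union of two diploid nuclear genomes; organelles from the maternal parent.

    ``paternal_family_loss`` names satellite families whose paternal-
    subgenome arrays are erased at formation (post-hybridisation paternal
    attrition); families still present maternally are unaffected there.
    At formation the organelles are byte-identical to the maternal
    parent's; ``post_formation_divergence`` (substitutions/site) then lets
    the hybrid lineage drift on all compartments, reflecting its age.
    """
    if maternal.ploidy != 2 or paternal.ploidy != 2:
        raise ValueError("both parents must be diploid")
    auto = maternal.species == paternal.species
    if auto:
        warnings.warn(f"{label}: same parent genome passed twice; "
                      "flagging as autopolyploid")

    rng = np.random.default_rng([int(seed), 99])
    pat_nuc = paternal.nuclear.copy()
    pat_ann = paternal.annotation.copy()
    pat_copies = dict(paternal.sat_copies)
    bp = paternal.blueprint
    for fid in paternal_family_loss:
        idx = next((i for i, f in enumerate(bp.sat_families) if f.family_id == fid), None)
        if idx is None:
            raise ValueError(f"unknown satellite family {fid!r}")
        mask = pat_ann == ANN_SAT_BASE + idx
        pat_nuc[mask] = random_seq_arr(rng, int(mask.sum()), bp.gc_content)
        pat_ann[mask] = ANN_SINGLE
        pat_copies[fid] = 0

    combined = {
        fid: maternal.sat_copies.get(fid, 0) + pat_copies.get(fid, 0)
        for fid in set(maternal.sat_copies) | set(pat_copies)
    }
    d_age = float(post_formation_divergence)
    return SimulatedGenome(
        species=label, ploidy=4,
        nuclear=mutate_jc(np.concatenate([maternal.nuclear, pat_nuc]),
                          d_age, rng),
        annotation=np.concatenate([maternal.annotation, pat_ann]),
        plastome=mutate_jc(maternal.plastome, d_age, rng),
        mitogenome=mutate_jc(maternal.mitogenome, d_age, rng),
        sat_copies=combined,
        blueprint=maternal.blueprint,
        parents=(maternal.species, paternal.species),
        subgenome_boundary=maternal.nuclear.shape[0],
        is_autopolyploid=auto,
        sat_regions=maternal.sat_regions,
    )


# --------------------------------------------------------------------------
# read simulation


def _ann_to_truth(ann_codes: np.ndarray, blueprint: GenomeBlueprint):
    """Map annotation codes to (compartment, family) label arrays."""
    comp = np.full(ann_codes.shape, "single_copy", dtype=object)
    fam = np.full(ann_codes.shape, "", dtype=object)
    comp[ann_codes == ANN_RDNA] = "rDNA"
    for i, f in enumerate(blueprint.sat_families):
        hit = ann_codes == ANN_SAT_BASE + i
        comp[hit] = "satellite"
        fam[hit] = f.family_id
    for j in range(len(blueprint.te_families)):
        hit = ann_codes == ANN_TE_BASE + j
        comp[hit] = "repeat_clustered"
        fam[hit] = f"TE{j + 1}"
    return comp, fam


def simulate_reads(genome: SimulatedGenome, coverage: float, read_len: int = 150,
                   insert_mean: float = 350.0, insert_sd: float = 30.0,
                   error_rate: float = 0.0, seed: int = 0):
    """Paired-end reads with per-read truth.

    Fragment starts are uniform over each compartment (organelles are
    circular and wrap); per-compartment depth is coverage x copy
    multiplier (organelles get the blueprint's copy boost); errors are
    i.i.d. substitutions; read truth is labelled by the annotation at
    each mate's centre.  Returns (ReadSet, truth DataFrame).
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_len > insert_mean:
        raise ValueError("read_len must be <= insert_mean")
    rng = np.random.default_rng(seed)
    bp = genome.blueprint
    boost = bp.organelle_copy_boost
    compartments = [
        ("nuclear", genome.nuclear, 1.0, False),
        ("plastome", genome.plastome, float(boost), True),
        ("mitogenome", genome.mitogenome, float(boost), True),
    ]

    r1_parts, r2_parts, comp_parts, fam_parts = [], [], [], []
    for name, seq, mult, circ in compartments:
        L = seq.shape[0]
        if read_len > L:
            warnings.warn(f"{genome.species}: compartment {name} shorter than "
                          f"read length; skipped")
            continue
        n_pairs = int(round(coverage * mult * L / (2 * read_len)))
        if n_pairs == 0:
            continue
        inserts = np.clip(
            np.round(rng.normal(insert_mean, insert_sd, n_pairs)).astype(np.int64),
            read_len, L)
        if circ:
            starts = rng.integers(0, L, n_pairs)
        else:
            starts = np.floor(rng.random(n_pairs) * (L - inserts + 1)).astype(np.int64)
        offs = np.arange(read_len)
        idx1 = (starts[:, None] + offs[None, :]) % L
        idx2 = ((starts + inserts - read_len)[:, None] + offs[None, :]) % L
        r1 = seq[idx1]
        r2 = (3 - seq[idx2])[:, ::-1]
        r1 = add_sequencing_errors(r1, error_rate, rng)
        r2 = add_sequencing_errors(r2, error_rate, rng)
        r1_parts.append(r1)
        r2_parts.append(r2)

        if name == "nuclear":
            c1 = (starts + read_len // 2) % L
            c2 = (starts + inserts - read_len // 2 - 1) % L
            comp1, fam1 = _ann_to_truth(genome.annotation[c1], bp)
            comp2, fam2 = _ann_to_truth(genome.annotation[c2], bp)
        else:
            lab = "chloroplast" if name == "plastome" else "mitochondrial"
            comp1 = comp2 = np.full(n_pairs, lab, dtype=object)
            fam1 = fam2 = np.full(n_pairs, "", dtype=object)
        comp_parts.append((comp1, comp2))
        fam_parts.append((fam1, fam2))

    if not r1_parts:
        raise ValueError("no compartment was long enough to simulate reads from")
    rs = ReadSet(genome.species, np.vstack(r1_parts), np.vstack(r2_parts))

    comp1 = np.concatenate([c[0] for c in comp_parts])
    comp2 = np.concatenate([c[1] for c in comp_parts])
    fam1 = np.concatenate([f[0] for f in fam_parts])
    fam2 = np.concatenate([f[1] for f in fam_parts])
    n = rs.n_pairs
    comp = np.empty(2 * n, dtype=object)
    fam = np.empty(2 * n, dtype=object)
    comp[0::2], comp[1::2] = comp1, comp2
    fam[0::2], fam[1::2] = fam1, fam2
    truth = pd.DataFrame({
        "read_id": rs.mate_ids(),
        "species": genome.species,
        "compartment": comp,
        "family": fam,
    })
    return rs, truth


# --------------------------------------------------------------------------
# whole-study driver


@dataclass
class PolyploidSpec:
    label: str
    maternal: str
    paternal: str
    paternal_family_loss: tuple = ()
    post_formation_divergence: float = 0.0


@dataclass
class TruthBundle:
    """Simulator ground truth for a full study."""

    tree_newick: str
    parentage: dict            # polyploid -> (maternal, paternal)
    abundances: dict           # species -> {family: fraction of nuclear genome}
    read_truth: dict           # species -> DataFrame
    effective_bases: dict      # species -> bases incl. organelle copy boost
    nuclear_bases: dict

    def presence(self, min_abundance: float = 0.0) -> pd.DataFrame:
        species = sorted(self.abundances)
        fams = sorted({f for d in self.abundances.values() for f in d})
        data = {
            sp: [self.abundances[sp].get(f, 0.0) > max(min_abundance, 0.0)
                 for f in fams]
            for sp in species
        }
        return pd.DataFrame(data, index=fams).T  # species x family

    def expected_read_fraction(self, species: str, family: str) -> float:
        """Expected fraction of the species' reads deriving from a family."""
        nuc = self.abundances[species].get(family, 0.0) * self.nuclear_bases[species]
        return nuc / self.effective_bases[species]


def simulate_study(tree_spec: SpeciesTreeSpec, blueprint: GenomeBlueprint,
                   polyploids=(), coverage: float = 5.0, error_rate: float = 0.01,
                   read_len: int = 150, insert_mean: float = 350.0,
                   insert_sd: float = 30.0, seed: int = 0):
    """Simulate genomes and reads for all diploids plus allopolyploids.

    Returns (readsets, truth, genomes): dicts keyed by sample label and a
    TruthBundle.
    """
    genomes = evolve_sequences(tree_spec, blueprint, seed=seed)
    for i, ps in enumerate(polyploids):
        genomes[ps.label] = make_allopolyploid(
            genomes[ps.maternal], genomes[ps.paternal], ps.label,
            paternal_family_loss=ps.paternal_family_loss, seed=seed + i,
            post_formation_divergence=ps.post_formation_divergence)

    readsets, read_truth, abundances = {}, {}, {}
    effective, nuclear_bases = {}, {}
    boost = blueprint.organelle_copy_boost
    for i, (label, g) in enumerate(sorted(genomes.items())):
        rs, tr = simulate_reads(
            g, coverage, read_len=read_len, insert_mean=insert_mean,
            insert_sd=insert_sd, error_rate=error_rate,
            seed=np.random.SeedSequence([int(seed), 3, i]))
        readsets[label] = rs
        read_truth[label] = tr
        abundances[label] = {
            f.family_id: g.sat_abundance(f.family_id)
            for f in blueprint.sat_families
        }
        nuclear_bases[label] = float(g.nuclear.shape[0])
        effective[label] = float(
            g.nuclear.shape[0]
            + boost * (g.plastome.shape[0] + g.mitogenome.shape[0]))

    truth = TruthBundle(
        tree_newick=tree_spec.newick,
        parentage={ps.label: (ps.maternal, ps.paternal) for ps in polyploids},
        abundances=abundances,
        read_truth=read_truth,
        effective_bases=effective,
        nuclear_bases=nuclear_bases,
    )
    return readsets, truth, genomes
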