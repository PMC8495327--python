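"""End-to-end orchestration: simulate -> assemble -> classify -> repeats
-> satellitome -> phylo -> report, as one reproducible seeded run.

Stage seeds fan out from the single run seed by fixed offsets so stages
are individually reproducible.  Every stage writes its outputs before the
next begins; the report traces every claim to a stage output file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seq import write_fasta
from .kmers import build_profile, classify_reads
from .organelle import assemble_circular
from .phylo import (
    classify_polyploid_topology,
    distance_matrix,
    infer_maternal_parent,
    neighbor_joining,
    bootstrap_supports,
    scale_tree_ages,
)
from .reads import ReadSet
from .repeats import (
    cluster_consensus,
    cluster_reads,
    detect_tandem,
    sample_reads_scaled,
)
from .satellites import (
    filter_min_abundance,
    group_families,
    infer_parental_signatures,
    presence_absence,
    satellite_abundance,
)
from .simulate import (
    GenomeBlueprint,
    PolyploidSpec,
    SatFamilySpec,
    SpeciesTreeSpec,
    simulate_study,
)
from .trees import Tree, robinson_foulds

DEFAULT_TREE = ("(O:0.045,((H:0.008,S:0.01)cI:0.03,"
                "((P:0.012,M:0.01)cIIa:0.008,V:0.018)cII:0.025)stem:0.012);")

DEFAULT_SATS = [
    dict(family_id="satA", target_abundance=0.020, monomer_len=165,
         drift_sigma=0.15, homogenize=True),
    dict(family_id="satB", target_abundance=0.012, monomer_len=165,
         gain_branch="cI", homogenize=True),
    dict(family_id="satC", target_abundance=0.012, monomer_len=170,
         gain_branch="cII", homogenize=True),
    dict(family_id="satD", target_abundance=0.008, monomer_len=130,
         gain_branch="V", homogenize=True),
    dict(family_id="satE", target_abundance=0.008, monomer_len=120,
         gain_branch="H", homogenize=True),
    dict(family_id="satF", target_abundance=0.010, monomer_len=150,
         loss_branches=["cII"], drift_sigma=0.1, homogenize=True),
]

DEFAULT_POLYPLOIDS = [
    # paternal attrition at formation (maternal subgenome favoured): the
    # shared high-copy family and one paternal-specific family are lost
    # from the paternal subgenome; a clade-diagnostic family survives
    dict(label="X1", maternal="H", paternal="V",
         paternal_family_loss=["satA", "satD"],
         post_formation_divergence=0.004),
    dict(label="X2", maternal="M", paternal="S",
         paternal_family_loss=["satA", "satF"],
         post_formation_divergence=0.004),
]

COMPARTMENT_ORDER = ("chloroplast", "mitochondrial", "satellite", "rDNA",
                     "repeat_clustered", "total")


@dataclass
class RunConfig:
    """Full parameterisation of a pipeline run; round-trips via YAML."""

    seed: int = 0
    outdir: str = "skimploid_run"
    tree_newick: str = DEFAULT_TREE
    root_age_mya: float = 12.4
    nuclear_len: int = 100_000
    plastome_len: int = 15_000
    mitogenome_len: int = 20_000
    organelle_copy_boost: int = 10
    rdna_unit_len: int = 2_000
    rdna_copies: int = 8
    gc_content: float = 0.5
    sat_families: list = field(default_factory=lambda: [dict(d) for d in DEFAULT_SATS])
    te_families: list = field(default_factory=lambda: [[800, 8]])
    polyploids: list = field(default_factory=lambda: [dict(d) for d in DEFAULT_POLYPLOIDS])
    coverage: float = 5.0
    error_rate: float = 0.01
    read_len: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 30.0
    k_aaf: int = 21
    k_cluster: int = 17
    k_assembly: int = 31
    min_count: int = 2
    min_frac: float = 0.5
    tau: float = 0.01
    base_n: int = 1500
    min_shared: int = 5
    min_cluster_size: int = 5
    min_bin_reads: int = 25
    d_cap: float = 0.3  # saturated AAF distances distort NJ if left at 1.0
    bootstrap: int = 0
    outgroup: str | None = "O"
    clades: dict = field(default_factory=lambda: {
        "cladeI": ["H", "S"], "cladeII": ["P", "M", "V"]})
    write_reads: bool = True
    map_satellitome: bool = True  # unique-mapping abundance table (slowest stage)

    # ------------------------------------------------------------- helpers
    def tree_spec(self) -> SpeciesTreeSpec:
        return SpeciesTreeSpec(self.tree_newick, root_age_mya=self.root_age_mya)

    def blueprint(self) -> GenomeBlueprint:
        return GenomeBlueprint(
            nuclear_len=self.nuclear_len,
            plastome_len=self.plastome_len,
            mitogenome_len=self.mitogenome_len,
            organelle_copy_boost=self.organelle_copy_boost,
            rdna_unit_len=self.rdna_unit_len,
            rdna_copies=self.rdna_copies,
            sat_families=[SatFamilySpec(**{**d, "loss_branches":
                                           tuple(d.get("loss_branches", ()))})
                          for d in self.sat_families],
            te_families=[tuple(t) for t in self.te_families],
            gc_content=self.gc_content,
        )

    def polyploid_specs(self) -> list:
        return [PolyploidSpec(
            label=d["label"], maternal=d["maternal"], paternal=d["paternal"],
            paternal_family_loss=tuple(d.get("paternal_family_loss", ())),
            post_formation_divergence=d.get("post_formation_divergence", 0.0))
            for d in self.polyploids]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @classmethod
    def small(cls, **kw) -> "RunConfig":
        """Desk-scale preset for tests and seed sweeps."""
        base = dict(
            nuclear_len=60_000, plastome_len=10_000, mitogenome_len=12_000,
            organelle_copy_boost=10, rdna_unit_len=1_500, rdna_copies=6,
            base_n=500, write_reads=False, min_bin_reads=20,
            sat_families=[
                dict(family_id="satA", target_abundance=0.045, monomer_len=165,
                     drift_sigma=0.15, homogenize=True),
                dict(family_id="satB", target_abundance=0.020, monomer_len=165,
                     gain_branch="cI", homogenize=True),
                dict(family_id="satC", target_abundance=0.020, monomer_len=170,
                     gain_branch="cII", homogenize=True),
                dict(family_id="satD", target_abundance=0.015, monomer_len=130,
                     gain_branch="V", homogenize=True),
                dict(family_id="satE", target_abundance=0.015, monomer_len=120,
                     gain_branch="H", homogenize=True),
                # outgroup-private family: keeps O basal in satellite space
                dict(family_id="satO", target_abundance=0.015, monomer_len=150,
                     gain_branch="O", drift_sigma=0.1, homogenize=True),
            ],
            te_families=[[600, 6]],
            polyploids=[
                dict(label="X1", maternal="H", paternal="V",
                     paternal_family_loss=["satA", "satD"],
                     post_formation_divergence=0.004),
                # X2 is the "older" hybrid: heavier paternal attrition, so
                # its satellitome is essentially maternal (its nuclear rDNA
                # still carries the paternal signal)
                dict(label="X2", maternal="M", paternal="S",
                     paternal_family_loss=["satA", "satB"],
                     post_formation_divergence=0.004),
            ],
        )
        base.update(kw)
        return cls(**base)


@dataclass
class RunReport:
    payload: dict

    def __getitem__(self, key):
        return self.payload[key]

    def get(self, key, default=None):
        return self.payload.get(key, default)

    def to_json(self, path=None, indent=2) -> str:
        text = json.dumps(self.payload, indent=indent, sort_keys=True,
                          default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "RunReport":
        return cls(json.loads(Path(path).read_text()))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_seed(seed: int, stage_index: int) -> int:
    return int(seed) + 1000 * stage_index


def run_pipeline(config: RunConfig, resume: bool = False) -> RunReport:
    """Execute all stages; identical config + seed gives an identical report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    log: list[dict] = []

    def log_stage(name, **info):
        log.append({"stage": name, **info})

    # ---------------------------------------------------------- 1 simulate
    try:
        readsets, truth, genomes = _stage_simulate(config, out, resume, log_stage)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    samples = sorted(readsets)
    diploids = [s for s in samples if genomes[s].ploidy == 2]
    polyploid_labels = [s for s in samples if genomes[s].ploidy == 4]

    # ---------------------------------------------------------- 2 assemble
    try:
        organelle_refs, assemblies = _stage_assemble(config, readsets, out, resume,
                                                     log_stage)
    except Exception as e:  # noqa: BLE001
        raise StageError("assemble", e) from e

    # ----------------------------------------- 3 preliminary classification
    try:
        prelim = {}
        for s in samples:
            refs = {b: [seq] for b, seq in organelle_refs[s].items()}
            prelim[s] = classify_reads(readsets[s], refs, k=config.k_aaf,
                                       min_frac=config.min_frac)
        log_stage("prelim_classify",
                  counts={s: prelim[s].counts() for s in samples})
    except Exception as e:  # noqa: BLE001
        raise StageError("prelim_classify", e) from e

    # ------------------------------------------------------------ 4 repeats
    try:
        clusters_by_species, panel, tandem_consensi, repeat_consensi = \
            _stage_repeats(config, prelim, genomes, organelle_refs, out,
                           log_stage)
    except Exception as e:  # noqa: BLE001
        raise StageError("repeats", e) from e

    # -------------------------------------------------------- 5 satellitome
    try:
        sat_section, panel_reps = _stage_satellitome(
            config, readsets, panel, out, polyploid_labels, log_stage)
    except Exception as e:  # noqa: BLE001
        raise StageError("satellitome", e) from e

    # ------------------------------------------------- 6 final classification
    try:
        bins = {}
        # rDNA units diverge slowly; a cross-sample panel rescues samples
        # whose own unit was missed (the satellite panel is pooled likewise)
        rdna_panel = [organelle_refs[s]["rDNA"] for s in samples
                      if "rDNA" in organelle_refs[s]]
        for s in samples:
            refs = {b: [seq] for b, seq in organelle_refs[s].items()}
            if rdna_panel:
                refs["rDNA"] = rdna_panel
            if panel:
                # period-trimmed monomers: consensus tails run into
                # single-copy flanks and would attract non-satellite reads
                refs["satellite"] = list(panel.values())
            if repeat_consensi:
                refs["repeat_clustered"] = repeat_consensi
            bins[s] = classify_reads(readsets[s], refs, k=config.k_aaf,
                                     min_frac=config.min_frac)
        bin_counts = {s: bins[s].counts() for s in samples}
        pd.concat([bins[s].to_frame().assign(sample=s) for s in samples]) \
            .to_csv(out / "bins.tsv", sep="\t", index=False)
        log_stage("classify", counts=bin_counts)
    except Exception as e:  # noqa: BLE001
        raise StageError("classify", e) from e

    # -------------------------------------------------------------- 7 phylo
    try:
        phylo_section = _stage_phylo(config, bins, organelle_refs, samples,
                                     diploids, polyploid_labels, out, log_stage)
    except Exception as e:  # noqa: BLE001
        raise StageError("phylo", e) from e

    # -------------------------------------------------------------- 8 report
    payload = {
        "seed": config.seed,
        "parameters": asdict(config),
        "samples": samples,
        "diploids": diploids,
        "polyploids": polyploid_labels,
        "bin_counts": bin_counts,
        "repeats": {
            s: [
                {"cluster_id": c.cluster_id, "size": c.size,
                 "abundance": c.abundance, "annotation": c.annotation,
                 "is_tandem": c.is_tandem, "period": c.period}
                for c in clusters_by_species[s]
            ]
            for s in clusters_by_species
        },
        "satellites": sat_section,
        "trees": phylo_section["trees"],
        "distance_matrices": phylo_section["distance_matrices"],
        "rf_matrix": phylo_section["rf_matrix"],
        "topology_labels": phylo_section["topology_labels"],
        "maternal_calls": phylo_section["maternal_calls"],
        "dated_tree": phylo_section["dated_tree"],
        "provenance": {"stages": log, "package": "skimploid 0.1.0"},
    }
    report = RunReport(payload)
    report.to_json(out / "report.json")
    return report


# --------------------------------------------------------------------------
# stages


def _stage_simulate(config, out, resume, log_stage):
    reads_dir = out / "reads"
    marker = out / "stage_simulate.done"
    tree_spec = config.tree_spec()
    if resume and marker.exists() and reads_dir.exists():
        readsets = {}
        for f1 in sorted(reads_dir.glob("*_1.fastq")):
            sample = f1.name[: -len("_1.fastq")]
            f2 = reads_dir / f"{sample}_2.fastq"
            readsets[sample] = ReadSet.from_fastq(f1, f2, sample)
        # genomes still need regeneration for ploidy/abundance truth
        _, truth, genomes = simulate_study(
            tree_spec, config.blueprint(), config.polyploid_specs(),
            coverage=config.coverage, error_rate=config.error_rate,
            read_len=config.read_len, insert_mean=config.insert_mean,
            insert_sd=config.insert_sd, seed=_stage_seed(config.seed, 1))
        log_stage("simulate", resumed=True, samples=sorted(readsets))
        return readsets, truth, genomes

    readsets, truth, genomes = simulate_study(
        tree_spec, config.blueprint(), config.polyploid_specs(),
        coverage=config.coverage, error_rate=config.error_rate,
        read_len=config.read_len, insert_mean=config.insert_mean,
        insert_sd=config.insert_sd, seed=_stage_seed(config.seed, 1))
    (out / "true_tree.nwk").write_text(config.tree_newick + "\n")
    if config.write_reads:
        reads_dir.mkdir(exist_ok=True)
        for s, rs in readsets.items():
            rs.write_fastq(reads_dir / f"{s}_1.fastq", reads_dir / f"{s}_2.fastq")
        pd.concat(truth.read_truth.values()).to_csv(
            out / "read_truth.tsv", sep="\t", index=False)
        marker.write_text("ok\n")
    log_stage("simulate", samples=sorted(readsets),
              n_pairs={s: rs.n_pairs for s, rs in readsets.items()})
    return readsets, truth, genomes


def _match_contigs(assembly, config):
    """Assign assembled contigs to organelle/rDNA classes by length."""
    expected = {
        "chloroplast": config.plastome_len,
        "mitochondrial": config.mitogenome_len,
        "rDNA": config.rdna_unit_len,
    }
    refs = {}
    for name, target in expected.items():
        best = None
        for contig in assembly.contigs:
            if abs(len(contig) - target) <= 0.3 * target:
                if best is None or abs(len(contig) - target) < abs(len(best) - target):
                    best = contig
        if best is not None:
            refs[name] = best
    return refs


def _stage_assemble(config, readsets, out, resume, log_stage):
    contig_dir = out / "contigs"
    contig_dir.mkdir(exist_ok=True)
    organelle_refs, assemblies = {}, {}
    for s in sorted(readsets):
        fa = contig_dir / f"{s}.fasta"
        assembly = assemble_circular(readsets[s], k=config.k_assembly,
                                     depth_threshold="auto")
        assemblies[s] = assembly
        matched = _match_contigs(assembly, config)
        organelle_refs[s] = {
            name: contig.sequence for name, contig in matched.items()}
        write_fasta(fa, {
            f"{name}|circular={contig.is_circular}|depth={contig.mean_depth:.1f}":
            contig.sequence for name, contig in matched.items()})
    log_stage("assemble", contigs={
        s: {name: len(seq) for name, seq in organelle_refs[s].items()}
        for s in organelle_refs})
    return organelle_refs, assemblies


def _stage_repeats(config, prelim, genomes, organelle_refs, out, log_stage):
    samples = sorted(prelim)
    nuclear_blocks = {s: prelim[s].reads_in("unassigned") for s in samples}
    ploidies = {s: genomes[s].ploidy for s in samples}
    # monoploid genome size: the polyploid nuclear is two subgenomes
    sizes = {s: genomes[s].nuclear.shape[0] / (genomes[s].ploidy / 2)
             for s in samples}
    ref = next(s for s in samples if ploidies[s] == 2)
    max_base = min(
        int(nuclear_blocks[s].n_reads /
            (sizes[s] * ploidies[s] / 2 / (sizes[ref] * 1.0)))
        for s in samples)
    base_n = min(config.base_n, max_base)
    sampled = sample_reads_scaled(nuclear_blocks, base_n, ploidies, sizes,
                                  seed=_stage_seed(config.seed, 4),
                                  reference=ref)

    clusters_by_species = {}
    panel, repeat_consensi = {}, []
    tandem_consensi = []  # full-length, pre-dedup; classification references
    rows = []
    from .repeats import classify_by_library

    for s in samples:
        clusters = cluster_reads(sampled[s], k=config.k_cluster,
                                 min_shared=config.min_shared,
                                 min_cluster_size=config.min_cluster_size)
        for c in clusters:
            cons, circ = cluster_consensus(sampled[s], c, k=config.k_cluster)
            c.consensus, c.consensus_circular = cons, circ
            members = sampled[s].subset(c.member_idx)
            td = detect_tandem(cons, members, k=config.k_cluster,
                               consensus_circular=circ or None)
            c.is_tandem, c.period = td.is_tandem, td.period
            c.secondary_periods = td.secondary_periods

        # the homogenised rDNA array surfaces as a tandem cluster whose
        # period matches the expected unit length; recover the unit when
        # whole-read assembly missed (or truncated) it
        rdna_cands = [c for c in clusters if c.is_tandem and c.period
                      and abs(c.period - config.rdna_unit_len)
                      <= 0.3 * config.rdna_unit_len]
        if rdna_cands:
            best = max(rdna_cands, key=lambda c: c.period)
            if best.period > len(organelle_refs[s].get("rDNA", "")):
                organelle_refs[s]["rDNA"] = best.consensus[: best.period]

        organelle_lib = {name: seq for name, seq in organelle_refs[s].items()}
        for c in clusters:
            cons = c.consensus
            # clusters of leaked organelle/rDNA reads must not re-enter the
            # nuclear repeat references
            leak = (classify_by_library(cons, organelle_lib, min_score=0.3,
                                        k=config.k_cluster)
                    if organelle_lib else "non-classified")
            if leak in organelle_lib:
                c.annotation = leak
            elif c.is_tandem and c.period and 50 <= c.period <= 2000:
                panel[f"{s}.{c.cluster_id}"] = cons[: c.period]
                tandem_consensi.append(cons[: c.period])
                c.annotation = "satellite"
            else:
                repeat_consensi.append(cons)
            rows.append({"sample": s, "cluster_id": c.cluster_id,
                         "size": c.size, "abundance": c.abundance,
                         "is_tandem": c.is_tandem, "period": c.period,
                         "consensus_len": len(cons),
                         "annotation": c.annotation})
        clusters_by_species[s] = clusters
    pd.DataFrame(rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
    write_fasta(out / "cluster_consensi.fasta",
                {cid: seq for cid, seq in panel.items()})
    log_stage("repeats", base_n=base_n,
              n_clusters={s: len(clusters_by_species[s]) for s in samples},
              panel_size=len(panel))
    return clusters_by_species, panel, tandem_consensi, repeat_consensi


def _stage_satellitome(config, readsets, panel, out, polyploid_labels,
                       log_stage):
    empty = {"abundance": {}, "presence": {}, "grouping": {},
             "signatures": {}, "panel": {}}
    if not panel:
        log_stage("satellitome", skipped="no tandem consensi")
        return empty, {}
    if not config.map_satellitome:
        log_stage("satellitome", skipped="disabled by config")
        return empty, {}

    # deduplicate the panel: keep one representative of near-identical
    # consensi (>= 99%), which would otherwise tie and discard each
    # other's reads under the unique-mapping rule
    raw_grouping = group_families(panel, variant_threshold=0.99)
    reps: dict[str, str] = {}
    chosen: dict[tuple, str] = {}
    for cid in sorted(panel, key=lambda c: (-len(panel[c]), c)):
        fv = raw_grouping[cid]
        if fv not in chosen:
            chosen[fv] = cid
            reps[cid] = panel[cid]

    table = satellite_abundance(readsets, reps, k=config.k_aaf,
                                min_frac=config.min_frac)
    table = filter_min_abundance(table, tau=config.tau)
    grouping = {cid: raw_grouping[cid] for cid in table.abundance.index}
    pa = presence_absence(table)

    signatures = {}
    for p in polyploid_labels:
        rep = infer_parental_signatures(pa, p, config.clades)
        signatures[p] = {
            "contributors": rep.contributors,
            "diagnostic": rep.diagnostic,
            "inconclusive": rep.inconclusive,
        }

    table.abundance.to_csv(out / "sat_abundance.tsv", sep="\t")
    pa.to_csv(out / "sat_presence.tsv", sep="\t")
    write_fasta(out / "sat_panel.fasta", {c: table.consensi[c]
                                          for c in table.abundance.index})
    log_stage("satellitome", retained=len(table.abundance.index))
    section = {
        "abundance": {c: table.abundance.loc[c].to_dict()
                      for c in table.abundance.index},
        "presence": {sp: {c: bool(pa.loc[sp, c]) for c in pa.columns}
                     for sp in pa.index},
        "grouping": {c: list(grouping[c]) for c in grouping},
        "signatures": signatures,
        "panel": {c: table.consensi[c] for c in table.abundance.index},
    }
    panel_kept = {c: table.consensi[c] for c in table.abundance.index}
    return section, panel_kept


def _stage_phylo(config, bins, organelle_refs, samples, diploids,
                 polyploid_labels, out, log_stage):
    trees: dict[str, str] = {}
    dmats: dict[str, dict] = {}
    tree_objs: dict[str, Tree] = {}
    skipped: dict[str, str] = {}

    for comp in COMPARTMENT_ORDER:
        blocks = {s: bins[s].reads_in(comp) for s in samples}
        too_small = [s for s in samples if blocks[s].n_reads < config.min_bin_reads]
        if too_small:
            skipped[comp] = f"too few reads in {too_small}"
            continue
        profiles = {s: build_profile(blocks[s], k=config.k_aaf,
                                     min_count=config.min_count, label=s)
                    for s in samples}
        D, labels = distance_matrix(profiles, d_cap=config.d_cap)
        if config.bootstrap > 0:
            tree = bootstrap_supports(profiles, B=config.bootstrap,
                                      seed=_stage_seed(config.seed, 7),
                                      d_cap=config.d_cap)
        else:
            tree = neighbor_joining(D, labels)
        tree_objs[comp] = tree
        trees[comp] = tree.to_newick(supports=config.bootstrap > 0)
        dmats[comp] = {la: {lb: float(D[i, j])
                            for j, lb in enumerate(labels)}
                       for i, la in enumerate(labels)}

    # alignment-based identity tree on assembled plastomes
    plastomes = {s: organelle_refs[s]["chloroplast"] for s in samples
                 if "chloroplast" in organelle_refs[s]}
    if len(plastomes) >= 3:
        from .phylo import identity_distance_matrix

        Dp, labp = identity_distance_matrix(plastomes, circular=True)
        ptree = neighbor_joining(Dp, labp)
        tree_objs["plastome_identity"] = ptree
        trees["plastome_identity"] = ptree.to_newick()
        dmats["plastome_identity"] = {
            la: {lb: float(Dp[i, j]) for j, lb in enumerate(labp)}
            for i, la in enumerate(labp)}

    # RF matrix across compartment trees sharing the full sample set
    comparable = {name: t for name, t in tree_objs.items()
                  if set(t.leaf_labels()) == set(samples)}
    rf = {a: {b: (robinson_foulds(comparable[a], comparable[b])
                  if a != b else 0)
              for b in comparable} for a in comparable}

    # polyploid topology labels per compartment
    clade_names = sorted(config.clades)
    labels_out: dict[str, dict] = {}
    for p in polyploid_labels:
        labels_out[p] = {}
        for name, t in comparable.items():
            pruned = t.copy()
            for q in polyploid_labels:
                if q != p:
                    pruned.prune_leaf(q)
            labels_out[p][name] = classify_polyploid_topology(
                pruned, p, config.clades[clade_names[0]],
                config.clades[clade_names[1]],
                labels=(clade_names[0], clade_names[1]))

    # maternal-parent calls from the organelle compartments
    maternal = {}
    for p in polyploid_labels:
        calls = {}
        for comp in ("chloroplast", "mitochondrial"):
            if comp not in dmats:
                continue
            labels = sorted(dmats[comp])
            D = np.array([[dmats[comp][a][b] for b in labels] for a in labels])
            best, ties = infer_maternal_parent(D, labels, p, diploids)
            calls[comp] = {"best": best, "ties": ties}
        maternal[p] = calls

    dated = None
    if "chloroplast" in tree_objs:
        try:
            dated_tree = scale_tree_ages(tree_objs["chloroplast"],
                                         root_age=config.root_age_mya)
            dated = dated_tree.to_newick()
        except ValueError as e:
            skipped["dated_tree"] = str(e)

    for name, nwk in trees.items():
        (out / f"tree_{name}.nwk").write_text(nwk + "\n")
    log_stage("phylo", trees=sorted(trees), skipped=skipped)
    return {
        "trees": trees,
        "distance_matrices": dmats,
        "rf_matrix": rf,
        "topology_labels": labels_out,
        "maternal_calls": maternal,
        "dated_tree": dated,
        "skipped": skipped,
    }


# --------------------------------------------------------------------------
# summaries & validation


def congruence_summary(report: RunReport) -> pd.DataFrame:
    """One row per (polyploid, compartment): topology label plus RF of that
    compartment's tree to every other compartment tree."""
    trees = report["trees"]
    if len(trees) < 2:
        raise ValueError("need >= 2 compartment trees")
    rf = report["rf_matrix"]
    rows = []
    for p, comp_labels in report["topology_labels"].items():
        for comp, label in comp_labels.items():
            row = {"polyploid": p, "compartment": comp, "label": label}
            for other, val in rf.get(comp, {}).items():
                if other != comp:
                    row[f"rf_vs_{other}"] = val
            rows.append(row)
    return pd.DataFrame(rows)


def validate_report(report: RunReport, schema_path=None) -> None:
    """Check the report against the published schema (minimal validator)."""
    if schema_path is None:
        schema_path = Path(__file__).parent / "data" / "report_schema.json"
    schema = json.loads(Path(schema_path).read_text())
    payload = report.payload
    for key, typename in schema["required"].items():
        if key not in payload:
            raise ValueError(f"report missing required key {key!r}")
        expected = {
            "object": dict, "array": list, "integer": int,
            "string": str, "string_or_null": (str, type(None)),
        }[typename]
        if not isinstance(payload[key], expected):
            raise ValueError(
                f"report key {key!r} has type {type(payload[key]).__name__}, "
                f"expected {typename}")
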