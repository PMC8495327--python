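"""Mapping-based satellite abundance across species, the 0.01% presence
rule, rotation-aware family/variant grouping, and parental-signature
inference for polyploids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp
from .kmers import matrix_codes, reference_code_set, _isin_sorted
from .reads import ReadSet

#: abundance presence threshold, in percent of reads
DEFAULT_TAU = 0.01


@dataclass
class SatFamilyTable:
    """Species x consensus abundance matrix (percent of reads uniquely mapped)."""

    abundance: pd.DataFrame      # rows = consensus ids, columns = species
    consensi: dict               # consensus id -> monomer sequence
    tau: float = DEFAULT_TAU
    grouping: dict | None = None  # consensus id -> (family, variant)
    mapping_stats: pd.DataFrame | None = None  # assigned/tie/unassigned per species

    def copy_with(self, **kw) -> "SatFamilyTable":
        from dataclasses import replace
        return replace(self, **kw)


def satellite_abundance(readsets: dict, consensi: dict, k: int = 21,
                        min_frac: float = 0.5) -> SatFamilyTable:
    """Uniquely map every read of every species against the consensus panel.

    A read counts for the single consensus sharing the greatest fraction
    of its canonical k-mers if that fraction is >= min_frac; exact
    equal-best ties count for no consensus (unique-mapping rule).
    A[species, consensus] = 100 x assigned reads / total reads.
    """
    if not consensi:
        raise ValueError("consensus panel must be nonempty")
    ids = sorted(consensi)
    refsets = {cid: reference_code_set([consensi[cid]], k, circular=True)
               for cid in ids}

    A = pd.DataFrame(0.0, index=ids, columns=sorted(readsets))
    stats = []
    for species in sorted(readsets):
        rs = readsets[species]
        block = rs.block() if isinstance(rs, ReadSet) else rs
        n = block.n_reads
        codes, ridx = matrix_codes(block.matrix, k)
        total = np.bincount(ridx, minlength=n).astype(float)
        total[total == 0] = np.nan

        fracs = np.zeros((len(ids), n))
        for ci, cid in enumerate(ids):
            member = _isin_sorted(codes, refsets[cid])
            fracs[ci] = np.bincount(ridx[member], minlength=n) / total
        fracs = np.nan_to_num(fracs, nan=0.0)
        best = fracs.max(axis=0)
        nbest = (fracs == best[None, :]).sum(axis=0)
        assigned = (best >= min_frac) & (nbest == 1)
        ties = (best >= min_frac) & (nbest > 1)
        argbest = fracs.argmax(axis=0)
        for ci, cid in enumerate(ids):
            A.loc[cid, species] = 100.0 * int((assigned & (argbest == ci)).sum()) / n
        stats.append({
            "species": species, "total": n,
            "assigned": int(assigned.sum()),
            "tie_discarded": int(ties.sum()),
            "unassigned": int(n - assigned.sum() - ties.sum()),
        })
    return SatFamilyTable(
        abundance=A, consensi=dict(consensi),
        mapping_stats=pd.DataFrame(stats).set_index("species"))


def filter_min_abundance(table: SatFamilyTable, tau: float = DEFAULT_TAU,
                         ) -> SatFamilyTable:
    """Keep consensi reaching at least ``tau`` percent in >= 1 species.

    Retained rows keep all species' values, including sub-threshold ones.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    keep = table.abundance.max(axis=1) >= tau
    kept = table.abundance.loc[keep]
    return table.copy_with(
        abundance=kept,
        consensi={cid: table.consensi[cid] for cid in kept.index},
        tau=tau)


def presence_absence(table: SatFamilyTable, tau: float | None = None,
                     ) -> pd.DataFrame:
    """Species x consensus boolean presence matrix: A >= tau percent.

    With tau = 0, any consensus with at least one mapped read is present.
    """
    t = table.tau if tau is None else tau
    if t == 0:
        return (table.abundance > 0).T
    return (table.abundance >= t).T


# --------------------------------------------------------------------------
# rotation/strand-aware consensus grouping


def _best_rotations(a: str, b: str, k: int = 8, n_candidates: int = 3) -> list[int]:
    """Candidate rotations of b maximising exact k-mer agreement with a."""
    if len(b) < k:
        return [0]
    apos = {}
    for i in range(len(a) - k + 1):
        apos.setdefault(a[i:i + k], []).append(i)
    shifts = np.zeros(len(b), dtype=int)
    bb = b + b[:k - 1]
    for j in range(len(b)):
        for i in apos.get(bb[j:j + k], ()):
            shifts[(j - i) % len(b)] += 1
    order = np.argsort(-shifts, kind="stable")
    return [int(s) for s in order[:n_candidates]]


def rotational_identity(a: str, b: str) -> float:
    """Global-alignment identity (0..1) over the best rotation and strand of b.

    Identity = matched columns / alignment length, so indel columns count
    against identity.
    """
    from .phylo import global_identity

    best = 0.0
    for cand in (b, revcomp(b)):
        for shift in _best_rotations(a, cand):
            rot = cand[shift:] + cand[:shift]
            best = max(best, global_identity(a, rot) / 100.0)
    return best


def group_families(consensi: dict, family_threshold: float = 0.60,
                   variant_threshold: float = 0.95) -> dict:
    """Single-linkage grouping of consensus monomers.

    Pairs at identity >= family_threshold share a family; within a
    family, components at >= variant_threshold define variants.  Returns
    {consensus id: (family_index, variant_index)} with 1-based indices in
    deterministic (sorted id) order.
    """
    if not (0 < family_threshold <= 1 and 0 < variant_threshold <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    if family_threshold > variant_threshold:
        raise ValueError("family_threshold must be <= variant_threshold")
    ids = sorted(consensi)
    n = len(ids)
    ident = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = rotational_identity(
                consensi[ids[i]], consensi[ids[j]])

    def components(threshold):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if ident[i, j] >= threshold:
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        return sorted(groups.values(), key=lambda g: g[0])

    grouping = {}
    for fi, fam_members in enumerate(components(family_threshold), start=1):
        sub_parent = {i: i for i in fam_members}

        def find(x):
            while sub_parent[x] != x:
                sub_parent[x] = sub_parent[sub_parent[x]]
                x = sub_parent[x]
            return x

        for ii, i in enumerate(fam_members):
            for j in fam_members[ii + 1:]:
                if ident[i, j] >= variant_threshold:
                    sub_parent[find(i)] = find(j)
        vgroups: dict[int, list[int]] = {}
        for i in fam_members:
            vgroups.setdefault(find(i), []).append(i)
        for vi, vmembers in enumerate(
                sorted(vgroups.values(), key=lambda g: g[0]), start=1):
            for i in vmembers:
                grouping[ids[i]] = (fi, vi)
    return grouping


# --------------------------------------------------------------------------
# parental signatures


@dataclass
class ParentalReport:
    polyploid: str
    contributors: dict = field(default_factory=dict)  # clade -> [satellite ids]
    diagnostic: dict = field(default_factory=dict)    # clade -> [satellite ids]
    inconclusive: bool = False


def infer_parental_signatures(pa: pd.DataFrame, polyploid: str,
                              clades: dict) -> ParentalReport:
    """Clade-diagnostic satellites present in the polyploid name its
    progenitor clades.

    ``pa`` is a species x satellite boolean matrix; ``clades`` maps clade
    names to diploid taxa.  A satellite is clade-diagnostic if present in
    >= 1 clade member and absent in all other diploids.
    """
    if len(clades) < 2:
        raise ValueError("need at least two diploid clades")
    if polyploid not in pa.index:
        raise ValueError(f"polyploid {polyploid!r} not in presence matrix")
    all_diploids = {t for taxa in clades.values() for t in taxa}
    missing = all_diploids - set(pa.index)
    if missing:
        raise ValueError(f"taxa missing from presence matrix: {sorted(missing)}")

    report = ParentalReport(polyploid=polyploid)
    any_diag = False
    for clade, taxa in clades.items():
        others = sorted(all_diploids - set(taxa))
        diag = [
            sat for sat in pa.columns
            if pa.loc[list(taxa), sat].any() and not pa.loc[others, sat].any()
        ]
        report.diagnostic[clade] = diag
        if diag:
            any_diag = True
        support = [sat for sat in diag if pa.loc[polyploid, sat]]
        if support:
            report.contributors[clade] = support
    report.inconclusive = not any_diag or not report.contributors
    return report
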