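"""Graph-based repeat discovery from sampled reads.

Reads are sampled per species scaled by ploidy and genome size, joined
into a k-mer-sharing similarity graph, and clustered as connected
components.  Each cluster gets a consensus (majority de Bruijn path), a
tandem/periodicity call, a library annotation, and a genomic abundance,
which are combined into the cross-species abundance table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from ._seq import decode, encode
from .kmers import matrix_codes, rc_codes, reference_code_set, seq_codes, _isin_sorted
from .reads import ReadBlock, ReadSet


def sample_reads_scaled(readsets: dict, base_n: int, ploidies: dict,
                        genome_sizes: dict, seed: int = 0,
                        reference: str | None = None) -> dict:
    """Sample reads per species scaled by ploidy and monoploid genome size.

    Species i receives ``round(base_n * (genome_size_i * ploidy_i/2) /
    (genome_size_ref * ploidy_ref/2))`` reads, drawn uniformly without
    replacement.  ``genome_sizes`` are monoploid (1Cx) sizes; the
    reference defaults to the first listed diploid.
    """
    if reference is None:
        reference = next(
            (s for s in readsets if ploidies.get(s, 2) == 2), None)
        if reference is None:
            raise ValueError("no diploid available as scaling reference")
    ref_weight = genome_sizes[reference] * ploidies[reference] / 2.0

    out = {}
    for i, (species, rs) in enumerate(readsets.items()):
        weight = genome_sizes[species] * ploidies[species] / 2.0
        n = int(round(base_n * weight / ref_weight))
        block = rs.block() if isinstance(rs, ReadSet) else rs
        if n > block.n_reads:
            raise ValueError(
                f"cannot sample {n} reads for {species!r}: only "
                f"{block.n_reads} available")
        rng = np.random.default_rng([int(seed), 11, i])
        idx = np.sort(rng.choice(block.n_reads, size=n, replace=False))
        out[species] = block.subset(idx)
    return out


@dataclass
class ReadCluster:
    cluster_id: str
    member_idx: np.ndarray
    member_ids: list
    abundance: float  # members / total sampled reads
    consensus: str | None = None
    consensus_circular: bool = False
    annotation: str = "non-classified"
    is_tandem: bool = False
    period: int | None = None
    secondary_periods: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return int(self.member_idx.shape[0])


def cluster_reads(block: ReadBlock, k: int = 17, min_shared: int = 5,
                  min_cluster_size: int = 5) -> list[ReadCluster]:
    """Connected components of the read graph with edges between reads
    sharing at least ``min_shared`` distinct canonical k-mers."""
    n = block.n_reads
    if n == 0:
        return []
    codes, ridx = matrix_codes(block.matrix, k)
    # deduplicate to distinct k-mers per read
    pairs = np.stack([ridx.astype(np.int64), codes.view(np.int64)], axis=1)
    pairs = np.unique(pairs, axis=0)
    ridx_u = pairs[:, 0]
    codes_u = pairs[:, 1].view(np.uint64)

    # drop k-mers seen in a single read: they cannot form edges
    uniq, inv, cnt = np.unique(codes_u, return_inverse=True, return_counts=True)
    keep = cnt[inv] > 1
    rows = ridx_u[keep]
    cols = inv[keep]
    if rows.size == 0:
        labels = np.arange(n)
    else:
        M = sp.csr_matrix(
            (np.ones(rows.size, dtype=np.int32), (rows, cols)),
            shape=(n, uniq.size))
        G = M @ M.T
        G.data[G.data < min_shared] = 0
        G.eliminate_zeros()
        _, labels = connected_components(G, directed=False)

    clusters = []
    order = []
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        if idx.size >= min_cluster_size:
            order.append(idx)
    order.sort(key=lambda idx: (-idx.size, idx[0]))
    for ci, idx in enumerate(order):
        clusters.append(ReadCluster(
            cluster_id=f"CL{ci + 1}",
            member_idx=idx,
            member_ids=[block.ids[i] for i in idx],
            abundance=idx.size / n,
        ))
    return clusters


def cluster_consensus(block: ReadBlock, cluster: ReadCluster, k: int = 17,
                      ) -> tuple[str, bool]:
    """Majority de Bruijn path consensus of a cluster.

    Starting from the highest-multiplicity k-mer, greedily extends to the
    highest-count neighbour (lexicographic tie-break); a walk returning to
    its start signals a circular (tandem) consensus.  Low-count error
    k-mers are filtered at 10% of the 90th-percentile depth.
    """
    if cluster.size == 0:
        raise ValueError("empty cluster")
    mat = block.matrix[cluster.member_idx]
    codes, _ = matrix_codes(mat, k)
    uniq, cnt = np.unique(codes, return_counts=True)
    thr = max(1, int(np.ceil(0.1 * np.percentile(cnt, 90))))
    keep = cnt >= thr
    kept = uniq[keep]
    kept_rc = rc_codes(kept, k)
    canon_map: dict[int, int] = {}
    depth: dict[int, int] = {}
    for c, r, n in zip(kept.tolist(), kept_rc.tolist(), cnt[keep].tolist()):
        canon_map[c] = c
        canon_map[r] = c
        depth[c] = int(n)

    mask = (1 << (2 * k)) - 1

    def canon(code):
        return canon_map[code]

    start = max(depth, key=lambda c: (depth[c], -c))
    path = [start]
    seen = {canon(start)}
    circular = False
    cur = start
    while True:
        cands = []
        for b in range(4):
            nxt = ((cur << 2) & mask) | b
            cn = canon_map.get(nxt)
            if cn is not None:
                cands.append((nxt, cn))
        if any(nxt == start for nxt, _ in cands) and len(path) > 1:
            circular = True
            break
        cands = [(nxt, cn) for nxt, cn in cands if cn not in seen]
        if not cands:
            break
        cands.sort(key=lambda t: (-depth[t[1]], t[0]))
        cur = cands[0][0]
        path.append(cur)
        seen.add(cands[0][1])
    if not circular:
        cur = start
        left = []
        while True:
            cands = []
            for b in range(4):
                nxt = (cur >> 2) | (b << (2 * (k - 1)))
                cn = canon_map.get(nxt)
                if cn is not None and cn not in seen:
                    cands.append((nxt, cn))
            if not cands:
                break
            cands.sort(key=lambda t: (-depth[t[1]], t[0]))
            cur = cands[0][0]
            left.append(cur)
            seen.add(cands[0][1])
        path = left[::-1] + path

    from .kmers import decode_kmer
    seq = decode_kmer(path[0], k) + "".join("ACGT"[c & 3] for c in path[1:])
    if circular:
        seq = seq[: len(path)]
    return seq, circular


@dataclass
class TandemResult:
    is_tandem: bool
    period: int | None
    secondary_periods: list = field(default_factory=list)
    mismatch: float | None = None


def detect_tandem(consensus: str, member_block: ReadBlock | None = None,
                  k: int = 17, max_mismatch: float = 0.2,
                  max_scan_len: int = 5000,
                  consensus_circular: bool | None = None) -> TandemResult:
    """Tandem periodicity of a consensus.

    The period m is the smallest circular shift whose self-mismatch
    fraction is <= max_mismatch; further qualifying shifts are recorded
    as secondary periods.  A consensus with no internal period still
    counts as tandem with period = its length when the cluster's k-mer
    structure is circular (the de Bruijn walk closes on itself), checked
    from ``consensus_circular`` or from junction-spanning k-mers in the
    member reads.
    """
    L = len(consensus)
    arr = encode(consensus)
    period = None
    if L <= max_scan_len and L >= 2:
        doubled = np.concatenate([arr, arr])
        probe = min(L, 256)  # cheap screen before the exact comparison
        for s in range(1, L):
            est = float(np.mean(arr[:probe] != doubled[s:s + probe]))
            if est > max_mismatch + 0.1:
                continue
            mm = float(np.mean(arr != doubled[s:s + L]))
            if mm <= max_mismatch:
                period = s
                break
    if period is not None:
        # secondary periods: larger qualifying shifts (multiples and the
        # complementary rotations)
        doubled = np.concatenate([arr, arr])
        secondary = [
            int(s) for s in range(period + 1, L)
            if float(np.mean(arr != doubled[s:s + L])) <= max_mismatch
        ]
        mm = float(np.mean(arr != doubled[period:period + L]))
        return TandemResult(True, period, secondary, mm)

    circular = consensus_circular
    if circular is None and member_block is not None and L >= k:
        # circular closure: nearly all k-mers spanning the end->start
        # junction must be seen in the member reads
        junction = consensus[-(k - 1):] + consensus[:k - 1]
        jcodes = np.unique(seq_codes(junction, k))
        rcodes = np.unique(matrix_codes(member_block.matrix, k)[0])
        if jcodes.size:
            circular = bool(_isin_sorted(jcodes, rcodes).mean() >= 0.8)
    if circular:
        return TandemResult(True, L, [], 0.0)
    return TandemResult(False, None, [], None)


def classify_by_library(consensus: str, library: dict, min_score: float = 0.5,
                        k: int = 17, circular: bool = True) -> str:
    """Best-scoring library label by shared canonical k-mer fraction.

    Returns 'non-classified' below min_score and 'ambiguous' on an exact
    tie of best scores.
    """
    if not library:
        raise ValueError("library must be nonempty")
    qcodes = np.unique(seq_codes(consensus, k))
    if qcodes.size == 0:
        return "non-classified"
    scores = {}
    for label, seq in library.items():
        refset = reference_code_set([seq], k, circular=circular)
        scores[label] = float(_isin_sorted(qcodes, refset).mean())
    best = max(scores.values())
    if best < min_score:
        return "non-classified"
    winners = sorted(lab for lab, s in scores.items() if s == best)
    if len(winners) > 1:
        return "ambiguous"
    return winners[0]


def comparative_abundance_table(clusters_by_species: dict) -> pd.DataFrame:
    """Family x species table of genomic abundances in percent.

    cell(family, species) = 100 x summed abundance of that species'
    clusters annotated to the family; families absent in a species are 0.
    """
    rows = sorted({c.annotation for cl in clusters_by_species.values() for c in cl})
    table = pd.DataFrame(0.0, index=rows, columns=sorted(clusters_by_species))
    for species, clusters in clusters_by_species.items():
        for c in clusters:
            table.loc[c.annotation, species] += 100.0 * c.abundance
    return table
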