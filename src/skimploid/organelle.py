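"""De novo recovery of high-copy circular sequences from reads,
long-repeat detection, and exact-anchor synteny blocks.

The assembler is a de Bruijn path walker over k-mers above a depth
threshold; it relies on organelle copy-number excess to separate the
organelle spectrum from the nuclear background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, normalize_circular, revcomp
from .kmers import matrix_codes, rc_codes
from .reads import ReadBlock, ReadSet


@dataclass
class CircularContig:
    sequence: str
    is_circular: bool
    mean_depth: float

    @property
    def normalized(self) -> str:
        """Rotation/strand-invariant canonical form."""
        if self.is_circular:
            return normalize_circular(self.sequence)
        return min(self.sequence, revcomp(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    contigs: list
    k: int
    depth_threshold: float
    diagnostics: list = field(default_factory=list)

    @property
    def primary(self) -> CircularContig:
        return max(self.contigs, key=len)

    @property
    def is_circular(self) -> bool:
        return self.primary.is_circular

    @property
    def complete(self) -> bool:
        return len(self.contigs) == 1 and self.contigs[0].is_circular


class AssemblyError(RuntimeError):
    pass


def _auto_threshold(counts: np.ndarray) -> float:
    """Valley of the k-mer depth histogram between its two largest modes.

    With a single mode (already depth-homogeneous input) fall back to a
    quarter of the modal depth.
    """
    hist = np.bincount(counts)
    hist[0] = 0
    if hist.size <= 2:
        return 1.0
    sm = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    peaks = [i for i in range(1, sm.size - 1)
             if sm[i] >= sm[i - 1] and sm[i] >= sm[i + 1] and sm[i] > 0]
    if not peaks:
        return 1.0
    peaks.sort(key=lambda i: -sm[i])
    if len(peaks) < 2 or peaks[1] < 2:
        mode = peaks[0]
        return max(2.0, mode / 4.0)
    p1, p2 = sorted(peaks[:2])
    if p2 - p1 < 2:
        return max(2.0, p2 / 4.0)
    valley = p1 + int(np.argmin(sm[p1:p2 + 1]))
    # cap well below the high-copy mode so stochastic depth dips do not
    # fragment the walk
    return float(max(2.0, min(valley, np.ceil(0.35 * p2))))


def assemble_circular(reads, k: int = 31, depth_threshold="auto") -> Assembly:
    """Walk the above-threshold de Bruijn graph into (circular) contigs.

    Returns an :class:`Assembly`; ``assembly.primary`` is the longest
    contig.  A branch above threshold ends the current walk and is
    reported in the diagnostics (partial contigs are still returned).
    """
    if isinstance(reads, ReadSet):
        mat = reads.interleaved()
    elif isinstance(reads, ReadBlock):
        mat = reads.matrix
    elif isinstance(reads, np.ndarray):
        mat = reads
    else:
        raise TypeError("reads must be a ReadSet, ReadBlock or matrix")

    codes, _ = matrix_codes(mat, k)
    if codes.size == 0:
        raise AssemblyError("no k-mers in input reads")
    uniq, cnt = np.unique(codes, return_counts=True)

    if depth_threshold == "auto":
        thr = _auto_threshold(cnt)
    else:
        thr = float(depth_threshold)
    keep = cnt >= thr
    if not keep.any():
        raise AssemblyError(
            f"insufficient depth: no k-mer reaches threshold {thr}")
    kept_codes = uniq[keep]  # canonical
    kept_rc = rc_codes(kept_codes, k)
    canon_map: dict[int, int] = {}  # directed code -> canonical code
    depth: dict[int, int] = {}
    for c, r, n in zip(kept_codes.tolist(), kept_rc.tolist(),
                       cnt[keep].tolist()):
        canon_map[c] = c
        canon_map[r] = c
        depth[c] = int(n)

    mask = (1 << (2 * k)) - 1
    diagnostics: list[str] = []
    contigs: list[CircularContig] = []
    visited: set[int] = set()

    # deterministic seed order: highest count, then smallest code
    order = sorted(depth, key=lambda c: (-depth[c], c))

    def extensions(code: int, forward: bool) -> list[int]:
        out = []
        for b in range(4):
            if forward:
                nxt = ((code << 2) & mask) | b
            else:
                nxt = (code >> 2) | (b << (2 * (k - 1)))
            if nxt in canon_map:
                out.append(nxt)
        return out

    for seed in order:
        if seed in visited:
            continue
        path = [seed]
        seen = {canon_map[seed]}
        circular = False
        # extend right
        cur = seed
        while True:
            exts = extensions(cur, True)
            nxt_new = [e for e in exts if canon_map[e] not in seen]
            if seed in exts and len(path) > 1:
                circular = True
                break
            if len(nxt_new) != 1:
                if len(nxt_new) > 1:
                    diagnostics.append(
                        f"branch after {len(path)} nodes ({len(nxt_new)} extensions)")
                break
            cur = nxt_new[0]
            path.append(cur)
            seen.add(canon_map[cur])
        if not circular:
            # extend left from the seed
            cur = seed
            left: list[int] = []
            while True:
                exts = extensions(cur, False)
                nxt_new = [e for e in exts if canon_map[e] not in seen]
                if len(nxt_new) != 1:
                    if len(nxt_new) > 1:
                        diagnostics.append(
                            f"left branch after {len(left)} nodes")
                    break
                cur = nxt_new[0]
                left.append(cur)
                seen.add(canon_map[cur])
            path = left[::-1] + path

        visited.update(canon_map[c] for c in path)
        from .kmers import decode_kmer
        seq = decode_kmer(path[0], k) + "".join(
            "ACGT"[c & 3] for c in path[1:])
        if circular:
            seq = seq[: len(path)]  # trim the wrapped (k-1) overlap implicitly
        md = float(np.mean([depth[canon_map[c]] for c in path]))
        contigs.append(CircularContig(seq, circular, md))

    contigs.sort(key=lambda c: -len(c.sequence))
    # drop tiny fragments (error-induced stubs)
    main = [c for c in contigs if len(c.sequence) >= 2 * k] or contigs[:1]
    return Assembly(contigs=main, k=k, depth_threshold=thr,
                    diagnostics=diagnostics)


# --------------------------------------------------------------------------
# long repeat pairs


@dataclass
class RepeatPair:
    start1: int
    start2: int
    length: int
    identity: float
    orientation: str = "+"


def _anchor_runs(pairs_by_diag: dict, anchor_len: int, merge_gap: int):
    """Merge same-diagonal anchors (sorted starts) into candidate runs."""
    runs = []
    for d, starts in pairs_by_diag.items():
        starts = sorted(set(starts))
        lo = hi = starts[0]
        for s in starts[1:]:
            if s - hi <= merge_gap:
                hi = s
            else:
                runs.append((d, lo, hi + anchor_len))
                lo = hi = s
        runs.append((d, lo, hi + anchor_len))
    return runs


def find_long_repeats(seq: str, min_len: int = 500, min_identity: float = 0.95,
                      anchor_len: int = 21, merge_gap: int = 200,
                      max_kmer_occurrences: int = 50) -> list[RepeatPair]:
    """Maximal direct self-repeats longer than min_len at identity above
    min_identity (both thresholds strict, matching the reporting rule
    '>95% similarity and >500 bp').

    Seeded with exact ``anchor_len``-mer matches, merged along diagonals,
    extended with an X-drop heuristic, scored by exact (gap-free) identity.
    """
    if len(seq) < min_len:
        raise ValueError("sequence shorter than min_len")
    arr = encode(seq)
    n = arr.shape[0]

    # positions of each forward k-mer
    m = n - anchor_len + 1
    codes = np.zeros(m, dtype=np.uint64)
    a = (arr & np.uint8(3)).astype(np.uint64)
    bad = (arr > 3).astype(np.int32)
    nbad = np.zeros(m, dtype=np.int32)
    for j in range(anchor_len):
        codes = (codes << np.uint64(2)) | a[j:j + m]
        nbad += bad[j:j + m]
    valid = nbad == 0

    order = np.argsort(codes[valid], kind="stable")
    pos = np.nonzero(valid)[0][order]
    sorted_codes = codes[valid][order]
    # group duplicate k-mers
    by_diag: dict[int, list[int]] = {}
    start = 0
    for end in range(1, sorted_codes.size + 1):
        if end == sorted_codes.size or sorted_codes[end] != sorted_codes[start]:
            group = pos[start:end]
            if 1 < group.size <= max_kmer_occurrences:
                g = np.sort(group)
                for x in range(g.size):
                    for y in range(x + 1, g.size):
                        d = int(g[y] - g[x])
                        by_diag.setdefault(d, []).append(int(g[x]))
            start = end
    if not by_diag:
        return []

    out = []
    reported: set[tuple] = set()
    for d, lo, hi in _anchor_runs(by_diag, anchor_len, merge_gap):
        lo, hi = _xdrop_extend(arr, d, lo, hi)
        length = hi - lo
        if length <= min_len:
            continue
        seg1 = arr[lo:hi]
        seg2 = arr[lo + d:hi + d]
        ident = float(np.mean(seg1 == seg2))
        if ident <= min_identity:
            continue
        key = (lo, lo + d)
        if any(abs(key[0] - r[0]) < anchor_len and abs(key[1] - r[1]) < anchor_len
               for r in reported):
            continue
        reported.add(key)
        out.append(RepeatPair(start1=lo, start2=lo + d, length=length,
                              identity=ident))
    out.sort(key=lambda r: (r.start1, r.start2))
    return out


def _xdrop_extend(arr: np.ndarray, d: int, lo: int, hi: int,
                  mismatch_cost: float = 19.0, xdrop: float = 40.0):
    """Extend [lo, hi) along diagonal d while identity stays near threshold.

    Score: +1 per match, -mismatch_cost per mismatch (neutral at the 95%
    identity boundary); extension stops when the running score falls
    ``xdrop`` below its maximum, and trims back to the maximum.
    """
    n = arr.shape[0]

    def walk(rng_iter):
        best, score, best_pos = 0.0, 0.0, None
        for i in rng_iter:
            j = i + d
            if j < 0 or j >= n or i < 0 or i >= n:
                break
            score += 1.0 if arr[i] == arr[j] else -mismatch_cost
            if score > best:
                best, best_pos = score, i
            if best - score > xdrop:
                break
        return best_pos

    right = walk(range(hi, n))
    if right is not None:
        hi = right + 1
    left = walk(range(lo - 1, -1, -1))
    if left is not None:
        lo = left
    return lo, hi


# --------------------------------------------------------------------------
# synteny blocks


@dataclass
class SyntenyBlock:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str
    n_anchors: int


def _unique_kmer_positions(arr: np.ndarray, k: int) -> dict:
    """canonical code -> (position, is_forward) for k-mers occurring once."""
    m = arr.shape[0] - k + 1
    if m <= 0:
        return {}
    a = (arr & np.uint8(3)).astype(np.uint64)
    bad = (arr > 3).astype(np.int32)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    nbad = np.zeros(m, dtype=np.int32)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | a[j:j + m]
        rev |= (np.uint64(3) - a[j:j + m]) << np.uint64(2 * j)
        nbad += bad[j:j + m]
    canon = np.minimum(fwd, rev)
    valid = nbad == 0
    canon = canon[valid]
    fwd_is_canon = fwd[valid] == canon
    positions = np.nonzero(valid)[0]
    uniq, idx, cnt = np.unique(canon, return_index=True, return_counts=True)
    single = cnt == 1
    return {
        int(c): (int(positions[i]), bool(fwd_is_canon[i]))
        for c, i in zip(uniq[single], idx[single])
    }


def synteny_blocks(seqA: str, seqB: str, anchor_len: int = 21,
                   max_gap: int = 1000) -> list[SyntenyBlock]:
    """Chain shared unique exact anchors into collinear same-orientation
    blocks with anchor gaps <= max_gap on both genomes."""
    if not seqA or not seqB:
        raise ValueError("both sequences must be nonempty")
    mapA = _unique_kmer_positions(encode(seqA), anchor_len)
    mapB = _unique_kmer_positions(encode(seqB), anchor_len)
    anchors = []
    for code, (pa, fa) in mapA.items():
        hit = mapB.get(code)
        if hit is None:
            continue
        pb, fb = hit
        anchors.append((pa, pb, "+" if fa == fb else "-"))
    anchors.sort()
    if not anchors:
        return []

    blocks = []
    cur = [anchors[0]]
    for a in anchors[1:]:
        pa, pb, o = a
        lpa, lpb, lo = cur[-1]
        gap_a = pa - lpa
        if o == lo and gap_a <= max_gap:
            gap_b = (pb - lpb) if o == "+" else (lpb - pb)
            if 0 < gap_b <= max_gap:
                cur.append(a)
                continue
        blocks.append(cur)
        cur = [a]
    blocks.append(cur)

    out = []
    for chain in blocks:
        pas = [c[0] for c in chain]
        pbs = [c[1] for c in chain]
        o = chain[0][2]
        out.append(SyntenyBlock(
            a_start=min(pas), a_end=max(pas) + anchor_len,
            b_start=min(pbs), b_end=max(pbs) + anchor_len,
            orientation=o, n_anchors=len(chain)))
    return out
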