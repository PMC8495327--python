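"""Canonical k-mer machinery and compartment-wise read classification.

K-mers are packed 2 bits/base into uint64 codes (k <= 31).  A canonical
k-mer is the minimum of a window's forward code and the code of its
reverse complement; windows containing non-ACGT symbols are skipped.
k must be odd so that no k-mer equals its own reverse complement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._seq import encode, revcomp
from .reads import ReadBlock, ReadSet

#: classification bins; every read lands in exactly one
BIN_NAMES = (
    "chloroplast",
    "mitochondrial",
    "satellite",
    "rDNA",
    "repeat_clustered",
    "unassigned",
)


def _check_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or k < 1 or k > 31:
        raise ValueError(f"k must be an integer in [1, 31], got {k}")
    if k % 2 == 0:
        raise ValueError(f"k must be odd to avoid self-reverse-complement k-mers, got {k}")


def _window_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes of all windows of an encoded array.

    Returns (codes, valid) of length len(arr)-k+1; ``valid`` marks windows
    free of non-ACGT symbols.  Invalid windows carry arbitrary codes.
    """
    n = arr.shape[0]
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    a = arr.astype(np.uint64)
    bad = (arr > 3).astype(np.int32)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    nbad = np.zeros(m, dtype=np.int32)
    b = a & np.uint64(3)  # mask invalid to in-range values; tracked via nbad
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | b[j:j + m]
        rev |= (np.uint64(3) - b[j:j + m]) << np.uint64(2 * j)
        nbad += bad[j:j + m]
    return np.minimum(fwd, rev), nbad == 0


def seq_codes(seq, k: int) -> np.ndarray:
    """Canonical k-mer codes (with multiplicity) of one sequence."""
    _check_k(k)
    arr = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    codes, valid = _window_codes(arr, k)
    return codes[valid]


def matrix_codes(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes of every row of a read matrix.

    Returns (codes, read_idx): flat arrays where read_idx[i] is the row of
    origin of codes[i].  Windows spanning row boundaries are excluded.
    """
    _check_k(k)
    n, L = mat.shape
    if n == 0 or L < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    padded = np.full((n, L + 1), 255, dtype=np.uint8)
    padded[:, :L] = mat
    flat = padded.ravel()
    codes, valid = _window_codes(flat, k)
    pos = np.nonzero(valid)[0]
    return codes[valid], pos // (L + 1)


_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse-complement of packed k-mer codes."""
    mask = np.uint64((1 << (2 * k)) - 1)
    x = (~codes.astype(np.uint64)) & mask  # complement every base
    x = x << np.uint64(64 - 2 * k)         # left-justify
    x = ((x & _M2) << np.uint64(2)) | ((x >> np.uint64(2)) & _M2)
    x = ((x & _M4) << np.uint64(4)) | ((x >> np.uint64(4)) & _M4)
    return x.byteswap()


def decode_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k):
        out.append("ACGT"[(int(code) >> (2 * (k - 1 - j))) & 3])
    return "".join(out)


def canonical(kmer: str) -> str:
    return min(kmer, revcomp(kmer))


def canonical_kmers(seq: str, k: int) -> Counter:
    """Multiset of canonical k-mers of a sequence (string form)."""
    codes = seq_codes(seq, k)
    return Counter(decode_kmer(c, k) for c in codes)


@dataclass
class KmerProfile:
    """Filtered canonical k-mer spectrum of a read set or sequence."""

    k: int
    codes: np.ndarray  # sorted distinct canonical codes surviving min_count
    counts: np.ndarray
    label: str = ""

    @property
    def n_distinct(self) -> int:
        return int(self.codes.shape[0])

    def code_set(self) -> np.ndarray:
        return self.codes


def _profile_from_codes(codes: np.ndarray, k: int, min_count: int, label: str) -> KmerProfile:
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    uniq, cnt = np.unique(codes, return_counts=True)
    keep = cnt >= min_count
    return KmerProfile(k=k, codes=uniq[keep], counts=cnt[keep], label=label)


def build_profile(reads, k: int = 21, min_count: int = 1, label: str = "") -> KmerProfile:
    """KmerProfile of a ReadSet, ReadBlock, read matrix, or list of sequences."""
    if isinstance(reads, ReadSet):
        reads = reads.block()
    if isinstance(reads, ReadBlock):
        if not label:
            label = reads.sample
        codes, _ = matrix_codes(reads.matrix, k)
    elif isinstance(reads, np.ndarray) and reads.ndim == 2:
        codes, _ = matrix_codes(reads, k)
    else:  # iterable of sequences
        parts = [seq_codes(s, k) for s in reads]
        codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    return _profile_from_codes(codes, k, min_count, label)


def profile_from_sequence(seq, k: int = 21, min_count: int = 1, label: str = "") -> KmerProfile:
    return _profile_from_codes(seq_codes(seq, k), k, min_count, label)


def reference_code_set(seqs, k: int, circular: bool = True) -> np.ndarray:
    """Sorted distinct canonical codes of a set of reference sequences.

    Circular references are doubled so that origin-spanning k-mers are
    represented (satellite monomers and organelle circles).
    """
    parts = []
    for s in seqs:
        if isinstance(s, np.ndarray):
            from ._seq import decode as _dec

            s = _dec(s)
        if circular and len(s) >= k:
            s = s + s[:k - 1]
        parts.append(seq_codes(s, k))
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def _isin_sorted(values: np.ndarray, sorted_ref: np.ndarray) -> np.ndarray:
    if sorted_ref.size == 0:
        return np.zeros(values.shape, dtype=bool)
    idx = np.searchsorted(sorted_ref, values)
    idx[idx == sorted_ref.size] = sorted_ref.size - 1
    return sorted_ref[idx] == values


@dataclass
class CompartmentBins:
    """Per-read compartment assignment over a ReadBlock."""

    block: ReadBlock
    assignment: np.ndarray  # index into bin_names per read
    best_frac: np.ndarray
    bin_names: tuple = BIN_NAMES

    def counts(self) -> dict:
        out = {name: 0 for name in self.bin_names}
        for b, c in zip(*np.unique(self.assignment, return_counts=True)):
            out[self.bin_names[b]] = int(c)
        return out

    def bin_of(self, read_index: int) -> str:
        return self.bin_names[self.assignment[read_index]]

    def reads_in(self, name: str) -> ReadBlock:
        """ReadBlock of reads in the named bin; 'total' returns everything."""
        if name == "total":
            return self.block
        b = self.bin_names.index(name)
        idx = np.nonzero(self.assignment == b)[0]
        return self.block.subset(idx)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "read_id": self.block.ids,
                "bin": [self.bin_names[a] for a in self.assignment],
                "best_frac": self.best_frac,
            }
        )


def classify_reads(
    reads,
    references: dict,
    k: int = 21,
    min_frac: float = 0.5,
    circular: bool = True,
) -> CompartmentBins:
    """Assign each read to the reference class sharing most of its k-mers.

    ``references`` maps bin names (any subset of BIN_NAMES except
    'unassigned') to lists of reference sequences.  A read is assigned to
    the class with the greatest shared canonical k-mer fraction if that
    fraction is >= min_frac; exact ties go to 'unassigned'.  Mates are
    classified independently.
    """
    if not references or all(len(v) == 0 for v in references.values()):
        raise ValueError("references must be non-empty")
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    for name in references:
        if name not in BIN_NAMES or name == "unassigned":
            raise ValueError(f"unknown reference class: {name}")

    if isinstance(reads, ReadSet):
        block = reads.block()
    elif isinstance(reads, ReadBlock):
        block = reads
    else:
        raise TypeError("reads must be a ReadSet or ReadBlock")

    n = block.n_reads
    codes, ridx = matrix_codes(block.matrix, k)
    total = np.bincount(ridx, minlength=n).astype(float)
    total[total == 0] = np.nan  # reads shorter than k get no assignment

    class_names = [name for name in references if len(references[name]) > 0]
    fracs = np.zeros((len(class_names), n))
    for ci, name in enumerate(class_names):
        refset = reference_code_set(references[name], k, circular=circular)
        member = _isin_sorted(codes, refset)
        shared = np.bincount(ridx[member], minlength=n).astype(float)
        fracs[ci] = shared / total

    fracs = np.nan_to_num(fracs, nan=0.0)
    best = fracs.max(axis=0)
    nbest = (fracs == best[None, :]).sum(axis=0)
    argbest = fracs.argmax(axis=0)

    assignment = np.full(n, BIN_NAMES.index("unassigned"), dtype=np.int8)
    ok = (best >= min_frac) & (nbest == 1)
    for ci, name in enumerate(class_names):
        assignment[ok & (argbest == ci)] = BIN_NAMES.index(name)
    return CompartmentBins(block=block, assignment=assignment, best_frac=best)
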