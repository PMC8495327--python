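"""Low-level nucleotide sequence utilities.

Sequences are handled in two representations: Python strings over ACGT
(user-facing) and numpy uint8 arrays with A=0, C=1, G=2, T=3 and 255 for
any other symbol (internal, vectorised).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
INVALID = np.uint8(255)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (255 = non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(arr: np.ndarray) -> str:
    """Decode a uint8 array back to a string; invalid positions become N."""
    arr = np.asarray(arr, dtype=np.uint8)
    out = np.full(arr.shape, ord("N"), dtype=np.uint8)
    ok = arr < 4
    out[ok] = _DECODE[arr[ok]]
    return out.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded array; invalid stays invalid."""
    out = arr[::-1].copy()
    ok = out < 4
    out[ok] = 3 - out[ok]
    return out


def random_seq_arr(rng: np.random.Generator, length: int, gc: float = 0.5) -> np.ndarray:
    """Random encoded sequence with the given expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def jc_substitution_probability(d: float) -> float:
    """Probability a site differs after Jukes-Cantor divergence d (subs/site)."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def mutate_jc(arr: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Apply Jukes-Cantor substitutions for branch length d (in place on a copy)."""
    if d < 0:
        raise ValueError(f"negative branch length: {d}")
    out = arr.copy()
    if d == 0:
        return out
    p = jc_substitution_probability(d)
    hit = rng.random(out.shape[0]) < p
    idx = np.nonzero(hit & (out < 4))[0]
    if idx.size:
        out[idx] = (out[idx] + rng.integers(1, 4, size=idx.size, dtype=np.uint8)) % 4
    return out


def add_sequencing_errors(mat: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitution errors on a (n_reads, read_len) encoded matrix."""
    out = mat.copy()
    if error_rate <= 0:
        return out
    hit = rng.random(out.shape) < error_rate
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


def min_rotation(seq: str) -> str:
    """Lexicographically minimal rotation (Booth's algorithm)."""
    s = seq + seq
    n = len(seq)
    f = [-1] * len(s)
    kk = 0
    for j in range(1, len(s)):
        sj = s[j]
        i = f[j - kk - 1]
        while i != -1 and sj != s[kk + i + 1]:
            if sj < s[kk + i + 1]:
                kk = j - i - 1
            i = f[i]
        if sj != s[kk + i + 1]:
            if sj < s[kk]:
                kk = j
            f[j - kk] = -1
        else:
            f[j - kk] = i + 1
    return s[kk:kk + n]


def normalize_circular(seq: str) -> str:
    """Canonical form of a circular sequence: minimal rotation over both strands."""
    return min(min_rotation(seq), min_rotation(revcomp(seq)))


def write_fasta(path, records: dict) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
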