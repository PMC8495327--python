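"""Read containers and FASTQ I/O.

A :class:`ReadSet` holds paired reads of a single sample as two encoded
matrices of shape (n_pairs, read_len).  Downstream operations that work on
arbitrary read subsets (compartment bins, sampled reads, cluster members)
use the lighter :class:`ReadBlock`, a flat matrix of single reads plus ids.

Read ordering convention: pair i yields mate ids ``{sample}:{i}/1`` and
``{sample}:{i}/2``; the interleaved single-read order is
r1[0], r2[0], r1[1], r2[1], ...
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import decode, encode


@dataclass
class ReadBlock:
    """A bag of equal-length single reads from one sample."""

    sample: str
    matrix: np.ndarray  # (n_reads, read_len) uint8
    ids: list[str]

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]

    @property
    def read_len(self) -> int:
        return self.matrix.shape[1]

    def subset(self, idx) -> "ReadBlock":
        idx = np.asarray(idx)
        return ReadBlock(self.sample, self.matrix[idx], [self.ids[i] for i in idx])

    def sequences(self) -> list[str]:
        return [decode(row) for row in self.matrix]


@dataclass
class ReadSet:
    """Paired reads of one sample."""

    sample: str
    r1: np.ndarray  # (n_pairs, read_len) uint8
    r2: np.ndarray

    def __post_init__(self):
        if self.r1.shape != self.r2.shape:
            raise ValueError("mate matrices must have identical shape")

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    @property
    def n_reads(self) -> int:
        return 2 * self.n_pairs

    @property
    def read_len(self) -> int:
        return self.r1.shape[1]

    def pair_ids(self) -> list[str]:
        return [f"{self.sample}:{i}" for i in range(self.n_pairs)]

    def mate_ids(self) -> list[str]:
        out = []
        for i in range(self.n_pairs):
            out.append(f"{self.sample}:{i}/1")
            out.append(f"{self.sample}:{i}/2")
        return out

    def interleaved(self) -> np.ndarray:
        """(2*n_pairs, read_len) matrix in the canonical interleaved order."""
        out = np.empty((self.n_reads, self.read_len), dtype=np.uint8)
        out[0::2] = self.r1
        out[1::2] = self.r2
        return out

    def block(self) -> ReadBlock:
        return ReadBlock(self.sample, self.interleaved(), self.mate_ids())

    def write_fastq(self, path1, path2) -> None:
        qual = "I" * self.read_len  # constant Phred 40
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for i in range(self.n_pairs):
                pid = f"{self.sample}:{i}"
                f1.write(f"@{pid}/1\n{decode(self.r1[i])}\n+\n{qual}\n")
                f2.write(f"@{pid}/2\n{decode(self.r2[i])}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path1, path2, sample: str) -> "ReadSet":
        r1 = _read_fastq_matrix(path1)
        r2 = _read_fastq_matrix(path2)
        return cls(sample, r1, r2)


def _read_fastq_matrix(path) -> np.ndarray:
    seqs = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            seqs.append(encode(seq))
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    return np.vstack(seqs)


def concat_blocks(blocks: list[ReadBlock], sample: str | None = None) -> ReadBlock:
    if not blocks:
        raise ValueError("no blocks to concatenate")
    name = sample if sample is not None else blocks[0].sample
    mat = np.vstack([b.matrix for b in blocks])
    ids: list[str] = []
    for b in blocks:
        ids.extend(b.ids)
    return ReadBlock(name, mat, ids)
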