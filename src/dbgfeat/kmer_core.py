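"""Canonical k-mer extraction, counting, and filtering from per-sample reads.

Each sample is reduced to its spectrum of canonical k-mers (the
lexicographic minimum of a k-mer and its reverse complement).  k defaults
to 31 and must be odd — an odd k can never equal its own reverse
complement, so every k-mer has a unique strand-neutral representative.
Singleton k-mers (count 1) are discarded by default, which removes most
isolated sequencing-error k-mers without a quality model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import io as _io
from ._encoding import (
    canonical_form,
    decode_kmer,
    encode_canonical_windows,
    encode_kmer,
    canonical_code,
)

__all__ = [
    "KmerCountTable",
    "canonical_form",
    "count_kmers",
    "count_sample_file",
    "kmer_set",
]

DEFAULT_K = 31
DEFAULT_MIN_COUNT = 2


def _validate_k(k: int) -> None:
    if k < 3 or k % 2 == 0:
        raise ValueError(f"k must be odd and >= 3, got {k}")
    if k > 31:
        raise ValueError(f"k must be <= 31, got {k}")


@dataclass
class KmerCountTable:
    """Per-sample map from canonical k-mer to multiplicity.

    Stored internally as a sorted ``uint64`` code array with parallel
    counts; the numeric code order equals lexicographic k-mer order, so
    serialized dumps are lexicographically sorted for free.
    """

    k: int
    sample_id: str
    codes: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    min_count: int = 1

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes and counts must be parallel arrays")

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str) -> bool:
        return self.get(kmer) > 0

    def get(self, kmer: str) -> int:
        code = canonical_code(encode_kmer(kmer), self.k)
        i = np.searchsorted(self.codes, np.uint64(code))
        if i < self.codes.size and int(self.codes[i]) == code:
            return int(self.counts[i])
        return 0

    def kmer_set(self) -> set[str]:
        """The sample's canonical k-mer set (strings)."""
        return {decode_kmer(int(c), self.k) for c in self.codes}

    def to_dict(self) -> dict[str, int]:
        return {
            decode_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }

    @classmethod
    def from_dict(
        cls, counts: Mapping[str, int], k: int | None = None, sample_id: str = "sample"
    ) -> "KmerCountTable":
        if counts:
            ks = {len(s) for s in counts}
            if len(ks) != 1:
                raise ValueError("all k-mers must share one k")
            k_inferred = ks.pop()
            if k is None:
                k = k_inferred
            elif k != k_inferred:
                raise ValueError(f"k-mers of length {k_inferred} but k={k}")
        elif k is None:
            raise ValueError("k required for an empty table")
        by_code: dict[int, int] = {}
        for s, n in counts.items():
            code = canonical_code(encode_kmer(s), k)
            by_code[code] = by_code.get(code, 0) + n  # strand-collapsed keys merge
        codes = np.array(sorted(by_code), dtype=np.uint64)
        cnt = np.array([by_code[int(c)] for c in codes], dtype=np.int64)
        return cls(k=k, sample_id=sample_id, codes=codes, counts=cnt)

    def write_tsv(self, path: str | Path) -> None:
        """Two-column TSV (kmer, count), lexicographically sorted."""
        with open(path, "w", encoding="utf-8") as fh:
            for c, n in zip(self.codes, self.counts):
                fh.write(f"{decode_kmer(int(c), self.k)}\t{int(n)}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, k: int | None = None, sample_id: str | None = None) -> "KmerCountTable":
        counts: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                km, n = line.rstrip("\n").split("\t")
                counts[km] = int(n)
        sid = sample_id if sample_id is not None else Path(path).stem
        return cls.from_dict(counts, k=k, sample_id=sid)


def _count_from_code_chunks(
    chunks: list[np.ndarray], k: int, min_count: int, sample_id: str
) -> KmerCountTable:
    if chunks:
        allc = np.concatenate(chunks)
    else:
        allc = np.empty(0, dtype=np.uint64)
    codes, counts = np.unique(allc, return_counts=True)
    keep = counts >= min_count
    return KmerCountTable(
        k=k,
        sample_id=sample_id,
        codes=codes[keep],
        counts=counts[keep].astype(np.int64),
        min_count=min_count,
    )


def count_kmers(
    reads: Iterable[str],
    k: int = DEFAULT_K,
    min_count: int = DEFAULT_MIN_COUNT,
    sample_id: str = "sample",
) -> KmerCountTable:
    """Count canonical k-mers over a collection of reads.

    Windows containing a non-ACGT character are skipped (only those
    windows); entries with multiplicity below *min_count* are dropped.
    If every read is shorter than k the result is empty and a warning is
    emitted.
    """
    _validate_k(k)
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    chunks: list[np.ndarray] = []
    n_reads = 0
    any_long_enough = False
    for read in reads:
        n_reads += 1
        if len(read) >= k:
            any_long_enough = True
            chunks.append(encode_canonical_windows(read, k))
    if n_reads == 0:
        raise ValueError("no reads provided")
    if not any_long_enough:
        warnings.warn(
            f"k={k} is longer than every read of sample {sample_id!r}; empty table",
            stacklevel=2,
        )
    return _count_from_code_chunks(chunks, k, min_count, sample_id)


def count_sample_file(
    path: str | Path,
    k: int = DEFAULT_K,
    min_count: int = DEFAULT_MIN_COUNT,
    sample_id: str | None = None,
) -> KmerCountTable:
    """Count canonical k-mers of one FASTA/FASTQ(.gz) sample file."""
    sid = sample_id
    if sid is None:
        name = Path(path).name
        for ext in _io.READ_EXTENSIONS:
            if name.endswith(ext):
                sid = name[: -len(ext)]
                break
        else:
            sid = Path(path).stem
    return count_kmers(_io.iter_reads(path), k=k, min_count=min_count, sample_id=sid)


def kmer_set(table: KmerCountTable) -> set[str]:
    """Key set of a count table — the sample's canonical k-mer set."""
    return table.kmer_set()
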