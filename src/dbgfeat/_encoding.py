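"""2-bit k-mer codecs shared by the counting, selection and graph layers.

A k-mer over {A,C,G,T} with k <= 31 is packed into a ``uint64`` with A=0,
C=1, G=2, T=3, most significant pair first.  Because the base order matches
the alphabetical order, the numeric order of codes of equal length is
exactly the lexicographic order of the k-mer strings, so the canonical
(strand-neutral) representative ``min(kmer, revcomp(kmer))`` is simply the
numeric minimum of the forward and reverse-complement codes.

All public surfaces of the package speak k-mer strings; these integer
routines are the internal representation only.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

#: byte -> 2-bit base value, 255 for anything that is not ACGT (case-insensitive)
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i

_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")

_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per-base)."""
    return seq.translate(_RC_TABLE)[::-1]


def is_valid_dna(seq: str) -> bool:
    return all(c in "ACGTacgt" for c in seq)


def canonical_form(seq: str) -> str:
    """Canonical (strand-neutral) form: min of *seq* and its reverse complement.

    Raises ``ValueError`` on ambiguous characters or empty input; callers
    that slide windows over reads catch this and skip the window.
    """
    if not seq:
        raise ValueError("empty sequence has no canonical form")
    if not is_valid_dna(seq):
        raise ValueError(f"ambiguous character in k-mer {seq!r}")
    s = seq.upper()
    rc = revcomp(s)
    return s if s <= rc else rc


def _check_k(k: int) -> None:
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")


def rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of packed k-mer codes."""
    _check_k(k)
    x = np.asarray(codes, dtype=np.uint64)
    x = ~x  # complement: each 2-bit group b -> 3-b
    # reverse the 2-bit groups inside each 64-bit word
    x = ((x & _M2) << np.uint64(2)) | ((x >> np.uint64(2)) & _M2)
    x = ((x & _M4) << np.uint64(4)) | ((x >> np.uint64(4)) & _M4)
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def rc_code(code: int, k: int) -> int:
    """Scalar reverse complement of a packed k-mer code."""
    x = code ^ ((1 << (2 * k)) - 1)
    r = 0
    for _ in range(k):
        r = (r << 2) | (x & 3)
        x >>= 2
    return r


def canonical_code(code: int, k: int) -> int:
    rc = rc_code(code, k)
    return code if code <= rc else rc


def encode_kmer(seq: str) -> int:
    """Pack a clean ACGT string into its (non-canonical) integer code."""
    v = 0
    for c in seq.upper():
        b = "ACGT".find(c)
        if b < 0:
            raise ValueError(f"ambiguous character in k-mer {seq!r}")
        v = (v << 2) | b
    return v


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def decode_codes(codes: np.ndarray, k: int) -> list[str]:
    return [decode_kmer(int(c), k) for c in np.asarray(codes)]


def encode_canonical_windows(seq: str, k: int) -> np.ndarray:
    """Canonical codes of every valid length-k window of *seq*.

    Windows containing a non-ACGT character are dropped (only those
    windows, not the whole read).  Returns an empty array when the
    sequence is shorter than k.
    """
    _check_k(k)
    a8 = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = a8.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = a8 == 255
    a = np.where(bad, 0, a8).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        col = a[j : j + n]
        fwd = (fwd << np.uint64(2)) | col
        rc |= (three - col) << np.uint64(2 * j)
    canon = np.minimum(fwd, rc)
    if bad.any():
        # a window starting at i is bad iff any of bases i..i+k-1 is bad
        cs = np.concatenate(([0], np.cumsum(bad.astype(np.int64))))
        bad_win = (cs[k:] - cs[:-k]) > 0
        canon = canon[~bad_win]
    return canon
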