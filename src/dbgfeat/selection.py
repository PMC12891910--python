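"""Group-specific k-mer selection.

Three strategies pick "pivot" k-mers that distinguish one category of
samples from the rest:

* ``select_unique`` — k-mers present in at least G samples of the target
  category and absent from every other sample; G can be chosen
  automatically to land in a usable feature range (~1000–10000).
* ``select_chisq`` — a 2x2 presence/absence chi-squared test per k-mer
  (target vs pooled rest) with Yates's continuity correction and
  Bonferroni control over the number of k-mers tested.
* ``select_stats`` — conjunction of the chi-squared presence test and a
  Mann–Whitney U test on per-sample abundances (absent = 0), both
  Bonferroni-corrected.

All modes keep only k-mers over-represented in the target category —
selected k-mers are assigned to a category, which is only coherent for
enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats as sps

from ._encoding import canonical_code, decode_kmer, encode_kmer
from .kmer_core import KmerCountTable

__all__ = [
    "GroupLabels",
    "PresenceMatrix",
    "SelectedKmers",
    "build_presence_matrix",
    "select_unique",
    "auto_select_G",
    "chisq_yates",
    "select_chisq",
    "mann_whitney_u",
    "select_stats",
]


@dataclass
class GroupLabels:
    """Sample → category assignment with a fixed category order."""

    assignment: dict[str, str]
    categories: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.categories is None:
            seen: list[str] = []
            for c in self.assignment.values():
                if c not in seen:
                    seen.append(c)
            self.categories = seen
        if len(self.categories) != len(set(self.categories)):
            raise ValueError("duplicate categories")
        if len(self.categories) < 2:
            raise ValueError("at least 2 categories required")
        extra = set(self.assignment.values()) - set(self.categories)
        if extra:
            raise ValueError(f"samples assigned to unknown categories: {sorted(extra)}")
        for cat in self.categories:
            if not any(v == cat for v in self.assignment.values()):
                raise ValueError(f"category {cat!r} has no samples")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupLabels":
        from . import io as _io

        return cls(_io.read_metadata(path))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignment)

    def samples_of(self, category: str) -> list[str]:
        return [s for s, c in self.assignment.items() if c == category]

    def group_sizes(self) -> dict[str, int]:
        return {c: len(self.samples_of(c)) for c in self.categories}


@dataclass
class PresenceMatrix:
    """Per k-mer, the number of samples of each category containing it.

    The sufficient statistic for the unique and chi-squared selections and
    for the color vectors: only k-mers supported by >= 1 sample are stored.
    """

    k: int
    categories: list[str]
    group_sizes: dict[str, int]
    codes: np.ndarray = field(repr=False)  # sorted uint64, shape (n,)
    presence: np.ndarray = field(repr=False)  # int64, shape (n, n_categories)

    def __len__(self) -> int:
        return int(self.codes.size)

    def counts_for(self, kmer: str) -> dict[str, int]:
        code = canonical_code(encode_kmer(kmer), self.k)
        i = np.searchsorted(self.codes, np.uint64(code))
        if i < self.codes.size and int(self.codes[i]) == code:
            row = self.presence[i]
        else:
            row = np.zeros(len(self.categories), dtype=np.int64)
        return {c: int(v) for c, v in zip(self.categories, row)}


@dataclass
class SelectedKmers:
    """Pivot k-mers selected for one category, optionally with scores."""

    category: str
    k: int
    codes: np.ndarray = field(repr=False)  # uint64, ranked order (mode-specific)
    statistic: np.ndarray | None = field(default=None, repr=False)
    p_raw: np.ndarray | None = field(default=None, repr=False)
    p_corrected: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return int(np.asarray(self.codes).size)

    @property
    def pivots(self) -> set[str]:
        return {decode_kmer(int(c), self.k) for c in self.codes}

    @property
    def scores(self) -> dict[str, float] | None:
        if self.statistic is None:
            return None
        return {
            decode_kmer(int(c), self.k): float(s)
            for c, s in zip(self.codes, self.statistic)
        }

    def write_tsv(self, path: str | Path) -> None:
        """Dump (kmer, statistic, p_raw, p_corrected), statistic-descending."""
        rows = []
        n = len(self)
        stat = self.statistic if self.statistic is not None else np.full(n, np.nan)
        praw = self.p_raw if self.p_raw is not None else np.full(n, np.nan)
        pcor = self.p_corrected if self.p_corrected is not None else np.full(n, np.nan)
        for c, s, pr, pc in zip(self.codes, stat, praw, pcor):
            rows.append((decode_kmer(int(c), self.k), float(s), float(pr), float(pc)))
        rows.sort(key=lambda r: (-(r[1] if not math.isnan(r[1]) else -1.0), r[0]))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("kmer\tstatistic\tp_raw\tp_corrected\n")
            for km, s, pr, pc in rows:
                fh.write(f"{km}\t{s:.6g}\t{pr:.6g}\t{pc:.6g}\n")


# ---------------------------------------------------------------------------
# presence matrix


def sample_codes(obj, k: int | None = None) -> tuple[np.ndarray, int]:
    """Coerce a sample's k-mer collection to (sorted unique codes, k).

    Accepts a KmerCountTable, a set/iterable of k-mer strings, or a raw
    uint64 code array (then *k* must be given).
    """
    if isinstance(obj, KmerCountTable):
        return obj.codes, obj.k
    if isinstance(obj, np.ndarray):
        if k is None:
            raise ValueError("k required with raw code arrays")
        return np.unique(obj.astype(np.uint64)), k
    kmers = list(obj)
    if not kmers:
        if k is None:
            raise ValueError("k required with an empty k-mer set")
        return np.empty(0, dtype=np.uint64), k
    ks = {len(s) for s in kmers}
    if len(ks) != 1:
        raise ValueError("k-mers of mixed length")
    kk = ks.pop()
    if k is not None and k != kk:
        raise ValueError(f"expected k={k}, found k-mers of length {kk}")
    codes = np.fromiter(
        (canonical_code(encode_kmer(s), kk) for s in kmers), dtype=np.uint64, count=len(kmers)
    )
    return np.unique(codes), kk


def build_presence_matrix(
    sample_sets: Mapping[str, object], labels: GroupLabels, k: int | None = None
) -> PresenceMatrix:
    """Per-category sample-containment counts for every supported k-mer."""
    missing = [s for s in labels.sample_ids if s not in sample_sets]
    if missing:
        raise ValueError(f"no k-mer set for labelled samples: {', '.join(missing)}")
    coerced: dict[str, np.ndarray] = {}
    kk = k
    for sid in labels.sample_ids:
        codes, kk_s = sample_codes(sample_sets[sid], kk)
        if kk is None:
            kk = kk_s
        elif kk_s != kk:
            raise ValueError(f"sample {sid!r} has k={kk_s}, expected {kk}")
        coerced[sid] = codes
    assert kk is not None
    union = np.unique(np.concatenate([c for c in coerced.values()] or [np.empty(0, np.uint64)]))
    pres = np.zeros((union.size, len(labels.categories)), dtype=np.int64)
    cat_index = {c: j for j, c in enumerate(labels.categories)}
    for sid, codes in coerced.items():
        j = cat_index[labels.assignment[sid]]
        idx = np.searchsorted(union, codes)
        pres[idx, j] += 1
    return PresenceMatrix(
        k=kk,
        categories=list(labels.categories),
        group_sizes=labels.group_sizes(),
        codes=union,
        presence=pres,
    )


# ---------------------------------------------------------------------------
# unique mode


def _unique_mask(presence: PresenceMatrix, category: str, G: int) -> np.ndarray:
    j = presence.categories.index(category)
    others = np.delete(presence.presence, j, axis=1)
    return (presence.presence[:, j] >= G) & (others.sum(axis=1) == 0)


def select_unique(presence: PresenceMatrix, category: str, G: int) -> SelectedKmers:
    """K-mers present in >= G target-category samples and absent elsewhere."""
    if category not in presence.categories:
        raise ValueError(f"unknown category {category!r}")
    size = presence.group_sizes[category]
    if not 1 <= G <= size:
        raise ValueError(f"G must be in [1, {size}] for category {category!r}, got {G}")
    mask = _unique_mask(presence, category, G)
    return SelectedKmers(category=category, k=presence.k, codes=presence.codes[mask])


def auto_select_G(
    presence: PresenceMatrix,
    category: str,
    target_range: tuple[int, int] = (1000, 10000),
) -> int:
    """Pick G so the unique-k-mer count lands in a usable feature range.

    Prefers the largest G whose count falls inside ``target_range``
    (stringency first); if no G lands inside, returns the G whose count is
    closest to the lower edge (ties to the larger G).  All counts zero is
    an error — the statistical modes are the fallback there.
    """
    lo, hi = target_range
    if not lo < hi:
        raise ValueError("target_range must satisfy lo < hi")
    size = presence.group_sizes[category]
    j = presence.categories.index(category)
    others_absent = np.delete(presence.presence, j, axis=1).sum(axis=1) == 0
    tgt = presence.presence[others_absent, j]
    # count(G) = #{km exclusive to category with presence >= G}; nonincreasing in G
    counts = {G: int((tgt >= G).sum()) for G in range(size, 0, -1)}
    in_range = [G for G in range(size, 0, -1) if lo <= counts[G] <= hi]
    if in_range:
        return in_range[0]
    nonzero = [G for G in counts if counts[G] > 0]
    if not nonzero:
        raise ValueError(
            f"no G yields unique k-mers for category {category!r}; "
            "consider the chisq or stats selection modes"
        )
    return min(nonzero, key=lambda G: (abs(counts[G] - lo), -G))


# ---------------------------------------------------------------------------
# chi-squared with Yates correction


def _chisq_yates_arrays(a, b, c, d):
    a, b, c, d = (np.asarray(x, dtype=np.float64) for x in (a, b, c, d))
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    num = np.maximum(0.0, np.abs(a * d - b * c) - n / 2.0) ** 2 * n
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(margins > 0, num / np.where(margins > 0, margins, 1.0), 0.0)
    p = sps.chi2.sf(stat, df=1)
    p = np.where(margins > 0, p, 1.0)
    stat = np.where(margins > 0, stat, 0.0)
    return stat, p


def chisq_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-corrected chi-squared for the 2x2 table [[a, b], [c, d]].

    statistic = N * (max(0, |ad - bc| - N/2))^2 / ((a+b)(c+d)(a+c)(b+d));
    any zero margin gives (0, 1).  p is the upper chi-squared(1) tail.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("cell counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty contingency table")
    stat, p = _chisq_yates_arrays(a, b, c, d)
    return float(stat), float(p)


def _contingency(presence: PresenceMatrix, category: str):
    j = presence.categories.index(category)
    n_cat = presence.group_sizes[category]
    n_rest = sum(presence.group_sizes.values()) - n_cat
    a = presence.presence[:, j]
    b = n_cat - a
    c = np.delete(presence.presence, j, axis=1).sum(axis=1)
    d = n_rest - c
    return a, b, c, d, n_cat, n_rest


def _enriched(a, b, c, d) -> np.ndarray:
    # target presence rate strictly above the pooled-rest rate
    with np.errstate(divide="ignore", invalid="ignore"):
        return a * (c + d) > c * (a + b)


def select_chisq(
    presence: PresenceMatrix,
    category: str,
    alpha: float = 0.05,
    top_n: int = 10000,
) -> SelectedKmers:
    """Top chi-squared-significant k-mers enriched in *category*.

    Bonferroni correction over the number of k-mers actually tested (all
    k-mers with support in >= 1 sample); survivors ranked by statistic
    descending (ties by k-mer) and truncated to *top_n*.
    """
    if category not in presence.categories:
        raise ValueError(f"unknown category {category!r}")
    m = len(presence)
    if m == 0:
        raise ValueError("no k-mers to test")
    a, b, c, d, _, _ = _contingency(presence, category)
    stat, p = _chisq_yates_arrays(a, b, c, d)
    p_corr = np.minimum(p * m, 1.0)
    keep = (p_corr <= alpha) & _enriched(a, b, c, d)
    idx = np.flatnonzero(keep)
    order = np.lexsort((presence.codes[idx], -stat[idx]))
    idx = idx[order][:top_n]
    return SelectedKmers(
        category=category,
        k=presence.k,
        codes=presence.codes[idx],
        statistic=stat[idx],
        p_raw=p[idx],
        p_corrected=p_corr[idx],
    )


# ---------------------------------------------------------------------------
# Mann–Whitney U

_EXACT_LIMIT = 12  # n + m up to this size -> full permutation enumeration


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann–Whitney U (for x over y) with midrank ties and a two-sided p.

    Exact p by full permutation enumeration (conditional on the observed
    pooled values) when n + m <= 12; otherwise a normal approximation with
    tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    if n + m <= _EXACT_LIMIT:
        # doubled integer ranks keep the enumeration exact
        r2 = np.rint(ranks * 2).astype(np.int64)
        dev = abs(2 * u - n * m)
        count = 0
        total = 0
        for comb in combinations(range(n + m), n):
            u2 = int(r2[list(comb)].sum()) - n * (n + 1)
            if abs(u2 - n * m) >= dev:
                count += 1
            total += 1
        return u, count / total
    # normal approximation with tie correction
    nm = n * m
    N = n + m
    _, t = np.unique(pooled, return_counts=True)
    tie_term = float((t**3 - t).sum()) / (N * (N - 1))
    sigma2 = nm / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    diff = u - nm / 2.0
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(sigma2)
    return u, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def _mw_exact_matrix(A: np.ndarray, cat_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise exact two-sided Mann–Whitney over an abundance matrix.

    ``A`` is (n_kmers, n_samples); ``cat_mask`` marks target columns.
    """
    n = int(cat_mask.sum())
    m = int((~cat_mask).sum())
    N = n + m
    ranks2 = np.rint(sps.rankdata(A, method="average", axis=1) * 2).astype(np.int64)
    u2 = ranks2[:, cat_mask].sum(axis=1) - n * (n + 1)
    combs = np.array(list(combinations(range(N), n)), dtype=np.int64)
    dev = np.abs(u2 - n * m)
    p = np.empty(A.shape[0], dtype=np.float64)
    chunk = max(1, 2_000_000 // max(1, combs.shape[0]))
    for lo in range(0, A.shape[0], chunk):
        hi = min(lo + chunk, A.shape[0])
        sub = ranks2[lo:hi]  # (c, N)
        u2_all = sub[:, combs].sum(axis=2) - n * (n + 1)  # (c, ncomb)
        p[lo:hi] = (np.abs(u2_all - n * m) >= dev[lo:hi, None]).mean(axis=1)
    u = (u2 - 0.0) / 2.0
    return u, p


def _mw_normal_matrix(A: np.ndarray, cat_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = int(cat_mask.sum())
    m = int((~cat_mask).sum())
    N = n + m
    ranks = sps.rankdata(A, method="average", axis=1)
    u = ranks[:, cat_mask].sum(axis=1) - n * (n + 1) / 2.0
    srt = np.sort(A, axis=1)
    # tie correction per row: sum(t^3 - t) over tie groups
    tie = np.empty(A.shape[0])
    for i in range(A.shape[0]):
        _, t = np.unique(srt[i], return_counts=True)
        tie[i] = float((t**3 - t).sum())
    sigma2 = n * m / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    diff = u - n * m / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2)
    p = np.where(sigma2 > 0, np.minimum(1.0, 2.0 * sps.norm.sf(np.abs(z))), 1.0)
    return u, p


def select_stats(
    counts: Mapping[str, KmerCountTable],
    labels: GroupLabels,
    category: str,
    alpha: float = 0.05,
    top_n: int = 10000,
) -> SelectedKmers:
    """Conjunction selection: chi-squared presence AND Mann–Whitney abundance.

    A k-mer is selected iff it passes the Bonferroni-corrected chi-squared
    presence test, the Bonferroni-corrected Mann–Whitney test on per-sample
    abundances (absent = 0), and is over-represented in the target.  Both
    corrections use the number of k-mers tested as denominator.  Ranked by
    chi-squared statistic.
    """
    presence = build_presence_matrix(counts, labels)
    m = len(presence)
    if m == 0:
        raise ValueError("no k-mers to test")
    a, b, c, d, _, _ = _contingency(presence, category)
    stat, p = _chisq_yates_arrays(a, b, c, d)
    p_chi_corr = np.minimum(p * m, 1.0)
    cand = np.flatnonzero((p_chi_corr <= alpha) & _enriched(a, b, c, d))
    if cand.size == 0:
        return SelectedKmers(
            category=category,
            k=presence.k,
            codes=presence.codes[:0],
            statistic=stat[:0],
            p_raw=p[:0],
            p_corrected=p_chi_corr[:0],
        )
    # abundance matrix for the chi-squared survivors only
    sample_ids = labels.sample_ids
    cat_mask = np.array([labels.assignment[s] == category for s in sample_ids])
    A = np.zeros((cand.size, len(sample_ids)), dtype=np.float64)
    cand_codes = presence.codes[cand]
    for j, sid in enumerate(sample_ids):
        t = counts[sid]
        idx = np.searchsorted(t.codes, cand_codes)
        idx = np.clip(idx, 0, max(0, t.codes.size - 1))
        if t.codes.size:
            hit = t.codes[idx] == cand_codes
            A[hit, j] = t.counts[idx[hit]]
    if len(sample_ids) <= _EXACT_LIMIT:
        _, p_mw = _mw_exact_matrix(A, cat_mask)
    else:
        _, p_mw = _mw_normal_matrix(A, cat_mask)
    p_mw_corr = np.minimum(p_mw * m, 1.0)
    keep = p_mw_corr <= alpha
    idx = cand[keep]
    order = np.lexsort((presence.codes[idx], -stat[idx]))
    idx = idx[order][:top_n]
    return SelectedKmers(
        category=category,
        k=presence.k,
        codes=presence.codes[idx],
        statistic=stat[idx],
        p_raw=p[idx],
        p_corrected=p_chi_corr[idx],
    )
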