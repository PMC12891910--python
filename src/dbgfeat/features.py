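"""Breadth/depth coverage of components per sample and feature tables.

For a component C and a sample S:

* breadth(C, S) = |kmers(C) ∩ kmers(S)| / |kmers(C)|, in [0, 1];
* depth(C, S)   = Σ_{km ∈ C ∩ S} count_S(km) / |kmers(C)|, the mean
  per-k-mer abundance of the component in the sample.

The component size in both denominators is the distinct-canonical-k-mer
count, not the contig length.  Breadth is the default table consumed by
classifiers; depth is always computed and saved alongside.  Tables are
serialized as TSV at 6 decimal places, which is the precision contract
for byte-reproducible round trips.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dbg import Component, read_components_fasta
from .kmer_core import KmerCountTable, count_kmers, count_sample_file
from .selection import sample_codes

__all__ = [
    "FeatureTable",
    "breadth",
    "depth",
    "build_feature_table",
    "calc_features",
]

MODES = ("breadth", "depth")


@dataclass
class FeatureTable:
    """N_features x M_samples coverage matrix with a fixed row/column order."""

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def write_tsv(self, path: str | Path) -> None:
        df = self.values.copy()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def read_tsv(cls, path: str | Path, mode: str = "breadth") -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(values=df, mode=mode)


def breadth(component: Component, sample) -> float:
    """Fraction of the component's k-mers present in the sample."""
    if component.size == 0:
        raise ValueError("empty component")
    codes, _ = sample_codes(sample, component.k)
    common = np.intersect1d(component.codes, codes, assume_unique=True)
    return common.size / component.size


def depth(component: Component, sample: KmerCountTable) -> float:
    """Mean per-k-mer abundance of the component in the sample."""
    if component.size == 0:
        raise ValueError("empty component")
    if not isinstance(sample, KmerCountTable):
        raise TypeError("depth requires a KmerCountTable (abundances needed)")
    idx = np.searchsorted(sample.codes, component.codes)
    idx = np.clip(idx, 0, max(0, sample.codes.size - 1))
    if sample.codes.size == 0:
        return 0.0
    hit = sample.codes[idx] == component.codes
    return float(sample.counts[idx[hit]].sum()) / component.size


def build_feature_table(
    components: Sequence[Component],
    samples: Mapping[str, KmerCountTable],
    mode: str = "breadth",
) -> FeatureTable:
    """Coverage of every component by every sample, deterministic order."""
    if not components:
        raise ValueError("no components")
    if not samples:
        raise ValueError("no samples")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    ks = {c.k for c in components} | {t.k for t in samples.values()}
    if len(ks) != 1:
        raise ValueError(f"k mismatch between components and samples: {sorted(ks)}")
    fn = breadth if mode == "breadth" else depth
    feature_ids = [c.id for c in components]
    sample_ids = list(samples)
    mat = np.empty((len(components), len(sample_ids)), dtype=np.float64)
    for j, sid in enumerate(sample_ids):
        t = samples[sid]
        for i, comp in enumerate(components):
            mat[i, j] = fn(comp, t)
    df = pd.DataFrame(mat, index=feature_ids, columns=sample_ids)
    return FeatureTable(values=df, mode=mode)


def calc_features(
    components_fasta: str | Path,
    new_samples: Mapping[str, object],
    k: int,
    mode: str = "breadth",
    min_count: int = 2,
    feature_order: Sequence[str] | None = None,
) -> FeatureTable:
    """Recompute features for novel samples from a stored components FASTA.

    Components are reconstructed by re-k-merizing contigs grouped by
    component id; coverage is then computed exactly as at training time
    (same counting parameters give a bit-exact round trip).  Sample values
    may be read-file paths, read lists, or ready KmerCountTables.
    *feature_order* pins the row order to a paired model's feature list.
    """
    components = read_components_fasta(components_fasta, k)
    if feature_order is not None:
        by_id = {c.id: c for c in components}
        missing = [f for f in feature_order if f not in by_id]
        if missing:
            raise ValueError(f"components FASTA lacks features: {', '.join(missing)}")
        components = [by_id[f] for f in feature_order]
    tables: dict[str, KmerCountTable] = {}
    for sid, obj in new_samples.items():
        if isinstance(obj, KmerCountTable):
            tables[sid] = obj
        elif isinstance(obj, (str, Path)):
            tables[sid] = count_sample_file(obj, k=k, min_count=min_count, sample_id=sid)
        else:
            tables[sid] = count_kmers(obj, k=k, min_count=min_count, sample_id=sid)
    return build_feature_table(components, tables, mode=mode)
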