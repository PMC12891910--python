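"""Synthetic metagenomic communities with planted group-specific markers.

The generator emulates the statistical structure a disease-vs-control
short-read study presents to the selection methods: every sample shares a
background community of random genomes, and every sample of a group
additionally carries that group's marker sequences.  With a substitution
error rate of zero and adequate coverage, the markers' canonical k-mers
are group-exclusive by construction, so the unique selection has a known
ground truth and recovery is measurable exactly.

Reads are single-end with uniform "overhanging" start positions (starts
may fall up to read_length-1 before a sequence), which keeps per-base
coverage — including the terminal marker k-mers — near the nominal value.
All randomness flows from one seed; identical specs give byte-identical
output files (gzip members are written with a zeroed mtime).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._encoding import encode_canonical_windows
from .dbg import read_components_fasta
from .io import wrap_fasta, write_metadata

__all__ = [
    "CommunitySpec",
    "CommunityManifest",
    "generate_community",
    "evaluate_marker_recovery",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GROUP_NAMES = ["A", "B", "C"]


@dataclass
class CommunitySpec:
    """Study conditions for one synthetic community."""

    n_background_genomes: int = 5
    genome_length: int = 5000
    n_groups: int = 2
    samples_per_group: int = 6
    markers_per_group: int = 2
    marker_length: int = 2000
    read_length: int = 150
    coverage: float = 30.0
    substitution_error_rate: float = 0.0
    k: int = 31
    seed: int = 42

    def validate(self) -> None:
        if self.n_groups not in (2, 3):
            raise ValueError("n_groups must be 2 or 3")
        if self.marker_length < 3 * self.k:
            raise ValueError(
                f"marker_length must be >= 3k = {3 * self.k} to plant multiple "
                "marker-specific k-mers"
            )
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.substitution_error_rate <= 0.05:
            raise ValueError("substitution_error_rate must be in [0, 0.05]")
        if self.read_length < self.k:
            raise ValueError("read_length must be >= k")
        for name in ("n_background_genomes", "genome_length", "samples_per_group", "markers_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class CommunityManifest:
    spec: CommunitySpec
    reads_dir: Path
    sample_fastas: dict[str, Path]
    metadata_path: Path
    truth_path: Path
    manifest_path: Path
    assignment: dict[str, str]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _kmer_codes(seq: str, k: int) -> set[int]:
    return set(int(c) for c in encode_canonical_windows(seq, k))


def _sample_reads(
    rng: np.random.Generator, sequences: list[str], read_length: int, coverage: float, k: int
) -> list[str]:
    reads: list[str] = []
    for seq in sequences:
        L = len(seq)
        span = L + read_length - 1
        n_reads = int(np.ceil(coverage * span / read_length))
        starts = rng.integers(-(read_length - 1), L, size=n_reads)
        for s in starts:
            read = seq[max(0, int(s)) : int(s) + read_length]
            if len(read) >= k:
                reads.append(read)
    return reads


def _apply_errors(rng: np.random.Generator, read: str, rate: float) -> str:
    if rate <= 0:
        return read
    arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size:
        # substitute with a uniformly chosen different base
        cur = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(cur + rng.integers(1, 4, size=hit.size)) % 4]
    return arr.tobytes().decode("ascii")


def generate_community(spec: CommunitySpec, out_dir: str | Path) -> CommunityManifest:
    """Write per-sample FASTA.gz reads, metadata, truth markers and manifest."""
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    backgrounds = [_random_dna(rng, spec.genome_length) for _ in range(spec.n_background_genomes)]
    bg_codes: set[int] = set()
    for g in backgrounds:
        bg_codes |= _kmer_codes(g, spec.k)

    groups = _GROUP_NAMES[: spec.n_groups]
    markers: dict[str, list[str]] = {}
    claimed = set(bg_codes)
    for grp in groups:
        markers[grp] = []
        for _ in range(spec.markers_per_group):
            # reject markers sharing any k-mer with the background or other markers
            while True:
                m = _random_dna(rng, spec.marker_length)
                codes = _kmer_codes(m, spec.k)
                if not (codes & claimed):
                    claimed |= codes
                    markers[grp].append(m)
                    break

    truth_path = out / "truth_markers.fasta"
    with open(truth_path, "w", encoding="utf-8") as fh:
        for grp in groups:
            for j, m in enumerate(markers[grp]):
                fh.write(f">marker_{grp}_{j} category={grp}\n{wrap_fasta(m)}\n")

    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    assignment: dict[str, str] = {}
    sample_fastas: dict[str, Path] = {}
    for grp in groups:
        for si in range(spec.samples_per_group):
            sid = f"{grp}{si + 1:02d}"
            assignment[sid] = grp
            pool = backgrounds + markers[grp]
            reads = _sample_reads(rng, pool, spec.read_length, spec.coverage, spec.k)
            if spec.substitution_error_rate > 0:
                reads = [_apply_errors(rng, r, spec.substitution_error_rate) for r in reads]
            path = reads_dir / f"{sid}.fasta.gz"
            raw = []
            for ri, r in enumerate(reads):
                raw.append(f">{sid}_r{ri}\n{r}\n")
            with open(path, "wb") as fb:
                with gzip.GzipFile(fileobj=fb, mode="wb", filename="", mtime=0) as gz:
                    gz.write("".join(raw).encode("ascii"))
            sample_fastas[sid] = path

    metadata_path = out / "metadata.tsv"
    write_metadata(metadata_path, assignment)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "spec": asdict(spec),
                "samples": {s: f"reads/{p.name}" for s, p in sample_fastas.items()},
                "metadata": metadata_path.name,
                "truth_markers": truth_path.name,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")

    return CommunityManifest(
        spec=spec,
        reads_dir=reads_dir,
        sample_fastas=sample_fastas,
        metadata_path=metadata_path,
        truth_path=truth_path,
        manifest_path=manifest_path,
        assignment=assignment,
    )


def read_truth_markers(path: str | Path, k: int) -> dict[str, set[int]]:
    """Truth marker k-mer codes keyed by group."""
    from Bio import SeqIO

    truth: dict[str, set[int]] = {}
    with open(path, encoding="utf-8") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            grp = None
            for tok in rec.description.split():
                if tok.startswith("category="):
                    grp = tok.split("=", 1)[1]
            if grp is None:
                raise ValueError(f"truth marker {rec.id!r} lacks a category= tag")
            truth.setdefault(grp, set()).update(_kmer_codes(str(rec.seq).upper(), k))
    if not truth:
        raise ValueError(f"no markers found in {path}")
    return truth


def evaluate_marker_recovery(
    components_fasta: str | Path, truth_markers: str | Path, k: int
) -> dict:
    """Fraction of marker k-mers recovered in correctly-labelled components.

    Returns per-group recall plus a marker-count-weighted overall recall.
    """
    truth = read_truth_markers(truth_markers, k)
    components = read_components_fasta(components_fasta, k)
    by_cat: dict[str, set[int]] = {}
    for comp in components:
        by_cat.setdefault(comp.category, set()).update(int(c) for c in comp.codes)
    per_group: dict[str, float] = {}
    hits = total = 0
    for grp, codes in truth.items():
        got = len(codes & by_cat.get(grp, set()))
        per_group[grp] = got / len(codes)
        hits += got
        total += len(codes)
    return {"per_group": per_group, "overall": hits / total, "n_marker_kmers": total}
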