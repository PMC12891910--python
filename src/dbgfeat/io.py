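"""Reading sequencing reads and small tabular formats.

Reads come in FASTA or FASTQ, plain or gzip-compressed, sniffed from the
file extension (.fa/.fasta/.fna/.fq/.fastq with optional .gz).  Quality
strings are ignored.  Parsing is delegated to Biopython's SeqIO.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

_FASTA_EXT = {".fa", ".fasta", ".fna"}
_FASTQ_EXT = {".fq", ".fastq"}

READ_EXTENSIONS = tuple(
    e + g for e in sorted(_FASTA_EXT | _FASTQ_EXT) for g in ("", ".gz")
)


def sniff_format(path: str | Path) -> tuple[str, bool]:
    """Return ``(format, gzipped)`` for a read file path.

    ``format`` is "fasta" or "fastq"; unknown extensions raise ValueError.
    """
    p = Path(path)
    suffixes = p.suffixes
    gzipped = bool(suffixes) and suffixes[-1] == ".gz"
    ext = suffixes[-2] if gzipped and len(suffixes) >= 2 else (suffixes[-1] if suffixes else "")
    ext = ext.lower()
    if ext in _FASTA_EXT:
        return "fasta", gzipped
    if ext in _FASTQ_EXT:
        return "fastq", gzipped
    raise ValueError(f"cannot infer read format from extension of {p.name!r}")


def open_text(path: str | Path, mode: str = "rt"):
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, mode)
    return open(p, mode)


def iter_reads(path: str | Path) -> Iterator[str]:
    """Yield read sequences (uppercased strings) from a FASTA/FASTQ file."""
    fmt, _ = sniff_format(path)
    with open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq).upper()


def find_sample_files(reads_dir: str | Path, sample_ids: list[str]) -> dict[str, Path]:
    """Locate one read file per sample id in a directory.

    A sample ``S`` matches ``S<ext>`` for any recognised read extension.
    Missing or ambiguous samples raise ValueError naming them.
    """
    d = Path(reads_dir)
    found: dict[str, Path] = {}
    missing = []
    for sid in sample_ids:
        hits = [d / (sid + ext) for ext in READ_EXTENSIONS if (d / (sid + ext)).exists()]
        if not hits:
            missing.append(sid)
        elif len(hits) > 1:
            raise ValueError(f"multiple read files for sample {sid!r}: {hits}")
        else:
            found[sid] = hits[0]
    if missing:
        raise ValueError(f"no read file found for samples: {', '.join(missing)}")
    return found


def read_metadata(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``sample_id<TAB>category``, no header, UTF-8."""
    assignment: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{ln}: expected 'sample<TAB>category', got {line!r}")
            if parts[0] in assignment:
                raise ValueError(f"{path}:{ln}: duplicate sample id {parts[0]!r}")
            assignment[parts[0]] = parts[1]
    if not assignment:
        raise ValueError(f"metadata file {path} is empty")
    return assignment


def write_metadata(path: str | Path, assignment: dict[str, str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, cat in assignment.items():
            fh.write(f"{sid}\t{cat}\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path: str | Path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def wrap_fasta(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))
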