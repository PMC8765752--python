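"""FASTA/FASTQ/TSV plumbing.

FASTQ is written gzipped with a zeroed mtime so that rerunning a seeded
simulation is byte-identical; quality strings are constant 'I' because
no downstream rule consumes base qualities.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .seqcodes import decode, encode

FASTA_WIDTH = 80


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i:i + FASTA_WIDTH] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_gz(path: str | Path, ids: Sequence[str], reads: np.ndarray,
                   mate: int | None = None) -> None:
    """Write reads (code matrix) as gzipped FASTQ, reproducibly.

    ``mate`` appends /1 or /2 to every id.
    """
    suffix = f"/{mate}" if mate else ""
    qual = "I" * (reads.shape[1] if reads.size else 0)
    buf = _io.BytesIO()
    with gzip.GzipFile(filename="", mode="wb", fileobj=buf, mtime=0) as gz:
        text = []
        for rid, row in zip(ids, reads):
            text.append(f"@{rid}{suffix}\n{decode(row)}\n+\n{qual}\n")
        gz.write("".join(text).encode())
    Path(path).write_bytes(buf.getvalue())


def read_fastq_codes(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a (possibly gzipped) FASTQ of equal-length reads into a code matrix."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    ids, rows = [], []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            ids.append(rec.id)
            rows.append(encode(str(rec.seq).upper()))
    if not rows:
        return [], np.zeros((0, 0), dtype=np.uint8)
    lengths = {r.size for r in rows}
    if len(lengths) > 1:
        raise ValueError("reads of unequal length are not supported")
    return ids, np.vstack(rows)
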