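"""Small-file sequence I/O helpers shared across the pipeline.

FASTA/FASTQ reading goes through :class:`pysam.FastxFile`, which handles
gzip transparently and exposes header comments. Writing is plain text.
"""

from __future__ import annotations

import gzip
import os
from typing import Iterable, Iterator, Tuple

import pysam

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N, case preserved."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_fasta_header(path: str) -> None:
    """Fail early, naming the offending line, when a file is not FASTA."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header starting "
                    f"with '>', got {line.strip()[:40]!r}"
                )
            return


def read_fasta(path: str) -> Iterator[Tuple[str, str, str]]:
    """Yield (id, description, sequence) tuples from a FASTA file."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _check_fasta_header(path)
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.comment or "", rec.sequence


def read_fastq_sequences(path: str) -> Iterator[str]:
    """Yield read sequences (upper-cased) from FASTQ, optionally gzipped.

    Quality strings are parsed by pysam but deliberately unused: the
    pipeline applies no quality filtering.
    """
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.sequence.upper()


def write_fasta(path: str, records: Iterable[Tuple[str, str]], width: int = 70) -> None:
    """Write (id, seq) pairs as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str, records: Iterable[Tuple[str, str]]) -> None:
    """Write (id, seq) pairs as FASTQ with dummy qualities ('I').

    Gzipped output is written with a zeroed timestamp so identical
    inputs produce byte-identical files.
    """
    if str(path).endswith(".gz"):
        import io

        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                fh = io.TextIOWrapper(gz)
                for name, seq in records:
                    fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
                fh.flush()
    else:
        with open(path, "w") as fh:
            for name, seq in records:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
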