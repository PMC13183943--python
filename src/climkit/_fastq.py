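"""Gzip FASTQ helpers (4-line records, Phred+33).

Reading goes through Biopython's FastqGeneralIterator; fixed-length
samples are additionally exposed as dense uint8 matrices for the
vectorized pipeline.  Writing emits records directly (bulk 4-line
output) with a zeroed gzip mtime so identical simulations are
byte-identical.
"""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33


def open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality string) records."""
    with open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def read_fastq_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a fixed-read-length FASTQ as uint8 (n, L) sequence and
    Phred-integer matrices; raises on ragged read lengths."""
    seqs: list[str] = []
    quals: list[str] = []
    length = None
    for _title, seq, qual in iter_fastq(path):
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError("read lengths vary; matrix path requires "
                             "fixed-length reads")
        seqs.append(seq)
        quals.append(qual)
    if not seqs:
        return np.empty((0, 0), np.uint8), np.empty((0, 0), np.int16)
    s = np.frombuffer("".join(seqs).encode(), np.uint8).reshape(len(seqs), length)
    q = (
        np.frombuffer("".join(quals).encode(), np.uint8)
        .reshape(len(quals), length)
        .astype(np.int16)
        - PHRED_OFFSET
    )
    return s, q


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    """Write (title, sequence, quality string) records to gzip FASTQ
    deterministically (mtime pinned to 0)."""
    with open(path, "wb") as raw:
        with gzip.GzipFile(
            filename="", fileobj=raw, mode="wb", compresslevel=4, mtime=0
        ) as gz:
            for title, seq, qual in records:
                gz.write(f"@{title}\n{seq}\n+\n{qual}\n".encode())


def write_fastq_matrix(path, titles: list[str], seqs: np.ndarray,
                       qual_char: str) -> None:
    """Bulk write of a dense (n, L) uint8 sequence matrix with one
    constant quality character for every base."""
    n, L = seqs.shape
    qual = qual_char * L
    lines = []
    append = lines.append
    raw = seqs.tobytes().decode()
    for i in range(n):
        append(f"@{titles[i]}\n{raw[i * L:(i + 1) * L]}\n+\n{qual}\n")
    with open(path, "wb") as fh:
        with gzip.GzipFile(
            filename="", fileobj=fh, mode="wb", compresslevel=4, mtime=0
        ) as gz:
            gz.write("".join(lines).encode())
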