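"""Minimal 4-line FASTQ reading/writing (plain or gzip, Sanger Phred+33).

Small-RNA FASTQ files are fixed-layout four-line records; this module reads
and writes them directly so that output bytes are fully deterministic.
FASTA parsing elsewhere in the package goes through Biopython.
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterator, NamedTuple


class FastqRecord(NamedTuple):
    id: str
    sequence: str
    quality: str


class FastqParseError(ValueError):
    """Raised for a structurally malformed FASTQ record; names the record index."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # fixed mtime/filename so identical content yields identical bytes
            raw = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
            return io.TextIOWrapper(raw, encoding="ascii", newline="\n")
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, mode, encoding="ascii", newline="\n" if "w" in mode else None)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Yield records from a FASTQ file, validating the 4-line structure."""
    with _open_text(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lines = [header, fh.readline(), fh.readline(), fh.readline()]
            lines = [ln.rstrip("\n").rstrip("\r") for ln in lines]
            if not lines[0].startswith("@"):
                raise FastqParseError(f"record {idx}: header does not start with '@'")
            if not lines[2].startswith("+"):
                raise FastqParseError(f"record {idx}: separator line does not start with '+'")
            if len(lines[1]) != len(lines[3]):
                raise FastqParseError(
                    f"record {idx}: sequence and quality lengths differ "
                    f"({len(lines[1])} vs {len(lines[3])})"
                )
            if not lines[1]:
                raise FastqParseError(f"record {idx}: empty sequence")
            yield FastqRecord(lines[0][1:].split()[0], lines[1], lines[3])
            idx += 1


def write_fastq(path: str | Path, records) -> int:
    """Write FastqRecord-like triples; returns the number of records written."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n
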