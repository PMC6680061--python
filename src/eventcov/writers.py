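"""Tabular output for coverage records: TSV, CSV and BED.

TSV/CSV carry a header line and 1-based inclusive coordinates. BED is
0-based half-open and headerless, and is only meaningful for interval
results (blocks, windows). Window means are printed with fixed 4-decimal
formatting so repeated runs are byte-identical.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from .core import CoverageRecord

FORMATS = ("tsv", "csv", "bed")
_HEADER = ("contig", "start", "end", "coverage")


def _fmt_coverage(value: int | float) -> str:
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(int(value))


def write_records(
    records: Iterable[CoverageRecord],
    fmt: str,
    path: str | os.PathLike,
) -> int:
    """Write sorted records to *path*; returns the number of rows written."""
    if fmt not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {fmt!r}")
    sep = "," if fmt == "csv" else "\t"
    n = 0
    with open(os.fspath(path), "w", newline="") as fh:
        if fmt != "bed":
            fh.write(sep.join(_HEADER) + "\n")
        for rec in records:
            if fmt == "bed":
                row = (rec.contig, str(rec.pos_start - 1), str(rec.pos_end),
                       _fmt_coverage(rec.coverage))
            else:
                row = (rec.contig, str(rec.pos_start), str(rec.pos_end),
                       _fmt_coverage(rec.coverage))
            fh.write(sep.join(row) + "\n")
            n += 1
    return n


def read_records(path: str | os.PathLike, fmt: str) -> Iterator[CoverageRecord]:
    """Parse a file written by :func:`write_records` back into records."""
    if fmt not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {fmt!r}")
    sep = "," if fmt == "csv" else "\t"
    with open(os.fspath(path)) as fh:
        if fmt != "bed":
            next(fh, None)  # header
        for line in fh:
            contig, start, end, cov = line.rstrip("\n").split(sep)
            coverage: int | float = float(cov) if "." in cov else int(cov)
            if fmt == "bed":
                yield CoverageRecord(contig, int(start) + 1, int(end), coverage)
            else:
                yield CoverageRecord(contig, int(start), int(end), coverage)
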