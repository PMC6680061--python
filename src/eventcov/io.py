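"""Alignment input: SAM/BAM reading, filtering, CIGAR block extraction, partitioning.

Coordinates are 1-based inclusive throughout; conversion to other conventions
(BED) happens only at the writer boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam

# SAM FLAG bits
FLAG_UNMAP = 0x4
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUP = 0x400

#: samtools-depth-compatible default: drop unmapped, secondary, QC-fail and duplicate reads.
DEFAULT_EXCLUDE_FLAGS = FLAG_UNMAP | FLAG_SECONDARY | FLAG_QCFAIL | FLAG_DUP

# CIGAR op codes as numbered by the SAM specification (and pysam).
_OP_M, _OP_I, _OP_D, _OP_N, _OP_S, _OP_H, _OP_P, _OP_EQ, _OP_X = range(9)
#: ops that advance the reference cursor
_REF_CONSUMING = frozenset({_OP_M, _OP_D, _OP_N, _OP_EQ, _OP_X})
#: ops whose reference bases count as covered (D is policy-dependent)
_COVERING = frozenset({_OP_M, _OP_EQ, _OP_X})

CIGAR_OPS = "MIDNSHP=X"


class UnsortedInputError(ValueError):
    """Raised when the input is not in coordinate order."""


class MalformedRecordError(ValueError):
    """Raised for a record that cannot be interpreted, naming its ordinal."""


@dataclass(frozen=True)
class ReadFilter:
    """Read-level filter: a read is kept iff (flags & exclude_flags) == 0 and mapq >= min_mapq."""

    exclude_flags: int = DEFAULT_EXCLUDE_FLAGS
    min_mapq: int = 0

    def keep(self, flags: int, mapq: int) -> bool:
        return (flags & self.exclude_flags) == 0 and mapq >= self.min_mapq


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read: contig, 1-based leftmost position, CIGAR, FLAG, MAPQ."""

    contig: str
    start: int  # 1-based leftmost mapped position
    cigar: tuple[tuple[int, int], ...]  # (op code, length) pairs
    flags: int
    mapq: int


@dataclass(frozen=True)
class AlignmentBlock:
    """A maximal reference-contiguous covered interval [start, start+len-1], 1-based."""

    contig: str
    start: int
    length: int

    @property
    def end(self) -> int:
        """Last covered position, inclusive."""
        return self.start + self.length - 1


@dataclass
class ReadSlice:
    """Partition i of the filtered read stream, in file (coordinate) order."""

    index: int
    reads: list[AlignedRead] = field(default_factory=list)


def read_header(path: str | os.PathLike) -> dict[str, int]:
    """Return the reference dictionary {contig: length} in header order."""
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as af:
        return dict(zip(af.references, af.lengths))


def read_alignments(
    path: str | os.PathLike,
    read_filter: ReadFilter | None = None,
) -> Iterator[AlignedRead]:
    """Stream the mapped reads of a coordinate-sorted SAM/BAM that pass *read_filter*.

    The header SO tag is trusted when it says ``coordinate``; otherwise a
    streaming monotonicity check raises :class:`UnsortedInputError` on the
    first out-of-order read. Unmapped reads are never yielded regardless of
    the filter mask.
    """
    read_filter = read_filter or ReadFilter()
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with pysam.AlignmentFile(path, check_sq=False) as af:
        so = (af.header.get("HD") or {}).get("SO")
        if so is not None and so != "coordinate":
            raise UnsortedInputError(
                f"input must be coordinate-sorted (header SO:{so})"
            )
        verify_order = so != "coordinate"
        last_tid = -1
        last_pos = -1
        for ordinal, rec in enumerate(af, start=1):
            if rec.is_unmapped:
                continue
            if verify_order:
                if rec.reference_id < last_tid or (
                    rec.reference_id == last_tid
                    and rec.reference_start < last_pos
                ):
                    raise UnsortedInputError(
                        "input must be coordinate-sorted "
                        f"(record {ordinal} at {rec.reference_name}:{rec.reference_start + 1} "
                        "is out of order)"
                    )
                last_tid, last_pos = rec.reference_id, rec.reference_start
            if not read_filter.keep(rec.flag, rec.mapping_quality):
                continue
            if rec.cigartuples is None:
                raise MalformedRecordError(
                    f"record {ordinal} is mapped but has no CIGAR"
                )
            yield AlignedRead(
                contig=rec.reference_name,
                start=rec.reference_start + 1,
                cigar=tuple(rec.cigartuples),
                flags=rec.flag,
                mapq=rec.mapping_quality,
            )


def extract_blocks(read: AlignedRead, count_deletions: bool = True) -> list[AlignmentBlock]:
    """Derive the maximal reference-contiguous covered intervals of a read's CIGAR.

    M, = and X cover reference bases; D covers iff *count_deletions*; N (a
    spliced-alignment skip) consumes reference but never covers, so it always
    splits blocks; I, S, H and P consume no reference and never split.
    Reference-adjacent covered segments are merged.
    """
    blocks: list[AlignmentBlock] = []
    pos = read.start  # reference cursor, 1-based
    cur_start: int | None = None
    cur_len = 0

    def flush() -> None:
        nonlocal cur_start, cur_len
        if cur_start is not None:
            blocks.append(AlignmentBlock(read.contig, cur_start, cur_len))
            cur_start, cur_len = None, 0

    for op, length in read.cigar:
        if op > _OP_X or op < 0:
            raise ValueError(f"unknown CIGAR op code {op} in read at {read.contig}:{read.start}")
        if length < 0:
            raise ValueError(f"negative CIGAR op length in read at {read.contig}:{read.start}")
        covers = op in _COVERING or (op == _OP_D and count_deletions)
        if covers:
            if cur_start is None:
                cur_start = pos
            cur_len += length
            pos += length
        elif op in _REF_CONSUMING:  # D (not counted) or N: gap in coverage
            flush()
            pos += length
        # I/S/H/P: no reference consumption, block continues across them
    flush()
    return [b for b in blocks if b.length > 0]


def partition_reads(reads: Iterable[AlignedRead], n: int) -> list[ReadSlice]:
    """Split a coordinate-ordered read stream into ≤n contiguous, near-equal slices.

    Boundaries fall at arbitrary reads (never aligned to contigs); downstream
    overlap correction makes that legal. With fewer reads than n, each read
    gets its own slice.
    """
    if n < 1:
        raise ValueError(f"partition count must be >= 1, got {n}")
    reads = list(reads)
    if not reads:
        return []
    n_eff = min(n, len(reads))
    base, extra = divmod(len(reads), n_eff)
    slices = []
    at = 0
    for i in range(n_eff):
        size = base + (1 if i < extra else 0)
        slices.append(ReadSlice(index=i, reads=reads[at : at + size]))
        at += size
    return slices


def cigar_to_string(cigar: Sequence[tuple[int, int]]) -> str:
    return "".join(f"{length}{CIGAR_OPS[op]}" for op, length in cigar)
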