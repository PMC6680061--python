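"""Event-vector coverage core.

Depth of coverage is computed from "events": for each alignment block
(start, len) the delta array gets +1 at ``start`` and -1 at ``start + len``;
the running (cumulative) sum of the deltas recovers the per-base depth:

    partial_coverage(j) = sum_{m<=j} events(m)

Arrays are extent-restricted: each vector stores only the covered span of its
(partition, contig) pair plus a recorded genomic offset, so memory scales with
the covered span rather than contig length.

Counters are compact by default (16-bit), with a checked promotion to wider
integers when any depth would exceed the compact range; silent wraparound is
a contract violation and cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io import AlignmentBlock, ReadSlice, extract_blocks

#: maximum depth representable by the compact counter mode
COMPACT_MAX = np.iinfo(np.uint16).max  # 65_535


class NegativeCoverageError(ValueError):
    """A negative prefix sum: the events vector is internally inconsistent."""


@dataclass
class EventsVector:
    """Per-(partition, contig) delta array; ``deltas[k]`` belongs to genomic position ``offset + k``."""

    partition: int
    contig: str
    offset: int  # 1-based genomic position of deltas[0]
    deltas: np.ndarray  # signed integer deltas; sums to 0 over the full extent


@dataclass
class PartialCoverage:
    """Per-(partition, contig) coverage vector; ``values[k]`` is the depth at ``start + k``.

    After trimming the first and last elements are nonzero.
    """

    partition: int
    contig: str
    start: int  # 1-based genomic position of values[0]
    values: np.ndarray  # non-negative integers

    @property
    def end(self) -> int:
        """Last genomic position held, inclusive."""
        return self.start + len(self.values) - 1


@dataclass(frozen=True)
class CoverageRecord:
    """One output row over [pos_start, pos_end], 1-based inclusive."""

    contig: str
    pos_start: int
    pos_end: int
    coverage: int | float


def _compact(arr: np.ndarray) -> np.ndarray:
    """Store deltas in 16 bits when they fit, otherwise keep the wide type."""
    if arr.size and np.int16(np.iinfo(np.int16).min) <= arr.min() and arr.max() <= np.iinfo(np.int16).max:
        return arr.astype(np.int16)
    return arr


def events_from_blocks(
    partition: int,
    blocks: Iterable[AlignmentBlock],
    contig_lengths: dict[str, int] | None = None,
) -> list[EventsVector]:
    """Build one delta array per contig from alignment blocks.

    The array spans [min block start, max block end + 1] so that every -1
    lands inside it and the full-extent sum is zero.
    """
    per_contig: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        per_contig.setdefault(b.contig, []).append(b)

    out: list[EventsVector] = []
    for contig, blist in per_contig.items():
        if contig_lengths is not None:
            clen = contig_lengths.get(contig)
            for b in blist:
                if clen is not None and b.end > clen:
                    raise ValueError(
                        f"alignment block ends at {contig}:{b.end}, "
                        f"beyond contig length {clen}"
                    )
        lo = min(b.start for b in blist)
        hi = max(b.end for b in blist) + 1  # decrement position of the rightmost block
        deltas = np.zeros(hi - lo + 1, dtype=np.int32)
        starts = np.fromiter((b.start - lo for b in blist), dtype=np.int64, count=len(blist))
        ends = np.fromiter((b.end + 1 - lo for b in blist), dtype=np.int64, count=len(blist))
        np.add.at(deltas, starts, 1)
        np.subtract.at(deltas, ends, 1)
        out.append(EventsVector(partition, contig, lo, _compact(deltas)))
    out.sort(key=lambda ev: ev.contig)
    return out


def build_events(
    read_slice: ReadSlice,
    count_deletions: bool = True,
    contig_lengths: dict[str, int] | None = None,
) -> list[EventsVector]:
    """Extract CIGAR blocks for every read of a slice and build its delta arrays."""
    blocks: list[AlignmentBlock] = []
    for read in read_slice.reads:
        blocks.extend(extract_blocks(read, count_deletions=count_deletions))
    return events_from_blocks(read_slice.index, blocks, contig_lengths)


def promote_depths(values: np.ndarray) -> np.ndarray:
    """Choose the narrowest unsigned type that holds the depths exactly."""
    if values.size == 0 or values.max() <= COMPACT_MAX:
        return values.astype(np.uint16)
    return values.astype(np.uint32)


def events_to_partial(events: EventsVector) -> PartialCoverage:
    """Cumulative-sum a delta array into a partial coverage vector.

    Leading and trailing zero runs are trimmed and the genomic start adjusted.
    A negative running sum means the events vector was malformed and raises.
    """
    cov = np.cumsum(events.deltas, dtype=np.int64)
    if cov.size and cov.min() < 0:
        raise NegativeCoverageError(
            f"negative coverage in partition {events.partition} on {events.contig}: "
            "events vector is inconsistent"
        )
    nz = np.flatnonzero(cov)
    if nz.size == 0:
        return PartialCoverage(events.partition, events.contig, events.offset,
                               np.zeros(0, dtype=np.uint16))
    first, last = int(nz[0]), int(nz[-1])
    return PartialCoverage(
        events.partition,
        events.contig,
        events.offset + first,
        promote_depths(cov[first : last + 1]),
    )


def _as_vector_list(
    cov: PartialCoverage | Sequence[PartialCoverage],
) -> list[PartialCoverage]:
    vecs = [cov] if isinstance(cov, PartialCoverage) else list(cov)
    vecs = [v for v in vecs if len(v.values)]
    vecs.sort(key=lambda v: v.start)
    for a, b in zip(vecs, vecs[1:]):
        if b.start <= a.end:
            raise ValueError("coverage vectors overlap; merge partitions first")
    return vecs


def to_per_base(
    cov: PartialCoverage | Sequence[PartialCoverage],
    include_zeros: bool = False,
    contig_length: int | None = None,
    contig: str | None = None,
) -> Iterator[CoverageRecord]:
    """One record per genomic position.

    Zero-depth positions are omitted unless *include_zeros*, in which case
    every position 1..contig_length is emitted.
    """
    vecs = _as_vector_list(cov)
    if include_zeros and contig_length is None:
        raise ValueError("include_zeros requires contig_length")
    prev_end = 0
    if vecs:
        contig = vecs[0].contig
    for v in vecs:
        if include_zeros:
            for p in range(prev_end + 1, v.start):
                yield CoverageRecord(v.contig, p, p, 0)
        for k, depth in enumerate(v.values.tolist()):
            if depth or include_zeros:
                p = v.start + k
                yield CoverageRecord(v.contig, p, p, depth)
        prev_end = v.end
    if include_zeros and contig is not None:
        for p in range(prev_end + 1, contig_length + 1):
            yield CoverageRecord(contig, p, p, 0)


def _runs(values: np.ndarray) -> Iterator[tuple[int, int, int]]:
    """Yield (offset, run_length, value) for maximal equal-value runs."""
    if values.size == 0:
        return
    change = np.flatnonzero(np.diff(values)) + 1
    bounds = np.concatenate(([0], change, [values.size]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        yield int(lo), int(hi - lo), int(values[lo])


def to_blocks(
    cov: PartialCoverage | Sequence[PartialCoverage],
    include_zeros: bool = False,
    contig_length: int | None = None,
    contig: str | None = None,
) -> Iterator[CoverageRecord]:
    """Merge adjacent equal-depth positions into intervals (lossless vs per-base)."""
    vecs = _as_vector_list(cov)
    if include_zeros and contig_length is None:
        raise ValueError("include_zeros requires contig_length")
    prev_end = 0
    if vecs:
        contig = vecs[0].contig
    for v in vecs:
        if include_zeros and v.start > prev_end + 1:
            yield CoverageRecord(v.contig, prev_end + 1, v.start - 1, 0)
        for off, run, depth in _runs(v.values):
            if depth or include_zeros:
                yield CoverageRecord(v.contig, v.start + off, v.start + off + run - 1, depth)
        prev_end = v.end
    if include_zeros and contig is not None and prev_end < contig_length:
        yield CoverageRecord(contig, prev_end + 1, contig_length, 0)


def to_windows(
    cov: PartialCoverage | Sequence[PartialCoverage],
    window: int,
    contig_length: int,
    contig: str | None = None,
) -> Iterator[CoverageRecord]:
    """Tile the contig from position 1 in fixed windows and report mean depth.

    Zero-depth positions always enter the means; the terminal window may be
    shorter than *window* and its mean is over its actual length.
    """
    if window < 1:
        raise ValueError(f"window size must be >= 1, got {window}")
    vecs = _as_vector_list(cov)
    n_windows = (contig_length + window - 1) // window
    sums = np.zeros(n_windows, dtype=np.float64)
    if vecs:
        contig = vecs[0].contig
    for v in vecs:
        idx = (np.arange(v.start - 1, v.end)) // window
        sums += np.bincount(idx, weights=v.values.astype(np.float64), minlength=n_windows)
        contig = v.contig
    if contig is None:
        return
    for w in range(n_windows):
        lo = w * window + 1
        hi = min((w + 1) * window, contig_length)
        yield CoverageRecord(contig, lo, hi, sums[w] / (hi - lo + 1))
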