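"""Cross-partition overlap correction and the end-to-end coverage pipeline.

Partition boundaries fall at arbitrary reads, so the partial coverage vectors
of consecutive partitions may overlap on the reference. Where an overlap of
length l exists, the l tailing values of the left vector are added elementwise
onto the head of the right vector and then removed from the left. A
left-to-right fold applies this pairwise, with the corrected right vector
carrying any accumulated tail into the next comparison — this handles reads
whose blocks span several downstream partitions and makes the result equal to
the single-partition computation.

The gather–scatter coordination is realized in-process (optionally over a
worker pool): workers return (extent, vector) pairs and the coordinator folds
them per contig.
"""

from __future__ import annotations

import multiprocessing
import os
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .core import (
    CoverageRecord,
    PartialCoverage,
    build_events,
    events_to_partial,
    promote_depths,
    to_blocks,
    to_per_base,
    to_windows,
)
from .io import ReadFilter, ReadSlice, partition_reads, read_alignments, read_header

RESULT_TYPES = ("per-base", "blocks", "windows")


@dataclass(frozen=True)
class Overlap:
    """Genomic intersection of length ``length`` between two consecutive partitions' vectors."""

    left_partition: int
    right_partition: int
    contig: str
    length: int


def detect_overlap(left: PartialCoverage, right: PartialCoverage) -> Overlap | None:
    """Return the overlap between consecutive partial vectors, or None.

    Abutting vectors (left ends exactly where right starts minus one) do not
    overlap. Vectors on different contigs never overlap.
    """
    if left.contig != right.contig:
        return None
    if len(left.values) == 0 or len(right.values) == 0:
        return None
    if right.start < left.start:
        raise ValueError(
            f"partitions out of order on {left.contig}: partition "
            f"{right.partition} starts at {right.start}, before partition "
            f"{left.partition} at {left.start}"
        )
    length = left.end - right.start + 1
    if length <= 0:
        return None
    return Overlap(left.partition, right.partition, left.contig, length)


def _trim_trailing_zeros(values: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(values)
    return values[: int(nz[-1]) + 1] if nz.size else values[:0]


def apply_correction(
    left: PartialCoverage, right: PartialCoverage, ov: Overlap
) -> tuple[PartialCoverage, PartialCoverage]:
    """Cut the left vector's l-length tail and add it onto the right vector's head.

    Total coverage mass is conserved. If the tail reaches past the right
    vector's end (a long block spanning several partitions), the right vector
    is zero-extended to the tail's end before the addition, so the fold can
    cascade the remainder into later partitions.
    """
    l = ov.length
    if l > len(left.values):
        raise ValueError(
            f"overlap length {l} exceeds left vector length {len(left.values)} "
            f"on {ov.contig}"
        )
    tail = left.values[-l:].astype(np.int64)
    # zero-extend right out to the end of the overlapped region if needed
    needed = max(len(right.values), l)
    head = np.zeros(needed, dtype=np.int64)
    head[: len(right.values)] = right.values
    head[:l] += tail
    new_right = PartialCoverage(right.partition, right.contig, right.start,
                                promote_depths(head))
    new_left_values = _trim_trailing_zeros(left.values[:-l])
    new_left = PartialCoverage(left.partition, left.contig, left.start,
                               promote_depths(new_left_values.astype(np.int64)))
    return new_left, new_right


def merge_partials(
    partials: Sequence[PartialCoverage],
) -> dict[str, list[PartialCoverage]]:
    """Fold per-partition vectors into non-overlapping final vectors per contig.

    Input must be in partition order. Gaps between partitions' extents
    (regions with no reads) are preserved, never interpolated.
    """
    by_contig: dict[str, list[PartialCoverage]] = {}
    for pc in partials:
        holders = by_contig.setdefault(pc.contig, [])
        if holders and pc.partition < holders[-1].partition:
            raise ValueError(
                f"partial coverage vectors out of partition order on {pc.contig}"
            )
        holders.append(pc)

    final: dict[str, list[PartialCoverage]] = {}
    for contig, vecs in by_contig.items():
        vecs = [v for v in vecs if len(v.values)]
        merged: list[PartialCoverage] = []
        if not vecs:
            final[contig] = merged
            continue
        cur = vecs[0]
        for nxt in vecs[1:]:
            ov = detect_overlap(cur, nxt)
            if ov is not None:
                cur, nxt = apply_correction(cur, nxt, ov)
            if len(cur.values):
                merged.append(cur)
            cur = nxt
        if len(cur.values):
            merged.append(cur)
        final[contig] = merged
    return final


def _slice_partials(
    args: tuple[ReadSlice, bool, dict[str, int]],
) -> list[PartialCoverage]:
    read_slice, count_deletions, contig_lengths = args
    return [
        events_to_partial(ev)
        for ev in build_events(read_slice, count_deletions, contig_lengths)
    ]


def coverage_vectors(
    path: str | os.PathLike,
    n_partitions: int = 1,
    workers: int = 1,
    read_filter: ReadFilter | None = None,
    count_deletions: bool = True,
) -> tuple[dict[str, int], dict[str, list[PartialCoverage]]]:
    """Run read → filter → partition → events → partial → merge; return header and final vectors."""
    contig_lengths = read_header(path)
    reads = list(read_alignments(path, read_filter))
    slices = partition_reads(reads, n_partitions)
    jobs = [(s, count_deletions, contig_lengths) for s in slices]
    if workers > 1 and len(jobs) > 1:
        with multiprocessing.get_context("fork").Pool(min(workers, len(jobs))) as pool:
            per_slice = pool.map(_slice_partials, jobs)
    else:
        per_slice = [_slice_partials(j) for j in jobs]
    partials = [pc for group in per_slice for pc in group]
    return contig_lengths, merge_partials(partials)


def compute_coverage(
    path: str | os.PathLike,
    result_type: str = "per-base",
    window: int | None = None,
    n_partitions: int = 1,
    workers: int = 1,
    read_filter: ReadFilter | None = None,
    count_deletions: bool = True,
    include_zeros: bool = False,
) -> Iterator[CoverageRecord]:
    """End-to-end depth of coverage for a coordinate-sorted SAM/BAM.

    The result is a pure function of the file contents and parameters:
    identical for every (n_partitions, workers) combination. Records are
    ordered by (contig header order, position). ``result_type`` is one of
    ``per-base``, ``blocks`` or ``windows`` (the latter requires *window*).
    """
    if result_type not in RESULT_TYPES:
        raise ValueError(f"result_type must be one of {RESULT_TYPES}, got {result_type!r}")
    if result_type == "windows" and (window is None or window < 1):
        raise ValueError("windows output requires a window size >= 1")
    contig_lengths, final = coverage_vectors(
        path, n_partitions, workers, read_filter, count_deletions
    )
    for contig, clen in contig_lengths.items():  # header order
        vecs = final.get(contig, [])
        if result_type == "per-base":
            if vecs or include_zeros:
                yield from to_per_base(vecs, include_zeros, clen, contig=contig)
        elif result_type == "blocks":
            if vecs or include_zeros:
                yield from to_blocks(vecs, include_zeros, clen, contig=contig)
        else:
            yield from to_windows(vecs, window, clen, contig=contig)
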