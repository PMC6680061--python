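"""Synthetic coordinate-sorted SAM/BAM generation and a brute-force pileup oracle.

The generator emulates the layout features depth of coverage depends on —
read placement, CIGAR structure (matches, insertions, deletions, splice
skips, soft clips), duplicate/secondary/QC-fail/unmapped flags and MAPQ —
and nothing else: base content and qualities are constant because coverage
never reads them.

The oracle deliberately implements the naive pileup approach: it walks every
read's CIGAR position by position and increments a per-base counter. It
shares no code with the event-based path, which is what gives agreement
between the two its evidential value.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .io import ReadFilter

# CIGAR op codes (SAM order); kept local so the oracle stays independent.
_M, _I, _D, _N, _S = 0, 1, 2, 3, 4
_OPS = "MIDNSHP=X"
_QUERY_CONSUMING = {_M, _I, _S, 7, 8}
_REF_CONSUMING = {_M, _D, _N, 7, 8}

_FLAG_UNMAP, _FLAG_SECONDARY, _FLAG_QCFAIL, _FLAG_DUP = 0x4, 0x100, 0x200, 0x400


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic read layout; a given seed reproduces it exactly."""

    contigs: tuple[tuple[str, int], ...] = (("chr1", 10_000), ("chr2", 6_000))
    n_reads: int = 1_000
    read_length: int = 100  # matched reference bases per read
    p_insertion: float = 0.05  # per internal junction
    p_deletion: float = 0.05
    p_skip: float = 0.02  # N ops, spliced-alignment introns
    p_softclip: float = 0.10  # per read end
    indel_length: tuple[int, int] = (1, 5)  # inclusive range
    skip_length: tuple[int, int] = (20, 200)
    frac_duplicate: float = 0.05
    frac_secondary: float = 0.03
    frac_qcfail: float = 0.02
    frac_unmapped: float = 0.02
    mapq_range: tuple[int, int] = (0, 60)  # inclusive
    start_range: tuple[int, int] | None = None  # fixed 1-based start window, else whole contig
    seed: int = 0


def _random_cigar(rng: np.random.Generator, spec: FixtureSpec) -> list[tuple[int, int]]:
    """Draw a CIGAR with spec.read_length matched bases and random gap structure."""
    ops: list[tuple[int, int]] = []
    if rng.random() < spec.p_softclip:
        ops.append((_S, int(rng.integers(1, 11))))
    remaining = spec.read_length
    seg_hi = max(2, spec.read_length)
    while remaining > 0:
        seg = int(min(remaining, rng.integers(max(1, spec.read_length // 4), seg_hi + 1)))
        ops.append((_M, seg))
        remaining -= seg
        if remaining > 0:
            r = rng.random()
            lo, hi = spec.indel_length
            if r < spec.p_insertion:
                ops.append((_I, int(rng.integers(lo, hi + 1))))
            elif r < spec.p_insertion + spec.p_deletion:
                ops.append((_D, int(rng.integers(lo, hi + 1))))
            elif r < spec.p_insertion + spec.p_deletion + spec.p_skip:
                slo, shi = spec.skip_length
                ops.append((_N, int(rng.integers(slo, shi + 1))))
    if rng.random() < spec.p_softclip:
        ops.append((_S, int(rng.integers(1, 11))))
    # coalesce adjacent identical ops so the CIGAR is canonical
    out: list[tuple[int, int]] = []
    for op, ln in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def _ref_span(cigar: Sequence[tuple[int, int]]) -> int:
    return sum(ln for op, ln in cigar if op in _REF_CONSUMING)


def _query_len(cigar: Sequence[tuple[int, int]]) -> int:
    return sum(ln for op, ln in cigar if op in _QUERY_CONSUMING)


def _truth_blocks(start: int, cigar: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Covered intervals under the count-deletions policy, by an independent cursor walk."""
    blocks: list[tuple[int, int]] = []
    pos = start
    for op, ln in cigar:
        if op in (_M, _D, 7, 8):
            if blocks and blocks[-1][0] + blocks[-1][1] == pos:
                blocks[-1] = (blocks[-1][0], blocks[-1][1] + ln)
            else:
                blocks.append((pos, ln))
            pos += ln
        elif op == _N:
            pos += ln
    return blocks


def generate_fixture(
    spec: FixtureSpec, out_path: str | os.PathLike
) -> tuple[str, pd.DataFrame]:
    """Write a coordinate-sorted SAM (or BAM, by extension) matching *spec*.

    Returns the path and a truth table with one row per alignment block of
    every mapped read, before any filtering (columns: qname, contig, start,
    cigar, flags, mapq, block_start, block_len).
    """
    rng = np.random.default_rng(spec.seed)
    out_path = os.fspath(out_path)
    contig_names = [c for c, _ in spec.contigs]
    contig_lengths = {c: l for c, l in spec.contigs}

    records = []
    for i in range(spec.n_reads):
        qname = f"read{i:06d}"
        r = rng.random()
        flags = 0
        if r < spec.frac_unmapped:
            flags = _FLAG_UNMAP
        elif r < spec.frac_unmapped + spec.frac_duplicate:
            flags = _FLAG_DUP
        elif r < spec.frac_unmapped + spec.frac_duplicate + spec.frac_secondary:
            flags = _FLAG_SECONDARY
        elif r < (spec.frac_unmapped + spec.frac_duplicate
                  + spec.frac_secondary + spec.frac_qcfail):
            flags = _FLAG_QCFAIL
        mapq = int(rng.integers(spec.mapq_range[0], spec.mapq_range[1] + 1))
        if flags & _FLAG_UNMAP:
            records.append((None, 0, [], flags, 0, qname))
            continue
        contig = contig_names[int(rng.integers(len(contig_names)))]
        cigar = _random_cigar(rng, spec)
        span = _ref_span(cigar)
        clen = contig_lengths[contig]
        if span > clen:
            raise ValueError(
                f"read span {span} exceeds contig {contig} length {clen}; "
                "shorten reads or lengthen contigs"
            )
        if spec.start_range is not None:
            lo, hi = spec.start_range
            hi = min(hi, clen - span + 1)
        else:
            lo, hi = 1, clen - span + 1
        if hi < lo:
            raise ValueError(f"no legal start for span {span} on {contig}:{lo}-")
        start = int(rng.integers(lo, hi + 1))  # 1-based
        records.append((contig, start, cigar, flags, mapq, qname))

    order = {c: i for i, c in enumerate(contig_names)}
    mapped = sorted(
        (r for r in records if r[0] is not None), key=lambda r: (order[r[0]], r[1])
    )
    unmapped = [r for r in records if r[0] is None]

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": l} for c, l in spec.contigs],
    }
    mode = "wb" if out_path.endswith(".bam") else "w"
    truth_rows = []
    with pysam.AlignmentFile(out_path, mode, header=header) as af:
        for contig, start, cigar, flags, mapq, qname in mapped + unmapped:
            seg = pysam.AlignedSegment(af.header)
            seg.query_name = qname
            seg.flag = flags
            if contig is None:
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
                seg.query_sequence = "A" * 10
            else:
                seg.reference_id = contig_names.index(contig)
                seg.reference_start = start - 1
                seg.mapping_quality = mapq
                seg.cigartuples = cigar
                seg.query_sequence = "A" * _query_len(cigar)
                for bs, bl in _truth_blocks(start, cigar):
                    truth_rows.append((qname, contig, start, flags, mapq, bs, bl))
            af.write(seg)
    if mode == "wb":
        pysam.index(out_path)
    truth = pd.DataFrame(
        truth_rows,
        columns=["qname", "contig", "start", "flags", "mapq", "block_start", "block_len"],
    )
    return out_path, truth


def pileup_oracle(
    path: str | os.PathLike,
    read_filter: ReadFilter | None = None,
    count_deletions: bool = True,
) -> pd.DataFrame:
    """Brute-force per-base depth: walk every kept read's CIGAR base by base.

    Returns a table (contig, pos, coverage) of positions with nonzero depth,
    sorted by (contig header order, pos). Filtering matches the main path's
    contract — a read is kept iff (flags & exclude_flags) == 0 and
    mapq >= min_mapq — but is re-implemented here.
    """
    read_filter = read_filter or ReadFilter()
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as af:
        counters = {
            c: np.zeros(l, dtype=np.int64) for c, l in zip(af.references, af.lengths)
        }
        contig_order = list(af.references)
        for rec in af:
            if rec.is_unmapped:
                continue
            if (rec.flag & read_filter.exclude_flags) != 0:
                continue
            if rec.mapping_quality < read_filter.min_mapq:
                continue
            counter = counters[rec.reference_name]
            pos = rec.reference_start  # 0-based cursor
            for op, ln in rec.cigartuples:
                if op in (_M, 7, 8) or (op == _D and count_deletions):
                    for p in range(pos, pos + ln):
                        counter[p] += 1
                    pos += ln
                elif op in (_D, _N):
                    pos += ln
    frames = []
    for contig in contig_order:
        counter = counters[contig]
        nz = np.flatnonzero(counter)
        if nz.size:
            frames.append(
                pd.DataFrame(
                    {"contig": contig, "pos": nz + 1, "coverage": counter[nz]}
                )
            )
    if not frames:
        return pd.DataFrame(columns=["contig", "pos", "coverage"])
    return pd.concat(frames, ignore_index=True)
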