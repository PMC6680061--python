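import pandas as pd
import pysam
import pytest

from eventcov import FixtureSpec, generate_fixture


@pytest.fixture
def small_fixture(tmp_path):
    """A modest mixed fixture (SAM) with flagged reads and indel/skip CIGARs."""
    spec = FixtureSpec(n_reads=400, seed=42)
    path, truth = generate_fixture(spec, tmp_path / "small.sam")
    return path, truth, spec


@pytest.fixture
def clean_fixture(tmp_path):
    """All-mapped, all-kept reads with plain match CIGARs on one contig."""
    spec = FixtureSpec(
        contigs=(("chr1", 5_000),),
        n_reads=300,
        read_length=80,
        p_insertion=0.0,
        p_deletion=0.0,
        p_skip=0.0,
        p_softclip=0.0,
        frac_duplicate=0.0,
        frac_secondary=0.0,
        frac_qcfail=0.0,
        frac_unmapped=0.0,
        seed=7,
    )
    path, truth = generate_fixture(spec, tmp_path / "clean.sam")
    return path, truth, spec


def write_sam(path, contigs, records):
    """Write a hand-specified SAM: records are (qname, flag, contig, start1, cigar, mapq)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": l} for c, l in contigs],
    }
    names = [c for c, _ in contigs]
    with pysam.AlignmentFile(str(path), "w", header=header) as af:
        for qname, flag, contig, start1, cigar, mapq in records:
            seg = pysam.AlignedSegment(af.header)
            seg.query_name = qname
            seg.flag = flag
            if contig is None:
                seg.reference_id = -1
                seg.reference_start = -1
                seg.query_sequence = "A" * 10
            else:
                seg.reference_id = names.index(contig)
                seg.reference_start = start1 - 1
                seg.mapping_quality = mapq
                seg.cigarstring = cigar
                seg.query_sequence = "A" * sum(
                    ln for op, ln in seg.cigartuples if op in (0, 1, 4, 7, 8)
                )
            af.write(seg)
    return path


def records_frame(records):
    """Per-base CoverageRecords -> (contig, pos, coverage) DataFrame for comparisons."""
    return pd.DataFrame(
        [(r.contig, r.pos_start, int(r.coverage)) for r in records],
        columns=["contig", "pos", "coverage"],
    )
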