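import numpy as np
import pytest

from eventcov import (
    PartialCoverage,
    apply_correction,
    compute_coverage,
    detect_overlap,
    merge_partials,
)

from conftest import records_frame, write_sam


def _pc(values, start, partition=0, contig="chr3"):
    return PartialCoverage(partition, contig, start, np.asarray(values, dtype=np.uint16))


class TestDetectOverlap:
    def test_worked_boundary_overlap(self):
        # left ends at chr3:104, right starts at chr3:101 -> length-4 overlap
        left = _pc([1, 1, 1, 1, 1, 1], start=99, partition=1)
        right = _pc([2, 2, 2, 2, 2], start=101, partition=2)
        ov = detect_overlap(left, right)
        assert ov is not None
        assert ov.length == 4
        assert (ov.contig, ov.left_partition, ov.right_partition) == ("chr3", 1, 2)
        # the overlapped positions are chr3:101-104
        assert (right.start, left.end) == (101, 104)

    def test_abutting_vectors_do_not_overlap(self):
        assert detect_overlap(_pc([1], 100), _pc([1], 101, partition=1)) is None

    def test_disjoint_vectors(self):
        assert detect_overlap(_pc([1], 100), _pc([1], 150, partition=1)) is None

    def test_different_contigs_are_never_overlaps(self):
        left = _pc([1, 1], 100, contig="chr1")
        right = _pc([1, 1], 100, partition=1, contig="chr2")
        assert detect_overlap(left, right) is None

    def test_misordered_partitions_rejected(self):
        with pytest.raises(ValueError, match="out of order"):
            detect_overlap(_pc([1, 1], 200), _pc([1, 1], 150, partition=1))


class TestApplyCorrection:
    def test_tail_cut_and_head_add(self):
        left = _pc([3, 2, 1, 1, 1, 1], start=99, partition=1)
        right = _pc([2, 2, 2, 2, 5], start=101, partition=2)
        ov = detect_overlap(left, right)
        new_left, new_right = apply_correction(left, right, ov)
        assert new_left.values.tolist() == [3, 2]
        assert new_left.end == 100
        assert new_right.values.tolist() == [3, 3, 3, 3, 5]
        assert new_right.start == 101

    def test_mass_conserved(self):
        rng = np.random.default_rng(21)
        left = _pc(rng.integers(1, 9, 40), start=1, partition=0)
        right = _pc(rng.integers(1, 9, 30), start=25, partition=1)
        ov = detect_overlap(left, right)
        before = int(left.values.sum() + right.values.sum())
        new_left, new_right = apply_correction(left, right, ov)
        assert int(new_left.values.sum() + new_right.values.sum()) == before

    def test_full_overlap_empties_left(self):
        left = _pc([1, 2, 3], start=100, partition=0)
        right = _pc([4, 4, 4, 4], start=100, partition=1)
        ov = detect_overlap(left, right)
        new_left, new_right = apply_correction(left, right, ov)
        assert len(new_left.values) == 0
        assert new_right.values.tolist() == [5, 6, 7, 4]

    def test_tail_longer_than_right_vector_extends_it(self):
        # a long left block reaching past the whole right vector
        left = _pc([1] * 20, start=1, partition=0)
        right = _pc([2, 2], start=5, partition=1)
        ov = detect_overlap(left, right)
        assert ov.length == 16
        new_left, new_right = apply_correction(left, right, ov)
        assert new_left.values.tolist() == [1] * 4
        assert new_right.values.tolist() == [3, 3] + [1] * 14
        assert new_right.end == 20


class TestMergePartials:
    def test_single_partition_is_identity(self):
        pc = _pc([1, 2, 1], start=10)
        (out,) = merge_partials([pc])["chr3"]
        assert out.values.tolist() == [1, 2, 1] and out.start == 10

    def test_fold_produces_non_overlapping_vectors(self):
        parts = [
            _pc([1, 1, 1, 1, 1, 1], start=99, partition=0),
            _pc([2, 2, 2, 2], start=101, partition=1),
            _pc([1, 1], start=120, partition=2),
        ]
        merged = merge_partials(parts)["chr3"]
        ends = [v.end for v in merged]
        starts = [v.start for v in merged]
        assert all(e < s for e, s in zip(ends, starts[1:]))
        total = sum(int(v.values.sum()) for v in merged)
        assert total == sum(int(p.values.sum()) for p in parts)

    def test_out_of_partition_order_rejected(self):
        with pytest.raises(ValueError, match="partition order"):
            merge_partials([_pc([1], 1, partition=2), _pc([1], 5, partition=1)])

    def test_gaps_preserved_not_interpolated(self):
        parts = [_pc([1, 1], 10, partition=0), _pc([1, 1], 500, partition=1)]
        merged = merge_partials(parts)["chr3"]
        assert [(v.start, v.end) for v in merged] == [(10, 11), (500, 501)]


class TestComputeCoverage:
    CONTIGS = (("chr1", 2_000),)

    def test_header_only_input(self, tmp_path):
        path = write_sam(tmp_path / "e.sam", self.CONTIGS, [])
        assert list(compute_coverage(path, "per-base")) == []

    def test_single_short_read_per_base(self, tmp_path):
        path = write_sam(
            tmp_path / "one.sam", self.CONTIGS, [("r1", 0, "chr1", 10, "3M", 60)]
        )
        recs = list(compute_coverage(path, "per-base"))
        assert [(r.contig, r.pos_start, r.pos_end, r.coverage) for r in recs] == [
            ("chr1", 10, 10, 1),
            ("chr1", 11, 11, 1),
            ("chr1", 12, 12, 1),
        ]

    def test_read_spanning_many_singleton_partitions(self, tmp_path):
        # one 600-base block followed by many tiny reads, one read per partition:
        # the long block's tail must cascade through >3 downstream partitions
        records = [("long", 0, "chr1", 1, "600M", 60)]
        records += [(f"s{i}", 0, "chr1", 50 + 100 * i, "10M", 60) for i in range(6)]
        path = write_sam(tmp_path / "span.sam", self.CONTIGS, records)
        baseline = records_frame(compute_coverage(path, "per-base", n_partitions=1))
        for n in (2, 3, 7):
            got = records_frame(compute_coverage(path, "per-base", n_partitions=n))
            assert got.equals(baseline), f"n_partitions={n} diverged"

    def test_partition_and_worker_invariance(self, small_fixture):
        path, _, _ = small_fixture
        baseline = records_frame(compute_coverage(path, "per-base", n_partitions=1))
        for n in (2, 5, 16):
            for w in (1, 2):
                got = records_frame(
                    compute_coverage(path, "per-base", n_partitions=n, workers=w)
                )
                assert got.equals(baseline)

    def test_windows_requires_window(self, small_fixture):
        path, _, _ = small_fixture
        with pytest.raises(ValueError, match="window"):
            list(compute_coverage(path, "windows"))

    def test_unknown_result_type(self, small_fixture):
        path, _, _ = small_fixture
        with pytest.raises(ValueError, match="result_type"):
            list(compute_coverage(path, "perbase"))

    def test_records_ordered_by_header_and_position(self, small_fixture):
        path, _, spec = small_fixture
        recs = list(compute_coverage(path, "per-base", n_partitions=4))
        names = [c for c, _ in spec.contigs]
        keys = [(names.index(r.contig), r.pos_start) for r in recs]
        assert keys == sorted(keys)

    def test_windows_tile_all_contigs_completely(self, small_fixture):
        path, _, spec = small_fixture
        recs = list(compute_coverage(path, "windows", window=500))
        per_contig = {}
        for r in recs:
            per_contig.setdefault(r.contig, []).append(r)
        for contig, clen in spec.contigs:
            ws = per_contig[contig]
            assert ws[0].pos_start == 1
            assert ws[-1].pos_end == clen
            # contiguous tiling
            for a, b in zip(ws, ws[1:]):
                assert b.pos_start == a.pos_end + 1
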