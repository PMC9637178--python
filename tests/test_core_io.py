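import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petloop.core_io import (
    GenomicInterval,
    Loop,
    PET,
    PETIndex,
    Profile1D,
    query_rectangle,
    read_bedpe,
    read_loops,
    read_profile,
    write_bedpe,
    write_loops,
    write_profile,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestGenomicInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_midpoint_and_length(self):
        assert iv(10, 20).midpoint == 15
        assert iv(10, 20).length == 10

    def test_overlaps_half_open(self):
        assert iv(0, 10).overlaps(iv(9, 20))
        assert not iv(0, 10).overlaps(iv(10, 20))
        assert not iv(0, 10).overlaps(iv(0, 10, chrom="chr2"))

    def test_expand_clamps_at_zero(self):
        assert iv(100, 200).expand(500) == iv(0, 700)


class TestPET:
    def test_ordered_swaps_ends(self):
        p = PET.ordered(iv(5000, 5100), iv(1000, 1100), 10, 20, True, False)
        assert p.left.start == 1000
        assert p.mapq_left == 20
        assert p.linker_left is False
        assert p.distance == 4000

    def test_trans_distance_undefined(self):
        p = PET(iv(0, 100), iv(0, 100, chrom="chr2"))
        assert not p.is_cis
        with pytest.raises(ValueError):
            p.distance


class TestReadBedpe:
    def test_two_lines_pass_through(self, tmp_path):
        path = tmp_path / "a.bedpe"
        path.write_text(
            "chr1\t100\t200\tchr1\t5000\t5100\tp0\t30\t.\t.\n"
            "chr1\t300\t400\tchr1\t9000\t9100\tp1\t30\t.\t.\n"
        )
        coll = read_bedpe(path)
        assert len(coll.cis) == 2 and not coll.trans

    def test_start_after_end_errors_with_line_number(self, tmp_path):
        path = tmp_path / "a.bedpe"
        path.write_text("chr1\t200\t100\tchr1\t5000\t5100\n")
        with pytest.raises(ValueError, match="line 1"):
            read_bedpe(path)

    def test_mapq_filter(self, tmp_path):
        path = tmp_path / "a.bedpe"
        path.write_text(
            "chr1\t100\t200\tchr1\t5000\t5100\tp0\t30\t.\t.\n"
            "chr1\t100\t200\tchr1\t5000\t5100\tp1\t5\t.\t.\n"
            "chr1\t300\t400\tchr1\t9000\t9100\tp2\t30\t.\t.\n"
        )
        assert len(read_bedpe(path, mapq_min=10).cis) == 2

    def test_trans_stored_separately(self, tmp_path):
        path = tmp_path / "a.bedpe"
        path.write_text("chr1\t100\t200\tchr2\t5000\t5100\n")
        coll = read_bedpe(path)
        assert not coll.cis and len(coll.trans) == 1

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        pets = [
            PET.ordered(iv(100, 200), iv(5000, 5100), 30, 30, True, False),
            PET.ordered(iv(7000, 7100), iv(300, 400), 30, 30),
        ]
        path = tmp_path / "rt.bedpe"
        write_bedpe(pets, path)
        back = read_bedpe(path).cis
        assert [(p.left.start, p.left.end, p.right.start, p.right.end) for p in back] == [
            (100, 200, 5000, 5100),
            (300, 400, 7000, 7100),
        ]
        assert back[0].linker_left and not back[0].linker_right

    def test_ordering_canonical_after_read(self, tmp_path):
        path = tmp_path / "a.bedpe"
        path.write_text("chr1\t9000\t9100\tchr1\t100\t200\n")
        p = read_bedpe(path).cis[0]
        assert p.left.start == 100 and p.distance > 0


class TestPETIndex:
    def test_empty_query(self):
        index = PETIndex.from_pets([])
        assert query_rectangle(index, iv(0, 100), iv(200, 300)) == 0

    def test_all_inside(self):
        pets = [
            PET.ordered(iv(100 + i, 150 + i), iv(5000 + i, 5050 + i))
            for i in range(10)
        ]
        index = PETIndex.from_pets(pets)
        assert query_rectangle(index, iv(0, 1000), iv(4000, 6000)) == 10

    def test_cross_chromosome_query_errors(self):
        index = PETIndex.from_pets([])
        with pytest.raises(ValueError):
            query_rectangle(index, iv(0, 100), iv(0, 100, chrom="chr2"))

    def test_random_queries_match_brute_force(self):
        rng = np.random.default_rng(0)
        xs = rng.integers(0, 100_000, 1000)
        ds = rng.integers(0, 50_000, 1000)
        pets = [
            PET.ordered(iv(int(x), int(x) + 50), iv(int(x + d), int(x + d) + 50))
            for x, d in zip(xs, ds)
        ]
        index = PETIndex.from_pets(pets)
        mids = np.array(
            [(p.left.midpoint, p.right.midpoint) for p in pets]
        )
        for _ in range(50):
            x0, y0 = rng.integers(0, 120_000, 2)
            wx, wy = rng.integers(1, 30_000, 2)
            expected = int(
                np.sum(
                    (mids[:, 0] >= x0)
                    & (mids[:, 0] < x0 + wx)
                    & (mids[:, 1] >= y0)
                    & (mids[:, 1] < y0 + wy)
                )
            )
            got = query_rectangle(
                index, iv(int(x0), int(x0 + wx)), iv(int(y0), int(y0 + wy))
            )
            assert got == expected

    def test_marginal_counts_and_distance_fraction(self):
        pets = [
            PET.ordered(iv(0, 100), iv(1000, 1100)),
            PET.ordered(iv(0, 100), iv(5000, 5100)),
            PET.ordered(iv(9000, 9100), iv(20000, 20100)),
        ]
        index = PETIndex.from_pets(pets)
        assert index.count_left("chr1", 0, 200) == 2
        assert index.count_right("chr1", 0, 6000) == 2
        assert index.distance_fraction("chr1", 0, 2000) == pytest.approx(1 / 3)


@settings(max_examples=25, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 5000), st.integers(0, 2000), st.integers(0, 5000)
        ),
        max_size=60,
    ),
    st.integers(0, 6000),
    st.integers(1, 3000),
    st.integers(0, 8000),
    st.integers(1, 3000),
)
def test_rectangle_query_equals_scan_property(rows, x0, wx, y0, wy):
    pets = [
        PET.ordered(iv(a, a + 20), iv(a + b, a + b + 20))
        for a, b, _ in rows
    ]
    index = PETIndex.from_pets(pets)
    expected = sum(
        x0 <= p.left.midpoint < x0 + wx and y0 <= p.right.midpoint < y0 + wy
        for p in pets
    )
    assert query_rectangle(index, iv(x0, x0 + wx), iv(y0, y0 + wy)) == expected


class TestLoopIO:
    def make_loops(self):
        return [
            Loop(iv(1000, 2000), iv(50_000, 51_000), 15, 1e-5, 8.0, "loop_0"),
            Loop(iv(9000, 9500), iv(90_000, 91_000), 22, 1e-9, 12.5, "loop_1"),
        ]

    def test_tsv_roundtrip(self, tmp_path):
        loops = self.make_loops()
        path = tmp_path / "loops.tsv"
        write_loops(loops, path, "tsv")
        assert read_loops(path) == loops

    def test_single_loop_has_header_and_row(self, tmp_path):
        path = tmp_path / "one.tsv"
        write_loops(self.make_loops()[:1], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 2 and lines[0].startswith("chrom1\t")

    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_loops([], path)
        assert len(path.read_text().splitlines()) == 1

    def test_washu_longrange(self, tmp_path):
        path = tmp_path / "loops.washU.txt"
        write_loops(self.make_loops(), path, "washU")
        first = path.read_text().splitlines()[0]
        assert first == "chr1\t1000\t2000\tchr1:50000-51000,15"

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError):
            write_loops([], tmp_path / "x", dialect="bed")

    def test_loop_validation(self):
        with pytest.raises(ValueError):
            Loop(iv(5000, 6000), iv(1000, 2000))
        with pytest.raises(ValueError):
            Loop(iv(0, 10), iv(20, 30), p_value=1.5)


class TestProfileIO:
    def test_single_nonzero_row(self, tmp_path):
        prof = Profile1D(iv(0, 300), 100, np.array([0.0, 2.0, 0.0]))
        path = tmp_path / "p.bedgraph"
        write_profile(prof, path)
        assert path.read_text() == "chr1\t100\t200\t2.0\n"

    def test_all_zero_empty(self, tmp_path):
        prof = Profile1D(iv(0, 300), 100, np.zeros(3))
        path = tmp_path / "p.bedgraph"
        write_profile(prof, path)
        assert path.read_text() == ""

    def test_roundtrip_nonzero_values(self, tmp_path):
        values = np.array([0.0, 1.5, 0.0, 3.25, 0.5])
        prof = Profile1D(iv(1000, 1500), 100, values)
        path = tmp_path / "p.bedgraph"
        write_profile(prof, path)
        back = read_profile(path, iv(1000, 1500), 100)
        np.testing.assert_array_equal(back.values, values)

    def test_bin_count_validation(self):
        with pytest.raises(ValueError):
            Profile1D(iv(0, 250), 100, np.zeros(2))  # ceil(250/100) = 3
        Profile1D(iv(0, 250), 100, np.zeros(3))
        with pytest.raises(ValueError):
            Profile1D(iv(0, 300), 100, np.array([0.0, -1.0, 0.0]))
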