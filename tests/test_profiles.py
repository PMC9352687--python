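import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnclonal import (
    AUTOSOMES,
    GenomeModel,
    GenomicInterval,
    SegFormatError,
    Segment,
    SegmentedProfile,
    harmonize_pair,
    infer_genome_from_seg,
    read_seg,
    restrict_to_autosomes,
    weighted_mean_std,
    write_seg,
)
from conftest import make_profile, random_segmentation


class TestGenomeModel:
    def test_toy(self):
        g = GenomeModel.toy()
        assert g.names == AUTOSOMES
        assert g.total_length == 22 * 10_000_000

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            GenomeModel(("1", "1"), (10, 10))

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            GenomeModel(("1",), (0,))

    def test_from_chrom_sizes(self, tmp_path):
        p = tmp_path / "sizes.txt"
        p.write_text("chr1\t1000\n2\t800\n")
        g = GenomeModel.from_chrom_sizes(p)
        assert g.names == ("1", "2")
        assert g.lengths == (1000, 800)


class TestInvariants:
    def test_interval_rejects_empty(self):
        with pytest.raises(ValueError):
            GenomicInterval("1", 100, 100)

    def test_segment_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            Segment(GenomicInterval("1", 0, 10), float("nan"))

    def test_profile_rejects_overlap(self, small_genome):
        with pytest.raises(ValueError, match="chromosome 1"):
            make_profile(small_genome, "s", [("1", 0, 100, 0.0), ("1", 50, 150, 0.0)])

    def test_profile_rejects_out_of_genome(self, small_genome):
        with pytest.raises(ValueError, match="exceeds"):
            make_profile(small_genome, "s", [("1", 0, 2000, 0.0)])

    def test_profile_rejects_empty(self, small_genome):
        with pytest.raises(ValueError, match="no segments"):
            SegmentedProfile("s", small_genome, ())

    def test_marker_weights_require_counts(self, small_genome):
        p = make_profile(small_genome, "s", [("1", 0, 100, 0.0)])
        with pytest.raises(ValueError, match="marker"):
            p.weights("markers")


class TestSegIO:
    def test_coordinate_convention(self, small_genome, tmp_path):
        # SEG rows (1,100) and (101,200) -> internal [0,100) and [100,200)
        f = tmp_path / "a.seg"
        f.write_text(
            "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
            "s1\t1\t1\t100\t10\t0.500000\n"
            "s1\t1\t101\t200\t10\t-0.250000\n"
        )
        profiles = read_seg(f, small_genome)
        assert set(profiles) == {"s1"}
        ivs = profiles["s1"].intervals
        assert (ivs[0].start, ivs[0].end) == (0, 100)
        assert (ivs[1].start, ivs[1].end) == (100, 200)

    def test_round_trip_byte_identity(self, small_genome, tmp_path):
        f = tmp_path / "a.seg"
        f.write_text(
            "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
            "s1\t1\t1\t100\t10\t0.500000\n"
            "s1\t2\t1\t800\t\t-0.250000\n"
        )
        profiles = read_seg(f, small_genome)
        g = tmp_path / "b.seg"
        write_seg(profiles, g)
        assert g.read_bytes() == f.read_bytes()

    def test_chr_prefix_stripped(self, small_genome, tmp_path):
        f = tmp_path / "a.seg"
        f.write_text(
            "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
            "s1\tchr1\t1\t100\t5\t0.000000\n"
        )
        profiles = read_seg(f, small_genome)
        assert profiles["s1"].intervals[0].chromosome == "1"

    def test_overlap_error_names_sample_and_chrom(self, small_genome, tmp_path):
        f = tmp_path / "a.seg"
        f.write_text(
            "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
            "sX\t1\t1\t100\t5\t0.000000\n"
            "sX\t1\t50\t150\t5\t0.000000\n"
        )
        with pytest.raises(SegFormatError, match=r"sX.*chromosome 1"):
            read_seg(f, small_genome)

    def test_malformed_row_names_line(self, small_genome, tmp_path):
        f = tmp_path / "a.seg"
        f.write_text(
            "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
            "s1\t1\t1\t100\t5\t0.000000\n"
            "s1\t1\tfoo\t200\t5\t0.000000\n"
        )
        with pytest.raises(SegFormatError, match=":3"):
            read_seg(f, small_genome)

    def test_wrong_column_count_names_line(self, small_genome, tmp_path):
        f = tmp_path / "a.seg"
        f.write_text(
            "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\ns1\t1\t1\t100\t5\n"
        )
        with pytest.raises(SegFormatError, match=":2"):
            read_seg(f, small_genome)

    def test_unknown_chromosome(self, small_genome, tmp_path):
        f = tmp_path / "a.seg"
        f.write_text(
            "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
            "s1\tchr9\t1\t100\t5\t0.000000\n"
        )
        with pytest.raises(SegFormatError, match="chr9"):
            read_seg(f, small_genome)

    def test_write_empty_collection(self, tmp_path):
        p = write_seg({}, tmp_path / "empty.seg")
        assert p.read_text() == "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"

    def test_write_single_segment(self, small_genome, tmp_path):
        p = make_profile(small_genome, "s", [("1", 0, 100, 0.25, 7)])
        path = write_seg([p], tmp_path / "one.seg")
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        assert lines[1] == "s\t1\t1\t100\t7\t0.250000"

    def test_infer_genome(self, tmp_path):
        f = tmp_path / "a.seg"
        f.write_text(
            "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
            "s1\tchr2\t1\t500\t5\t0.000000\n"
            "s1\t10\t1\t300\t5\t0.000000\n"
        )
        g = infer_genome_from_seg(f)
        assert g.names == ("2", "10")
        assert g.lengths == (500, 300)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_property(self, seed, tmp_path_factory):
        genome = GenomeModel(("1", "2", "3"), (500, 400, 300))
        rng = np.random.default_rng(seed)
        profiles = {
            sid: random_segmentation(rng, genome, sid) for sid in ("a", "b")
        }
        d = tmp_path_factory.mktemp("seg")
        p1 = write_seg(profiles, d / "x.seg")
        back = read_seg(p1, genome)
        p2 = write_seg(back, d / "y.seg")
        assert p1.read_bytes() == p2.read_bytes()
        for sid in profiles:
            assert back[sid] == profiles[sid]


class TestRestrictToAutosomes:
    def test_drops_sex_chromosomes(self):
        g = GenomeModel(("1", "X"), (1000, 1000))
        p = make_profile(g, "s", [("1", 0, 100, 0.0), ("X", 0, 100, 0.0)])
        out = restrict_to_autosomes(p)
        assert [iv.chromosome for iv in out.intervals] == ["1"]

    def test_identity_when_already_autosomal(self, small_genome):
        p = make_profile(small_genome, "s", [("1", 0, 100, 0.0)])
        assert restrict_to_autosomes(p) is p

    def test_error_when_empty(self):
        g = GenomeModel(("X",), (1000,))
        p = make_profile(g, "s", [("X", 0, 100, 0.0)])
        with pytest.raises(ValueError, match="no autosomal segments"):
            restrict_to_autosomes(p)


class TestHarmonize:
    def test_breakpoint_intersection(self, small_genome):
        a = make_profile(small_genome, "a", [("1", 0, 100, 0.1), ("1", 100, 200, 0.2)])
        b = make_profile(small_genome, "b", [("1", 0, 150, 0.3), ("1", 150, 200, 0.4)])
        h = harmonize_pair(a, b)
        assert [(iv.start, iv.end) for iv in h.intervals] == [(0, 100), (100, 150), (150, 200)]
        assert list(h.value_a) == [0.1, 0.2, 0.2]
        assert list(h.value_b) == [0.3, 0.3, 0.4]
        assert list(h.weights) == [100, 50, 50]

    def test_self_harmonization(self, small_genome):
        p = make_profile(
            small_genome, "p", [("1", 0, 100, 0.1), ("1", 100, 300, -0.2), ("2", 0, 800, 0.0)]
        )
        h = harmonize_pair(p, p)
        assert h.intervals == p.intervals
        assert np.array_equal(h.value_a, h.value_b)
        assert h.total_weight == sum(iv.length for iv in p.intervals)

    def test_disjoint_coverage_errors(self, small_genome):
        a = make_profile(small_genome, "a", [("1", 0, 100, 0.0)])
        b = make_profile(small_genome, "b", [("2", 0, 100, 0.0)])
        with pytest.raises(ValueError, match="no genomic coverage"):
            harmonize_pair(a, b)

    def test_different_genomes_rejected(self, small_genome):
        other = GenomeModel(("1",), (1000,))
        a = make_profile(small_genome, "a", [("1", 0, 100, 0.0)])
        b = make_profile(other, "b", [("1", 0, 100, 0.0)])
        with pytest.raises(ValueError, match="genome"):
            harmonize_pair(a, b)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_conservation_symmetry_and_values(self, seed):
        genome = GenomeModel(("1", "2"), (200, 150))
        rng = np.random.default_rng(seed)
        a = random_segmentation(rng, genome, "a", coverage=0.8)
        b = random_segmentation(rng, genome, "b", coverage=0.8)

        # per-bp brute-force oracle on this tiny genome
        def per_bp(profile):
            cover = {c: np.full(l, np.nan) for c, l in zip(genome.names, genome.lengths)}
            for seg in profile.segments:
                iv = seg.interval
                cover[iv.chromosome][iv.start:iv.end] = seg.log_ratio
            return cover

        ca, cb = per_bp(a), per_bp(b)
        mutual = sum(
            int((~np.isnan(ca[c]) & ~np.isnan(cb[c])).sum()) for c in genome.names
        )
        try:
            h = harmonize_pair(a, b)
        except ValueError:
            assert mutual == 0
            return
        assert h.total_weight == mutual
        for iv, va, vb in zip(h.intervals, h.value_a, h.value_b):
            assert np.all(ca[iv.chromosome][iv.start:iv.end] == va)
            assert np.all(cb[iv.chromosome][iv.start:iv.end] == vb)
        # symmetry up to swapping the value columns
        h2 = harmonize_pair(b, a)
        assert h2.intervals == h.intervals
        assert np.array_equal(h2.value_a, h.value_b)
        assert np.array_equal(h2.value_b, h.value_a)


class TestWeightedMeanStd:
    def test_hand_example(self):
        mean, std = weighted_mean_std([2, 3, 2, 2], [1, 1, 1, 1])
        assert mean == pytest.approx(2.25)
        assert std == pytest.approx(0.4330127018922193)

    def test_constant_values(self):
        _, std = weighted_mean_std([5.0, 5.0, 5.0], [1, 2, 3])
        assert std == 0.0

    def test_single_value(self):
        assert weighted_mean_std([3.5], [2.0]) == (3.5, 0.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            weighted_mean_std([], [])

    def test_nonpositive_weight_errors(self):
        with pytest.raises(ValueError, match="positive"):
            weighted_mean_std([1.0], [0.0])

    @settings(deadline=None, max_examples=50)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-10, 10, allow_nan=False),
                st.floats(0.1, 5, allow_nan=False),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_matches_numpy_average(self, data):
        v = np.array([x for x, _ in data])
        w = np.array([y for _, y in data])
        mean, std = weighted_mean_std(v, w)
        assert mean == pytest.approx(float(np.average(v, weights=w)), abs=1e-12)
        expected_var = float(np.average((v - np.average(v, weights=w)) ** 2, weights=w))
        assert std == pytest.approx(math.sqrt(expected_var), abs=1e-12)
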