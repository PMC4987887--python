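"""Domain types, format detection, readers/writers and binning."""

import json
import math

import numpy as np
import pytest

from trackmatch import (
    GenomeLayout,
    Region,
    ScoredRegion,
    SearchConfig,
    SignalTrack,
    bin_track,
    detect_format,
    read_chrom_sizes,
    read_signal,
    write_bedgraph,
    write_results,
)
from trackmatch.io import EmptyTrackError, FormatError, write_chrom_sizes


class TestGenomeLayout:
    def test_total_size_and_lookup(self, tiny_layout):
        assert tiny_layout.total_size == 150_000
        assert tiny_layout.length("chr2") == 50_000
        assert "chr3" not in tiny_layout

    @pytest.mark.parametrize(
        "entries",
        [
            [("chr1", 100), ("chr1", 200)],  # duplicate name
            [("chr1", 0)],  # non-positive length
            [("chr1", -5)],
        ],
    )
    def test_invalid_layouts_rejected(self, entries):
        with pytest.raises(ValueError):
            GenomeLayout(entries)

    def test_chrom_sizes_round_trip(self, tiny_layout, tmp_path):
        p = tmp_path / "genome.chrom.sizes"
        write_chrom_sizes(tiny_layout, str(p))
        assert read_chrom_sizes(str(p)) == tiny_layout


class TestRegion:
    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            Region("chr1", 500, 500)
        with pytest.raises(ValueError):
            Region("chr1", -1, 10)

    def test_overlap_semantics(self):
        a = Region("chr1", 100, 200)
        assert a.overlaps(Region("chr1", 199, 300))
        assert not a.overlaps(Region("chr1", 200, 300))  # adjacent, half-open
        assert not a.overlaps(Region("chr2", 100, 200))


class TestSignalTrack:
    def test_invariants_enforced(self, tiny_layout):
        with pytest.raises(ValueError):
            SignalTrack(
                tiny_layout,
                {"chr1": (np.array([0, 5]), np.array([10, 15]), np.array([1.0, 2.0]))},
            )  # overlapping
        with pytest.raises(ValueError):
            SignalTrack(
                tiny_layout,
                {"chr1": (np.array([0]), np.array([200_000]), np.array([1.0]))},
            )  # beyond chromosome end

    def test_values_per_base_implicit_zero(self, track_builder):
        t = track_builder({"chr1": [(10, 20, 2.5)]})
        v = t.values_per_base("chr1", 5, 25)
        assert v[:5].sum() == 0 and v[-5:].sum() == 0
        assert np.all(v[5:15] == 2.5)


class TestReadSignal:
    def test_bed_overlap_union(self, tmp_path, tiny_layout):
        p = tmp_path / "peaks.bed"
        p.write_text("chr1\t100\t200\nchr1\t150\t300\n")
        t = read_signal(str(p), "BED", tiny_layout)
        starts, ends, values = t.intervals("chr1")
        assert list(starts) == [100] and list(ends) == [300]
        assert list(values) == [1.0]

    def test_bedgraph_direct_transcription(self, tmp_path, tiny_layout):
        p = tmp_path / "sig.bedGraph"
        p.write_text("chr1\t0\t10\t2.5\n")
        t = read_signal(str(p), "bedGraph", tiny_layout)
        starts, ends, values = t.intervals("chr1")
        assert (list(starts), list(ends), list(values)) == ([0], [10], [2.5])

    def test_empty_bed_is_valid_and_unseedable(self, tmp_path, tiny_layout):
        from trackmatch import SearchConfig, find_seeds

        p = tmp_path / "empty.bed"
        p.write_text("")
        t = read_signal(str(p), "BED", tiny_layout)
        assert t.is_empty()
        other = read_signal(str(p), "BED", tiny_layout)
        assert find_seeds(t, other, "chr1", SearchConfig()) == []

    def test_wig_one_based_conversion(self, tmp_path, tiny_layout):
        p = tmp_path / "sig.wig"
        p.write_text(
            "fixedStep chrom=chr1 start=1 step=10 span=10\n3.0\n4.0\n"
            "variableStep chrom=chr2 span=5\n11\t7.5\n"
        )
        t = read_signal(str(p), "WIG", tiny_layout)
        s1, e1, v1 = t.intervals("chr1")
        assert list(s1) == [0, 10] and list(e1) == [10, 20] and list(v1) == [3.0, 4.0]
        s2, e2, v2 = t.intervals("chr2")
        assert (list(s2), list(e2), list(v2)) == ([10], [15], [7.5])

    def test_bigwig_round_trip(self, tmp_path, tiny_layout):
        pyBigWig = pytest.importorskip("pyBigWig")
        p = tmp_path / "sig.bw"
        bw = pyBigWig.open(str(p), "w")
        bw.addHeader([("chr1", 100_000)])
        bw.addEntries(["chr1", "chr1"], [100, 300], ends=[200, 350], values=[1.5, 2.0])
        bw.close()
        assert detect_format(str(p)) == "bigWig"
        t = read_signal(str(p), "auto", tiny_layout)
        starts, ends, values = t.intervals("chr1")
        assert list(starts) == [100, 300] and list(values) == [1.5, 2.0]

    def test_unknown_chromosomes_skipped_not_fatal(self, tmp_path, tiny_layout):
        p = tmp_path / "mixed.bedGraph"
        p.write_text("chr1\t0\t10\t1.0\nchrUn_patch\t0\t10\t1.0\n")
        t = read_signal(str(p), "bedGraph", tiny_layout)
        assert t.chroms == ["chr1"]

    def test_all_unknown_chromosomes_is_error(self, tmp_path, tiny_layout):
        p = tmp_path / "alien.bedGraph"
        p.write_text("scaffold_1\t0\t10\t1.0\n")
        with pytest.raises(EmptyTrackError):
            read_signal(str(p), "bedGraph", tiny_layout)

    def test_corrupt_record_names_line(self, tmp_path, tiny_layout):
        p = tmp_path / "bad.bedGraph"
        p.write_text("chr1\t0\t10\t1.0\nchr1\t20\tnot_a_number\t2\n")
        with pytest.raises(FormatError, match=":2"):
            read_signal(str(p), "bedGraph", tiny_layout)


class TestDetectFormat:
    def test_bigwig_magic_bytes(self, tmp_path):
        p = tmp_path / "magic.bin"
        p.write_bytes((0x888FFC26).to_bytes(4, "little") + b"\x00" * 64)
        assert detect_format(str(p)) == "bigWig"

    def test_three_integer_columns_is_bed(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("chr1\t100\t200\nchr1\t300\t400\n")
        assert detect_format(str(p)) == "BED"

    def test_fourth_numeric_column_is_bedgraph(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("chr1\t100\t200\t0.35\n")
        assert detect_format(str(p)) == "bedGraph"

    def test_named_fourth_column_is_bed(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("chr1\t100\t200\tpeak_1\nchr1\t300\t400\tpeak_2\n")
        assert detect_format(str(p)) == "BED"

    def test_fixedstep_keyword_is_wig(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("fixedStep chrom=chr1 start=1 step=1\n1.0\n")
        assert detect_format(str(p)) == "WIG"

    def test_unclassifiable_lists_accepted_formats(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("hello world\n")
        with pytest.raises(FormatError, match="bigWig"):
            detect_format(str(p))


class TestBinTrack:
    @pytest.mark.parametrize(
        "intervals,bin_size,expected",
        [
            ([(0, 10, 4.0)], 5, [4.0, 4.0]),  # constant signal
            ([(0, 5, 2.0)], 10, [1.0]),  # coverage-weighted mean
            ([], 10, []),  # all-zero stays zero
        ],
    )
    def test_bin_values(self, track_builder, intervals, bin_size, expected):
        layout = GenomeLayout([("chr1", 10)])
        t = SignalTrack.from_interval_lists(layout, {"chr1": intervals})
        got = t.dense_bins("chr1", bin_size)
        nonzero = {i: v for i, v in enumerate(got) if v != 0}
        want = {i: v for i, v in enumerate(expected) if v != 0}
        assert nonzero == want

    def test_mass_conservation(self, track_builder):
        rng = np.random.default_rng(7)
        ivs, pos = [], 0
        for _ in range(50):
            pos += int(rng.integers(0, 50))
            w = int(rng.integers(10, 200))
            ivs.append((pos, pos + w, float(rng.uniform(0.5, 5))))
            pos += w
        t = track_builder({"chr1": ivs})
        binned = bin_track(t, 10)
        assert binned.total_mass() == pytest.approx(t.total_mass(), rel=1e-12)

    def test_binarized_bed_is_idempotent(self, track_builder):
        t = track_builder({"chr1": [(100, 200, 1.0), (500, 800, 1.0)]})
        once = bin_track(t, 10)
        twice = bin_track(once, 10)
        for chrom in once.chroms:
            s1, e1, v1 = once.intervals(chrom)
            s2, e2, v2 = twice.intervals(chrom)
            assert np.array_equal(s1, s2) and np.array_equal(e1, e2)
            assert np.allclose(v1, v2)

    def test_bedgraph_round_trip(self, track_builder, tiny_layout, tmp_path):
        t = track_builder({"chr1": [(0, 10, 2.5), (30, 45, 1.25)], "chr2": [(7, 9, 3.0)]})
        p = tmp_path / "rt.bedGraph"
        write_bedgraph(t, str(p))
        back = read_signal(str(p), "bedGraph", tiny_layout)
        for chrom in t.chroms:
            s1, e1, v1 = t.intervals(chrom)
            s2, e2, v2 = back.intervals(chrom)
            assert np.array_equal(s1, s2) and np.array_equal(e1, e2)
            assert np.allclose(v1, v2, rtol=1e-9)


class TestWriteResults:
    def test_bed6_line_and_manifest(self, tmp_path):
        r = ScoredRegion(Region("chr1", 100, 2100), 0.95, 0.75, "T1")
        out = tmp_path / "results.bed"
        write_results([r], str(out), SearchConfig())
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        fields = lines[0].split("\t")
        assert fields[:6] == ["chr1", "100", "2100", "T1", "750", "."]
        manifest = json.loads((tmp_path / "results.bed.json").read_text())
        assert manifest["results"][0]["correlation"] == pytest.approx(0.95)
        assert manifest["config"]["alpha"] == 0.01

    def test_score_clamped_but_manifest_exact(self, tmp_path):
        r = ScoredRegion(Region("chr1", 0, 100), 1.0, 1.4, "T")
        out = tmp_path / "r.bed"
        write_results([r], str(out))
        line = [l for l in out.read_text().splitlines() if not l.startswith("#")][0]
        assert line.split("\t")[4] == "1000"
        manifest = json.loads((tmp_path / "r.bed.json").read_text())
        assert manifest["results"][0]["score"] == pytest.approx(1.4)

    def test_empty_results(self, tmp_path):
        out = tmp_path / "empty.bed"
        write_results([], str(out))
        assert [l for l in out.read_text().splitlines() if not l.startswith("#")] == []
        assert json.loads((tmp_path / "empty.bed.json").read_text())["n_results"] == 0


class TestSearchConfig:
    def test_defaults_valid(self):
        SearchConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": -0.1},
            {"delta": 0},
            {"seed_window": 10, "bin_size": 10},
            {"result_cap": 0},
            {"threads": 0},
            {"threads": 25},
            {"subsets": 101},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SearchConfig(**kwargs)
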