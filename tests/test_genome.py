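"""Genome partition, occupancy baselines, and repeat catalog loading."""

import numpy as np
import pytest

from peakrep.genome import (
    DEFAULT_PRIORITY,
    GenomeClassPartition,
    ParseError,
    build_partition,
    class_occupancy_report,
    load_chrom_sizes,
    load_class_intervals,
    load_repeatmasker,
    normalize_repeat_category,
)
from peakrep.intervals import (
    GenomicInterval,
    intersect_pairs,
    merge_pairs,
    subtract_pairs,
    total_bp,
)

from conftest import paint_genome


class TestIntervalArithmetic:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([], []),
            ([(0, 10)], [(0, 10)]),
            ([(0, 10), (5, 20)], [(0, 20)]),
            ([(0, 10), (10, 20)], [(0, 20)]),  # book-ended
            ([(5, 8), (0, 3)], [(0, 3), (5, 8)]),
        ],
    )
    def test_merge(self, pairs, expected):
        assert merge_pairs(pairs) == expected

    def test_set_ops_match_per_base_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = merge_pairs([(int(s), int(s + w)) for s, w in
                             zip(rng.integers(0, 900, 8), rng.integers(1, 120, 8))])
            b = merge_pairs([(int(s), int(s + w)) for s, w in
                             zip(rng.integers(0, 900, 8), rng.integers(1, 120, 8))])
            mask_a = np.zeros(1100, bool)
            mask_b = np.zeros(1100, bool)
            for s, e in a:
                mask_a[s:e] = True
            for s, e in b:
                mask_b[s:e] = True

            def covered(pairs):
                m = np.zeros(1100, bool)
                for s, e in pairs:
                    m[s:e] = True
                return m

            assert (covered(intersect_pairs(a, b)) == (mask_a & mask_b)).all()
            assert (covered(subtract_pairs(a, b)) == (mask_a & ~mask_b)).all()

    def test_merge_idempotent_property(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(derandomize=True, max_examples=60)
        @given(
            st.lists(
                st.tuples(st.integers(0, 500), st.integers(1, 80)).map(
                    lambda t: (t[0], t[0] + t[1])
                ),
                max_size=15,
            )
        )
        def check(pairs):
            merged = merge_pairs(pairs)
            assert merge_pairs(merged) == merged
            assert total_bp(merged) <= sum(e - s for s, e in pairs)
            assert all(a[1] < b[0] for a, b in zip(merged, merged[1:]))

        check()

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)


class TestBedLoading:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert load_class_intervals(p) == []

    def test_basic_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        assert load_class_intervals(p) == [GenomicInterval("chr1", 100, 200)]

    def test_overlapping_lines_unmerged_at_load(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\t150\t300\n")
        ivs = load_class_intervals(p)
        assert len(ivs) == 2  # merging is build_partition's job

    def test_comments_and_track_lines_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("# header\ntrack name=x\nchr1\t0\t5\n")
        assert len(load_class_intervals(p)) == 1

    @pytest.mark.parametrize("bad", ["chr1\tx\t200", "chr1\t200\t100", "chr1\t5"])
    def test_malformed_lines_name_line_number(self, tmp_path, bad):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\n" + bad + "\n")
        with pytest.raises(ParseError, match=":2"):
            load_class_intervals(p)

    def test_chrom_sizes(self, tmp_path):
        p = tmp_path / "sizes.txt"
        p.write_text("chr1\t1000\nchr2\t500\n")
        assert load_chrom_sizes(p) == {"chr1": 1000, "chr2": 500}


# 10-row rmsk fixture exercising category normalization (tab-separated,
# UCSC table-dump column layout with leading bin column).
RMSK_ROWS = [
    ("chr1", 100, 250, "L1Md", "LINE"),
    ("chr1", 400, 700, "Lx9", "LINE"),
    ("chr1", 900, 1000, "B1", "SINE"),
    ("chr2", 50, 150, "RLTR", "LTR"),
    ("chr2", 200, 260, "(TTTG)n", "Simple_repeat"),
    ("chr2", 300, 380, "polypurine", "Low_complexity"),
    ("chr2", 500, 650, "MER2", "DNA"),
    ("chr2", 700, 790, "GSAT", "Satellite"),
    ("chr1", 1200, 1300, "Mys1", "Unknown"),
    ("chr1", 1400, 1500, "L1?", "LINE?"),
]


def write_rmsk(path):
    with open(path, "w") as fh:
        fh.write("#bin\tswScore\tmilliDiv\tmilliDel\tmilliIns\tgenoName\tgenoStart\tgenoEnd"
                 "\tgenoLeft\tstrand\trepName\trepClass\trepFamily\trepStart\trepEnd\trepLeft\tid\n")
        for chrom, s, e, name, cls in RMSK_ROWS:
            fh.write(f"0\t1000\t10\t1\t1\t{chrom}\t{s}\t{e}\t-1000\t+\t{name}\t{cls}\t{cls}\t1\t100\t0\t1\n")


class TestRepeatCatalog:
    def test_rmsk_fixture_counts_and_normalization(self, tmp_path):
        p = tmp_path / "rmsk.txt"
        write_rmsk(p)
        cat = load_repeatmasker(p)
        assert cat.total_repeats == 10
        assert cat.category_counts["LINE"] == 3  # incl. the 'LINE?' row
        assert cat.category_counts["low_complexity"] == 1
        assert cat.category_counts["simple_repeat"] == 1
        assert cat.category_counts["other"] == 1  # Unknown
        assert sum(cat.category_counts.values()) == cat.total_repeats

    def test_bed_dialect(self, tmp_path):
        p = tmp_path / "rep.bed"
        p.write_text("chr1\t0\t100\tLINE\nchr1\t200\t300\tLINE\nchr1\t400\t500\tSINE\n")
        cat = load_repeatmasker(p)
        assert cat.total_repeats == 3
        assert cat.category_counts == {"LINE": 2, "SINE": 1}

    def test_counts_invariant_under_row_permutation(self, tmp_path):
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        rows = ["chr1\t0\t10\tLINE", "chr1\t20\t30\tSINE", "chr2\t0\t9\tLTR"]
        p1.write_text("\n".join(rows) + "\n")
        p2.write_text("\n".join(reversed(rows)) + "\n")
        c1, c2 = load_repeatmasker(p1), load_repeatmasker(p2)
        assert c1.category_counts == c2.category_counts
        assert c1.total_repeats == c2.total_repeats

    def test_unknown_dialect_error_lists_accepted(self, tmp_path):
        p = tmp_path / "junk.txt"
        p.write_text("just\tsome\ttext\n")
        with pytest.raises(ValueError, match="rmsk.*bed|bed.*rmsk"):
            load_repeatmasker(p)

    @pytest.mark.parametrize(
        "raw,expected",
        [("LINE", "LINE"), ("Low_complexity", "low_complexity"), ("Unknown", "other"),
         ("SINE?", "SINE"), ("RC", "other")],
    )
    def test_category_normalization(self, raw, expected):
        assert normalize_repeat_category(raw) == expected


class TestBuildPartition:
    def test_single_class_complement(self):
        part = build_partition(
            {"exon": [GenomicInterval("chr1", 0, 300)]},
            priority=("exon",),
            genome_sizes={"chr1": 1000},
        )
        assert part.occupancy_bp == {"exon": 300, "intergenic": 700}
        assert part.fractions["exon"] == pytest.approx(0.3)

    def test_priority_resolution_toy(self, toy_partition):
        assert toy_partition.occupancy_bp == {"exon": 200, "intron": 200, "intergenic": 600}

    def test_matches_per_base_oracle_on_random_configs(self):
        rng = np.random.default_rng(7)
        sizes = {"chr1": 2000, "chr2": 1500}
        priority = DEFAULT_PRIORITY[:4]
        for _ in range(10):
            class_sets = {}
            for cls_label in priority:
                ivs = []
                for _ in range(rng.integers(1, 6)):
                    chrom = rng.choice(list(sizes))
                    s = int(rng.integers(0, sizes[chrom] - 50))
                    ivs.append(GenomicInterval(chrom, s, s + int(rng.integers(1, 300).clip(1, sizes[chrom] - s))))
                class_sets[cls_label] = ivs
            part = build_partition(class_sets, priority, sizes)
            painted = paint_genome(class_sets, priority, sizes)
            # occupancy agreement
            for cls_label in list(priority) + ["intergenic"]:
                oracle_bp = sum(int((painted[c] == cls_label).sum()) for c in sizes)
                assert part.occupancy_bp.get(cls_label, 0) == oracle_bp
            # sampled positions: exactly one class claims each
            for _ in range(200):
                chrom = rng.choice(list(sizes))
                pos = int(rng.integers(0, sizes[chrom]))
                assert part.class_at(chrom, pos) == painted[chrom][pos]

    def test_occupancy_conservation_exact(self, toy_partition):
        assert sum(toy_partition.occupancy_bp.values()) == toy_partition.total_bp == 1000

    def test_merge_idempotence(self, toy_partition):
        rebuilt_sets = {
            cls_label: [
                GenomicInterval(chrom, s, e)
                for chrom, pairs in per_chrom.items()
                for s, e in pairs
            ]
            for cls_label, per_chrom in toy_partition.class_intervals.items()
            if cls_label != "intergenic"
        }
        again = build_partition(rebuilt_sets, toy_partition.priority, toy_partition.genome_sizes)
        assert again.occupancy_bp == toy_partition.occupancy_bp

    def test_interval_exceeding_chromosome_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_partition(
                {"exon": [GenomicInterval("chr1", 0, 2000)]},
                ("exon",),
                {"chr1": 1000},
            )

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="absent"):
            build_partition(
                {"exon": [GenomicInterval("chrX", 0, 10)]},
                ("exon",),
                {"chr1": 1000},
            )

    def test_class_missing_from_priority_errors(self):
        with pytest.raises(ValueError, match="priority"):
            build_partition(
                {"exon": [GenomicInterval("chr1", 0, 10)]},
                ("intron",),
                {"chr1": 1000},
            )


class TestOccupancyReport:
    def test_single_class_fraction_one(self):
        part = GenomeClassPartition.from_occupancy({"intergenic": 500})
        df = class_occupancy_report(part)
        assert df["fraction"].tolist() == [1.0]

    def test_toy_rows(self, toy_partition):
        df = class_occupancy_report(toy_partition).set_index("class")
        assert df.loc["exon", "fraction"] == pytest.approx(0.2)
        assert df.loc["intron", "fraction"] == pytest.approx(0.2)
        assert df.loc["intergenic", "fraction"] == pytest.approx(0.6)
        assert df["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_published_intergenic_baseline_two_decimals(self):
        part = GenomeClassPartition.from_occupancy(
            {"intergenic": 813_929_088}, total_bp=2_631_564_759
        )
        df = class_occupancy_report(part).set_index("class")
        assert f"{df.loc['intergenic', 'percent']:.2f}" == "30.93"
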