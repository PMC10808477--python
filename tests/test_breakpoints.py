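"""Coordinate parsing, junction homology, mechanism classification,
repeat annotation and primer SNP screening."""

import numpy as np
import pytest

from masscnv import (
    BreakpointError,
    GenomicVariant,
    MechanismThresholds,
    annotate_repeats,
    characterize,
    classify_mechanism,
    event_size,
    junction_homology,
    parse_hgvs_g,
    read_bed,
    read_variant_frequencies,
    screen_primers,
)
from masscnv.breakpoints import BedInterval


def brute_force_homology(ref: str, start: int, end: int) -> int:
    """Independent oracle: number of shifted deletion placements producing
    the identical mutant sequence, minus one."""
    mutant = ref[: start - 1] + ref[end:]
    size = end - start + 1
    count = 0
    for s in range(1, len(ref) - size + 2):
        if ref[: s - 1] + ref[s + size - 1:] == mutant:
            count += 1
    return count - 1


class TestParseHgvsG:
    @pytest.mark.parametrize(
        "text,start,end,kind",
        [
            ("g.61,101_98,034del", 61101, 98034, "del"),
            ("g.73,379_93,235del", 73379, 93235, "del"),
            ("g.5_5del", 5, 5, "del"),
            ("g.100_200dup", 100, 200, "dup"),
            ("NG_005905.2:g.61,101_98,034del", 61101, 98034, "del"),
        ],
    )
    def test_valid_strings(self, text, start, end, kind):
        v = parse_hgvs_g(text)
        assert (v.start, v.end, v.kind) == (start, end, kind)

    def test_refseq_prefix_captured(self):
        assert parse_hgvs_g("NG_012772.3:g.48,409_56,300del").sequence_name == "NG_012772.3"

    @pytest.mark.parametrize("text", ["g.10_5del", "g.5del", "g.5_10ins", "chr17:5-10", ""])
    def test_malformed_strings_rejected(self, text):
        with pytest.raises(BreakpointError):
            parse_hgvs_g(text)


class TestEventSize:
    @pytest.mark.parametrize(
        "text,size",
        [
            ("g.61,101_98,034del", 36934),
            ("g.73,379_93,235del", 19857),
            ("g.61,422_98,355del", 36934),
            ("g.110,371_122,487del", 12117),
            ("g.48,409_56,300del", 7892),
        ],
    )
    def test_published_breakpoint_sizes(self, text, size):
        assert event_size(parse_hgvs_g(text)) == size

    def test_single_base(self):
        assert event_size(parse_hgvs_g("g.5_5del")) == 1


class TestJunctionHomology:
    def test_no_repeated_context(self):
        ref = "ACGTACCCGGGTTTAAGCTG"
        # pick a junction with no identity: verify against the oracle
        v = GenomicVariant("", 5, 12, "del")
        h, _ = junction_homology(v, ref)
        assert h == brute_force_homology(ref, 5, 12)

    def test_constructed_five_bp_homology(self):
        core = "TTTTT"
        ref = "ACGCA" + core + "GGATC" * 3 + core + "CATGC"
        v = GenomicVariant("", 6, 25, "del")  # ref[26..30] repeats the core
        h, (lo, hi) = junction_homology(v, ref)
        assert h == 5 == brute_force_homology(ref, 6, 25)
        assert (lo, hi) == (6, 11)

    def test_embedded_long_repeats(self):
        rng = np.random.default_rng(3)
        bases = "ACGT"
        repeat = "".join(rng.choice(list(bases), 40))
        spacer = "".join(rng.choice(list(bases), 60))
        flank_l = "".join(rng.choice(list(bases), 25))
        flank_r = "".join(rng.choice(list(bases), 25))
        ref = flank_l + repeat + spacer + repeat + flank_r
        # breakpoints inside the two repeat copies, 10 bp in
        start = len(flank_l) + 10 + 1
        end = len(flank_l) + 40 + 60 + 10
        v = GenomicVariant("", start, end, "del")
        h, _ = junction_homology(v, ref)
        assert h >= 30
        assert h == brute_force_homology(ref, start, end)

    def test_agrees_with_brute_force_on_random_deletions(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(20, 120))
            ref = "".join(rng.choice(list("ACGT"), n))
            start = int(rng.integers(1, n))
            end = int(rng.integers(start, n + 1))
            h, _ = junction_homology(GenomicVariant("", start, end, "del"), ref)
            assert h == brute_force_homology(ref, start, end)

    def test_reference_too_short_errors(self):
        with pytest.raises(BreakpointError, match="span"):
            junction_homology(GenomicVariant("", 5, 50, "del"), "ACGT" * 5)


class TestClassifyMechanism:
    @pytest.mark.parametrize(
        "homology,left,right,expected",
        [
            (0, None, "AluSx", "NHEJ"),
            (45, "AluSx", "AluSz", "NAHR"),
            (10, None, None, "MMEJ"),
            (0, None, None, "NHEJ"),
            (3, None, None, "NHEJ"),
            (4, None, None, "MMEJ"),
            (29, None, None, "MMEJ"),
            (30, None, None, "NAHR"),
            (5, "AluSx", "AluSz", "NAHR"),      # same-family repeats + microhomology
            (0, "AluSx", "AluSz", "ambiguous"),  # repeat evidence vs no junction identity
            (0, "PsiBRCA1", "L1MB7", "NHEJ"),
        ],
    )
    def test_default_thresholds(self, homology, left, right, expected):
        assert classify_mechanism(homology, left, right) == expected

    def test_monotone_in_homology(self):
        order = {"NHEJ": 0, "ambiguous": 0, "MMEJ": 1, "NAHR": 2}
        for repeats in [(None, None), ("AluSx", "AluSz"), (None, "AluSx"), ("L1", "MIR")]:
            ranks = [order[classify_mechanism(h, *repeats)] for h in range(0, 60)]
            assert ranks == sorted(ranks)

    def test_custom_thresholds(self):
        t = MechanismThresholds(nahr_min=20, nhej_max=1)
        assert classify_mechanism(2, thresholds=t) == "MMEJ"
        assert classify_mechanism(20, thresholds=t) == "NAHR"


class TestAnnotateRepeats:
    def test_containment(self):
        repeats = [BedInterval("", 90, 120, "AluSx", line=1)]
        left, right = annotate_repeats(GenomicVariant("", 100, 115, "del"), repeats)
        assert left == "AluSx" and right == "AluSx"

    def test_no_overlap(self):
        repeats = [BedInterval("", 0, 50, "MIR", line=1)]
        assert annotate_repeats(GenomicVariant("", 100, 200, "del"), repeats) == (None, None)

    def test_larger_overlap_wins(self):
        v = GenomicVariant("", 100, 200, "del")
        repeats = [
            BedInterval("", 95, 105, "SmallRep", line=1),
            BedInterval("", 90, 180, "BigRep", line=2),
        ]
        left, _ = annotate_repeats(v, repeats)
        assert left == "BigRep"

    def test_bed_parsing_and_errors(self, tmp_path):
        good = tmp_path / "r.bed"
        good.write_text("chr1\t90\t120\tAluSx\nchr1\t200\t260\tAluJb\n")
        intervals = read_bed(good)
        assert [iv.name for iv in intervals] == ["AluSx", "AluJb"]
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t90\t120\tAluSx\nchr1\tX\t120\tAluJb\n")
        with pytest.raises(BreakpointError, match="line 2"):
            read_bed(bad)

    def test_characterize_full_report(self):
        rng = np.random.default_rng(8)
        repeat = "".join(rng.choice(list("ACGT"), 40))
        ref = "A" * 20 + repeat + "C" * 50 + repeat + "G" * 20
        start, end = 21 + 5, 20 + 40 + 50 + 5
        repeats = [
            BedInterval("", 20, 60, "AluSx", line=1),
            BedInterval("", 110, 150, "AluSz", line=2),
        ]
        report = characterize(GenomicVariant("", start, end, "del"), ref, repeats)
        assert report.size_bp == end - start + 1
        assert report.homology_len >= 30
        assert report.mechanism == "NAHR"
        assert (report.repeat_left, report.repeat_right) == ("AluSx", "AluSz")


class TestScreenPrimers:
    def make_primer(self, start1, end1, name="P1"):
        # primer interval given 1-based inclusive -> BED half-open
        return BedInterval("chr17", start1 - 1, end1, name, line=1)

    def test_common_variant_flags_primer(self):
        import pandas as pd

        variants = pd.DataFrame({"chrom": ["chr17"], "pos": [110], "af": [0.01]})
        result = screen_primers([self.make_primer(100, 120)], variants)
        assert result.flagged_names() == ["P1"]

    def test_rare_variant_not_flagged(self):
        import pandas as pd

        variants = pd.DataFrame({"chrom": ["chr17"], "pos": [110], "af": [0.001]})
        assert screen_primers([self.make_primer(100, 120)], variants).flagged == ()

    def test_maf_folding_of_high_af(self):
        import pandas as pd

        # AF 0.999 -> MAF 0.001 -> below threshold
        variants = pd.DataFrame({"chrom": ["chr17"], "pos": [110], "af": [0.999]})
        assert screen_primers([self.make_primer(100, 120)], variants).flagged == ()
        # AF 0.99 -> MAF 0.01 -> flagged
        variants = pd.DataFrame({"chrom": ["chr17"], "pos": [110], "af": [0.99]})
        assert screen_primers([self.make_primer(100, 120)], variants).flagged_names() == ["P1"]

    def test_variant_outside_interval_ignored(self):
        import pandas as pd

        variants = pd.DataFrame({"chrom": ["chr17"], "pos": [121], "af": [0.5]})
        assert screen_primers([self.make_primer(100, 120)], variants).flagged == ()

    def test_missing_frequency_skipped_with_warning(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("chrom\tpos\taf\nchr17\t110\t0.01\nchr17\t111\t\n")
        variants = read_variant_frequencies(path)
        assert variants.attrs["n_skipped"] == 1
        with pytest.warns(UserWarning, match="without allele frequency"):
            result = screen_primers([self.make_primer(100, 120)], variants)
        assert result.n_skipped_no_frequency == 1
        assert result.flagged_names() == ["P1"]

    def test_vcf_input(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n'
            "##contig=<ID=chr17>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr17\t110\t.\tA\tG\t.\t.\tAF=0.02\n"
            "chr17\t500\t.\tC\tT\t.\t.\tAF=0.3\n"
        )
        variants = read_variant_frequencies(vcf)
        assert len(variants) == 2
        result = screen_primers([self.make_primer(100, 120)], variants)
        assert result.flagged_names() == ["P1"]
        assert result.flagged[0].positions == (110,)
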