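import gzip

import pytest

import rsnpscan as rs

V1 = rs.Variant("rs1", 100, "A", "G")
V2 = rs.Variant("rs2", 300, "C", "T")


def hit(score, model="M1", factor="AR", strand="+", start=95, tag="wt", width=12):
    return rs.Hit(model, factor, strand, start, start + width - 1, score,
                  "ACGTACGTACGT"[:width], tag)


def pair(change, variant=V1, model="M1", factor="AR", start=95,
         wt_score=None, mut_score=None, significant=None):
    wt = hit(wt_score, model, factor, start=start) if wt_score is not None else None
    mut = hit(mut_score, model, factor, start=start, tag="mut") \
        if mut_score is not None else None
    if wt is None and mut is None:
        mut = hit(change, model, factor, start=start, tag="mut")
    direction = "gain" if wt is None else "loss"
    return rs.HitPair(variant, wt, mut, change, direction,
                      significant if significant is not None else change >= 2)


class TestFilterPairs:
    def test_either_hit_score_rule(self):
        p = pair(1.0, wt_score=1.0)  # mut absent
        spec = rs.FilterSpec(min_hit_score=0.5)
        assert rs.filter_pairs([p], spec) == [p]
        assert rs.filter_pairs([p], rs.FilterSpec(min_hit_score=1.5)) == []

    def test_score_change_threshold(self):
        p = pair(1.6, wt_score=4.6, mut_score=3.0)
        assert rs.filter_pairs([p], rs.FilterSpec(min_score_change=2)) == []
        assert rs.filter_pairs([p], rs.FilterSpec(min_score_change=1.5)) == [p]

    def test_factor_filter_case_insensitive_substring(self):
        p = pair(3.0, factor="Sp-1")
        assert rs.filter_pairs([p], rs.FilterSpec(factor_pattern="sp")) == [p]
        assert rs.filter_pairs([p], rs.FilterSpec(factor_pattern="nrf")) == []

    def test_filters_compose_conjunctively(self):
        p = pair(3.0, factor="Sp-1", wt_score=3.0)
        spec = rs.FilterSpec(min_hit_score=2.0, min_score_change=2.0,
                             factor_pattern="sp")
        assert rs.filter_pairs([p], spec) == [p]
        spec2 = rs.FilterSpec(min_hit_score=5.0, min_score_change=2.0,
                              factor_pattern="sp")
        assert rs.filter_pairs([p], spec2) == []

    def test_percentile_filter_requires_calibration(self):
        p = pair(3.0)
        with pytest.raises(rs.UsageError):
            rs.filter_pairs([p], rs.FilterSpec(percentile_level=0.9))

    def test_percentile_filter_uses_per_model_thresholds(self, uniform_bg):
        import numpy as np
        model = rs.ScoringModel("M1", "AR", np.zeros((4, 4)))
        pct = {"M1": rs.calibrate_percentiles(model, uniform_bg, 1000, 1)}
        p = pair(3.0, mut_score=3.0)
        kept = rs.filter_pairs([p], rs.FilterSpec(percentile_level=0.99), pct)
        assert kept == [p]  # threshold is 0 for the uniform model

    def test_exclusive_threshold_options(self):
        with pytest.raises(rs.UsageError):
            rs.FilterSpec(min_hit_score=1.0, percentile_level=0.9)

    def test_monotonicity_raising_thresholds(self, study_result):
        pairs = study_result.pairs
        previous = len(pairs)
        for threshold in (0.0, 1.0, 2.0, 3.0, 5.0):
            kept = rs.filter_pairs(pairs, rs.FilterSpec(min_score_change=threshold))
            assert len(kept) <= previous
            previous = len(kept)
        previous = len(pairs)
        for threshold in (0.0, 1.0, 2.0, 4.0, 8.0):
            kept = rs.filter_pairs(pairs, rs.FilterSpec(min_hit_score=threshold))
            assert len(kept) <= previous
            previous = len(kept)


class TestBestPerVariant:
    def test_highest_change_survives(self):
        pairs = [pair(4.9, model="A1"), pair(2.4, model="B1"), pair(1.7, model="C1")]
        (best,) = rs.best_per_variant(pairs)
        assert best.score_change == 4.9

    def test_empty_input(self):
        assert rs.best_per_variant([]) == []

    def test_tie_broken_by_max_hit_score(self):
        low = pair(3.0, mut_score=3.0, model="A1")
        high = pair(3.0, wt_score=5.0, mut_score=2.0, model="B1")
        (best,) = rs.best_per_variant([low, high])
        assert best is high

    def test_full_tie_broken_by_model_id(self):
        a = pair(3.0, mut_score=3.0, model="A1")
        b = pair(3.0, mut_score=3.0, model="B1")
        (best,) = rs.best_per_variant([b, a])
        assert best.model_id == "A1"

    def test_one_pair_per_variant(self):
        pairs = [pair(4.0, V1), pair(1.0, V1), pair(2.0, V2), pair(3.0, V2)]
        best = rs.best_per_variant(pairs)
        assert [p.variant.variant_id for p in best] == ["rs1", "rs2"]
        assert [p.score_change for p in best] == [4.0, 3.0]


class TestSortPairs:
    def test_score_change_descending(self):
        pairs = [pair(1.7), pair(4.9), pair(2.4)]
        assert [p.score_change for p in rs.sort_pairs(pairs, "score_change")] \
            == [4.9, 2.4, 1.7]

    def test_position_ascending(self):
        pairs = [pair(1.0, start=300), pair(1.0, start=50), pair(1.0, start=120)]
        assert [p.abs_start for p in rs.sort_pairs(pairs, "position")] == [50, 120, 300]

    def test_stability_on_equal_keys(self):
        a = pair(2.0, model="Z9")
        b = pair(2.0, model="A1")
        assert rs.sort_pairs([a, b], "score_change") == [a, b]

    def test_unknown_key_rejected(self):
        with pytest.raises(rs.UsageError):
            rs.sort_pairs([], "accession_number")


class TestAnnotateConserved:
    def test_overlap_flags(self):
        p = pair(3.0, start=100)  # span [100, 111] 1-based inclusive
        overlapping = rs.ConservedRegions([("chr1", 105, 200)])
        flagged = rs.annotate_conserved([p], overlapping)
        assert flagged[0].conserved is True

    def test_adjacent_interval_does_not_overlap(self):
        # interval [112, 200) covers 1-based bases 113..200: base 112 is
        # 0-based start 111, one past the hit's last base
        p = pair(3.0, start=100)
        adjacent = rs.ConservedRegions([("chr1", 112, 200)])
        assert rs.annotate_conserved([p], adjacent)[0].conserved is False
        touching = rs.ConservedRegions([("chr1", 110, 200)])
        assert rs.annotate_conserved([p], touching)[0].conserved is True

    def test_no_regions_all_false(self):
        flagged = rs.annotate_conserved([pair(3.0)], None)
        assert flagged[0].conserved is False

    def test_chromosome_must_match_when_context_named(self):
        ctx = rs.CoordinateContext(chrom="chr2")
        regions = rs.ConservedRegions([("chr1", 0, 10000)])
        assert rs.annotate_conserved([pair(3.0)], regions, ctx)[0].conserved is False

    def test_from_bed(self):
        regions = rs.ConservedRegions.from_bed(
            "track name=cons\nchr1\t104\t200\tx\n")
        assert regions.intervals == (("chr1", 104, 200),)


class TestExportPairs:
    CTX = rs.CoordinateContext(chrom="chr1")

    def test_text_round_trip_lossless(self):
        pairs = [pair(4.9, V1), pair(1.6, V2, wt_score=4.6, mut_score=3.0)]
        text = rs.export_pairs(pairs, "text", context=self.CTX)
        records = rs.parse_text_export(text)
        assert len(records) == 2
        assert records[0]["variant_id"] == "rs1"
        assert records[0]["wt_score"] is None
        assert records[0]["mut_score"] == pytest.approx(4.9)
        assert records[0]["score_change"] == pytest.approx(4.9)
        assert (records[0]["start"], records[0]["end"]) == (95, 106)
        assert records[1]["wt_score"] == pytest.approx(4.6)
        assert records[1]["significant"] == "no"

    def test_delimiter_changes_only_separators(self):
        pairs = [pair(4.9)]
        tab = rs.export_pairs(pairs, "text", delimiter="\t", context=self.CTX)
        comma = rs.export_pairs(pairs, "text", delimiter=",", context=self.CTX)
        assert tab.replace("\t", ",") == comma
        assert len(tab.splitlines()[1].split("\t")) == \
            len(comma.splitlines()[1].split(","))

    def test_alignments_format_adds_site_sequences(self):
        text = rs.export_pairs([pair(4.9)], "alignments", context=self.CTX)
        rec = rs.parse_text_export(text)[0]
        assert rec["wt_site"] == "-"
        assert rec["mut_site"] == "ACGTACGTACGT"

    def test_bed_coordinates_and_score_scaling(self):
        p = pair(4.9, start=100)  # span [100, 111]
        bed = rs.export_pairs([p], "bed", context=self.CTX)
        fields = bed.splitlines()[1].split("\t")
        assert fields[:3] == ["chr1", "99", "111"]
        assert fields[3] == "AR|rs1"
        assert fields[4] == "1000"  # 4.9 * 250 capped at 1000
        small = rs.export_pairs([pair(1.6, wt_score=4.6, mut_score=3.0)],
                                "bed", context=self.CTX)
        assert small.splitlines()[1].split("\t")[4] == "400"

    def test_gff_records(self):
        gff = rs.export_pairs([pair(2.4)], "gff", context=self.CTX)
        lines = gff.splitlines()
        assert lines[0] == "##gff-version 2"
        fields = lines[1].split("\t")
        assert fields[2] == "TFBS_variant"
        assert (fields[3], fields[4]) == ("95", "106")
        assert float(fields[5]) == pytest.approx(2.4)
        assert 'Variant "rs1"' in fields[8]

    def test_bed_requires_absolute_context(self):
        with pytest.raises(rs.UsageError):
            rs.export_pairs([pair(1.0)], "bed", context=None)

    def test_compress_gzip_round_trip(self):
        pairs = [pair(4.9)]
        raw = rs.export_pairs(pairs, "text", context=self.CTX)
        packed = rs.export_pairs(pairs, "text", context=self.CTX, compress=True)
        assert gzip.decompress(packed).decode() == raw

    def test_relative_coordinate_display(self):
        ctx = rs.CoordinateContext(chrom="chr1", tss_abs=100, strand="+")
        text = rs.export_pairs([pair(4.9, start=95)], "text", context=ctx,
                               coordinate_system="tss")
        rec = rs.parse_text_export(text)[0]
        assert (rec["start"], rec["end"]) == (-5, 7)  # span straddles the TSS
        assert rec["notation"] == "A1G"  # variant at abs 100 == TSS

    def test_filtered_exports_respect_filters(self, study_result):
        spec = rs.FilterSpec(min_score_change=2.0)
        kept = rs.filter_pairs(study_result.pairs, spec)
        assert all(p.score_change >= 2.0 for p in kept)
        best = rs.best_per_variant(kept)
        assert all(p.score_change >= 2.0 for p in best)
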