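"""CIGAR-walk variant calling, canonical naming, normalization, aggregation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editprofile.alignments import AlignedSegment
from editprofile.config import GeneRegion, RunConfig
from editprofile.errors import NamingError, RegionBoundsError
from editprofile.impact import apply_variants
from editprofile.variants import (
    Variant,
    aggregate_alleles,
    call_variants,
    left_align,
    name_allele,
    normalize_variants,
    parse_allele_name,
    sort_variants,
)


def region_over(ref: str, start: int = 1, end: int = None, **kw) -> GeneRegion:
    end = end or len(ref)
    kw.setdefault("cut_sites", ((start + end) // 2,))
    return GeneRegion(name="r", chrom="frag", region_start=start, region_end=end,
                      window_start=start, window_end=end, **kw)


def seg(ref_start: int, cigar, query: str, read_id: str = "r1") -> AlignedSegment:
    return AlignedSegment(read_id, "frag", ref_start, tuple(cigar), query)


class TestCallVariants:
    def test_snp_from_mismatch_in_m_run(self):
        ref = "ACGTACGTAC"
        vs = call_variants(seg(0, [("M", 10)], "ACGTTCGTAC"), ref, region_over(ref))
        assert vs == [Variant("SNP", 5, 5, "A", "T")]

    def test_deletion_coordinates(self):
        ref = "A" * 100 + "ACGTACGTAC" + "CCCCC" + "GTGTGTGTGT" + "A" * 75
        region = region_over(ref)
        vs = call_variants(seg(100, [("M", 10), ("D", 5), ("M", 10)], "ACGTACGTAC" + "GTGTGTGTGT"), ref, region)
        assert vs == [Variant("DEL", 111, 115, "CCCCC", "")]

    def test_insertion_after_position(self):
        ref = "AAAAACCCCC" + "T" * 20
        region = region_over(ref)
        vs = call_variants(seg(0, [("M", 5), ("I", 3), ("M", 5)], "AAAAA" + "GGG" + "CCCCC"), ref, region)
        assert vs == [Variant("INS", 5, 5, "", "GGG")]

    def test_n_in_query_never_calls_snp(self):
        ref = "ACGTACGTAC"
        vs = call_variants(seg(0, [("M", 10)], "ACGTNCGTAC"), ref, region_over(ref))
        assert vs == []

    def test_clips_emit_nothing(self):
        ref = "ACGTACGTACGTACGTACGT"
        vs = call_variants(seg(5, [("S", 3), ("M", 10), ("H", 2)], "TTT" + ref[5:15]), ref, region_over(ref))
        assert vs == []

    def test_alignment_past_reference_is_bounds_error(self):
        ref = "ACGTACGT"
        with pytest.raises(RegionBoundsError):
            call_variants(seg(5, [("M", 10)], "ACGTACGTAC"), ref, region_over(ref))

    def test_variant_outside_region_dropped(self):
        ref = "ACGTACGTACGTACGTACGT"
        region = region_over(ref, start=11, end=20)
        # SNP at absolute position 3 lies before the region
        vs = call_variants(seg(0, [("M", 20)], "ACTTACGTACGTACGTACGT"), ref, region)
        assert vs == []


class TestNaming:
    def test_large_deletion_name(self):
        # a deletion of region-relative bases 2..183 (two-guide null allele)
        ref = "A" * 400
        region = region_over(ref, start=1, end=400)
        v = Variant("DEL", 2, 183, ref[1:183], "")
        assert name_allele([v], region) == "2-183del"

    def test_empty_set_is_wt(self, std_region):
        assert name_allele([], std_region) == "WT"

    def test_multi_variant_join_order(self):
        ref = "ACGTACGTACGTACGTACGT"
        region = region_over(ref)
        vs = [Variant("INS", 12, 12, "", "TT"), Variant("SNP", 7, 7, "G", "A")]
        assert name_allele(vs, region) == "7G>A;12insTT"

    def test_single_base_deletion_short_form(self):
        ref = "ACGTACGTAC"
        region = region_over(ref)
        assert name_allele([Variant("DEL", 10, 10, "C", "")], region) == "10del"

    def test_variant_outside_region_raises(self):
        ref = "ACGTACGTAC"
        region = region_over(ref, start=3, end=8)
        with pytest.raises(NamingError):
            name_allele([Variant("SNP", 1, 1, "A", "C")], region)

    @settings(derandomize=True, max_examples=50)
    @given(st.data())
    def test_parse_inverts_naming(self, data):
        ref = "ACGTTGCAAC" * 30
        region = region_over(ref)
        n = data.draw(st.integers(0, 4))
        vs, used = [], set()
        for _ in range(n):
            kind = data.draw(st.sampled_from(["SNP", "INS", "DEL"]))
            pos = data.draw(st.integers(5, 280))
            if any(abs(pos - u) < 8 for u in used):
                continue
            used.add(pos)
            if kind == "SNP":
                alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref[pos - 1]]))
                vs.append(Variant("SNP", pos, pos, ref[pos - 1], alt))
            elif kind == "INS":
                alt = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=5))
                vs.append(Variant("INS", pos, pos, "", alt))
            else:
                ln = data.draw(st.integers(1, 5))
                vs.append(Variant("DEL", pos, pos + ln - 1, ref[pos - 1 : pos + ln - 1], ""))
        name = name_allele(vs, region)
        assert name_allele(parse_allele_name(name, region, ref), region) == name


class TestNormalization:
    def test_left_alignment_in_repeat_context(self):
        #      123456789012  (T homopolymer spans 4..9)
        ref = "ACGTTTTTTGCA"
        region = region_over(ref)
        # deleting any two Ts of the homopolymer is the same molecule
        for s in (5, 6, 7, 8):
            v = Variant("DEL", s, s + 1, ref[s - 1 : s + 1], "")
            (n,) = normalize_variants([v], ref, region)
            assert (n.start, n.end) == (4, 5)

    def test_left_alignment_preserves_molecule(self):
        ref = "ACGTTTTTTGCAACGTACGTACGT"
        region = region_over(ref)
        for s in (5, 6, 7, 8):
            v = Variant("DEL", s, s + 1, ref[s - 1 : s + 1], "")
            (n,) = normalize_variants([v], ref, region)
            before = apply_variants(ref, [v], region).sequence
            after = apply_variants(ref, [n], region).sequence
            assert before == after

    def test_insertion_rotation(self):
        ref = "ACGTTTTTTGCA"
        region = region_over(ref)
        # inserting TT after any T of the run is the same molecule
        names = set()
        for p in (4, 5, 6, 7, 8, 9):
            (n,) = normalize_variants([Variant("INS", p, p, "", "TT")], ref, region)
            names.add(name_allele([n], region))
        assert len(names) == 1

    def test_shift_never_crosses_other_variants(self):
        # junction pair: insertion immediately left of a deletion in repeat context
        ref = "ACGTTTTTTTTTGCAACGT"
        region = region_over(ref)
        ins = Variant("INS", 7, 7, "", "GG")
        dele = Variant("DEL", 8, 10, ref[7:10], "")
        before = apply_variants(ref, [ins, dele], region).sequence
        normalized = normalize_variants([ins, dele], ref, region)
        after = apply_variants(ref, normalized, region).sequence
        assert before == after


class TestAggregation:
    def _reads(self, region, ref):
        d = Variant("DEL", region.region_start + 9, region.region_start + 9,
                    ref[region.region_start + 8], "")
        return [("r1", ()), ("r2", ()), ("r3", ()), ("r4", (d,))]

    def test_counts_and_frequencies(self, std_ref, std_region):
        alleles = aggregate_alleles(self._reads(std_region, std_ref), RunConfig(), std_region)
        assert [(a.name, a.count, a.frequency) for a in alleles] == [
            ("WT", 3, 0.75),
            ("10del", 1, 0.25),
        ]

    def test_ignore_single_suppresses_but_keeps_denominator(self, std_ref, std_region):
        alleles = aggregate_alleles(
            self._reads(std_region, std_ref), RunConfig(ignore_single=True), std_region
        )
        reported = [a for a in alleles if a.reported]
        assert [(a.name, a.count) for a in reported] == [("WT", 3)]
        assert sum(a.count for a in alleles) == 4
        assert reported[0].frequency == 0.75

    def test_ignore_snp_collapses_snp_only_reads_to_wt(self, std_ref, std_region):
        snp = Variant("SNP", 300, 300, std_ref[299], "A" if std_ref[299] != "A" else "C")
        reads = [("r1", (snp,)), ("r2", (snp,))]
        alleles = aggregate_alleles(reads, RunConfig(ignore_snp=True), std_region)
        assert [(a.name, a.count) for a in alleles] == [("WT", 2)]

    def test_frequencies_sum_to_one_over_all_alleles(self, std_ref, std_region):
        alleles = aggregate_alleles(
            self._reads(std_region, std_ref), RunConfig(cutoff=30.0, ignore_single=True), std_region
        )
        assert sum(a.frequency for a in alleles) == pytest.approx(1.0)

    def test_error_reads_grouped_as_error_pseudo_allele(self, std_ref, std_region):
        reads = [("r1", ()), ("r2", None)]
        alleles = aggregate_alleles(reads, RunConfig(), std_region)
        assert {a.name for a in alleles} == {"WT", "ERROR"}
        assert sum(a.count for a in alleles) == 2
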