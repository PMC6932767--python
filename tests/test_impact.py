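"""Mutant-sequence construction and the twelve coding-impact metrics."""

import dataclasses

import pytest

from editprofile.config import GeneRegion, RunConfig, revcomp
from editprofile.impact import (
    FLAG_ORDER,
    ImpactProfile,
    annotate_impact,
    apply_variants,
    find_cryptic_orfs,
)
from editprofile.errors import OverlapError
from editprofile.simulate import SimSpec, cryptic_start_analog, make_reference, simulate_reads
from editprofile.variants import Variant


def tiny_region(ref, **kw):
    kw.setdefault("cds_start", None)
    kw.setdefault("cds_end", None)
    return GeneRegion(name="t", chrom="c", region_start=1, region_end=len(ref),
                      cut_sites=(len(ref) // 2,), window_start=1, window_end=len(ref), **kw)


class TestApplyVariants:
    def test_deletion(self):
        ref = "ATGAAATAG"
        region = tiny_region(ref)
        mut = apply_variants(ref, [Variant("DEL", 4, 6, "AAA", "")], region)
        assert mut.sequence == "ATGTAG"
        assert mut.ref_to_mut[3] is None and mut.ref_to_mut[6] == 3

    def test_snp(self):
        ref = "ATGAAATAG"
        region = tiny_region(ref)
        mut = apply_variants(ref, [Variant("SNP", 5, 5, "A", "C")], region)
        assert mut.sequence == "ATGACATAG"

    def test_insertion_and_map_monotone(self):
        ref = "ATGAAATAG"
        region = tiny_region(ref)
        mut = apply_variants(ref, [Variant("INS", 3, 3, "", "GGG")], region)
        assert mut.sequence == "ATGGGGAAATAG"
        survivors = [m for m in mut.ref_to_mut if m is not None]
        assert survivors == sorted(survivors)

    def test_overlap_raises(self):
        ref = "ATGAAATAG"
        region = tiny_region(ref)
        with pytest.raises(OverlapError):
            apply_variants(
                ref,
                [Variant("DEL", 2, 5, "TGAA", ""), Variant("SNP", 3, 3, "G", "A")],
                region,
            )

    def test_overlapping_variants_give_error_profile(self):
        ref = "ATGAAATAG"
        region = tiny_region(ref, cds_start=1, cds_end=9)
        p = annotate_impact(
            [Variant("DEL", 2, 5, "TGAA", ""), Variant("SNP", 3, 3, "G", "A")],
            region, ref, RunConfig(),
        )
        assert p.ERROR is True
        assert all(getattr(p, f) is None for f in FLAG_ORDER if f != "ERROR")


@pytest.fixture(scope="module")
def gene():
    ref = make_reference(400, seed=3, cds=(101, 280))
    region = GeneRegion(name="g", chrom="c", region_start=1, region_end=400,
                        cut_sites=(200,), window_start=1, window_end=400,
                        cds_start=101, cds_end=280)
    region.validate(ref)
    return ref, region


class TestAnnotate:
    def test_empty_set_is_wt_with_reference_cds_length(self, gene):
        ref, region = gene
        p = annotate_impact([], region, ref, RunConfig())
        assert p.WT is True and p.CODING is True and p.cds_length == 180
        assert not any(getattr(p, f) for f in ("FS", "SNP", "ATG", "STOP", "PSTOP", "SM", "LG"))

    def test_one_bp_deletion_mid_cds_frameshifts(self, gene):
        ref, region = gene
        v = Variant("DEL", 200, 200, ref[199], "")
        p = annotate_impact([v], region, ref, RunConfig())
        assert p.FS is True and p.SM is True and p.LG is False and p.WT is False

    def test_three_bp_inframe_deletion(self, gene):
        ref, region = gene
        v = Variant("DEL", 200, 202, ref[199:202], "")
        p = annotate_impact([v], region, ref, RunConfig())
        assert p.FS is False and p.SM is True and p.PSTOP is False and p.CODING is True

    def test_utr_indel_flagged_utr_not_fs(self, gene):
        ref, region = gene
        v = Variant("DEL", 20, 22, ref[19:22], "")
        p = annotate_impact([v], region, ref, RunConfig())
        assert p.UTR is True and p.FS is False and p.WT is True

    def test_start_codon_deletion_destroys_atg(self, gene):
        ref, region = gene
        v = Variant("DEL", 101, 103, ref[100:103], "")
        p = annotate_impact([v], region, ref, RunConfig())
        assert p.ATG is True and p.CODING is False and p.cds_length == 0

    def test_stop_codon_destroyed_flagged(self, gene):
        ref, region = gene
        # substitute the stop codon's middle base away from any stop triplet
        mid = ref[279 - 1]
        p = None
        for alt in "ACGT":
            if alt == mid:
                continue
            cand = ref[277:280].replace(mid, alt, 1)
            new = ref[277] + alt + ref[279]
            if new not in ("TAA", "TAG", "TGA"):
                p = annotate_impact([Variant("SNP", 279, 279, mid, alt)], region, ref, RunConfig())
                break
        assert p is not None and p.STOP is True and p.SNP is True

    def test_premature_stop_from_substitution(self, gene):
        ref, region = gene
        # force codon at 161..163 to TAA via up to three SNPs
        vs = [
            Variant("SNP", 161 + i, 161 + i, ref[160 + i], b)
            for i, b in enumerate("TAA")
            if ref[160 + i] != b
        ]
        p = annotate_impact(vs, region, ref, RunConfig())
        assert p.CODING is True and p.PSTOP is True
        assert p.cds_length == 163 - 101 + 1  # truncated ORF, stop included

    def test_large_deletion_flag_threshold(self, gene):
        ref, region = gene
        v = Variant("DEL", 150, 179, ref[149:179], "")
        assert annotate_impact([v], region, ref, RunConfig()).LG is True
        assert annotate_impact([v], region, ref, RunConfig(small_indel_max=40)).SM is True

    def test_no_cds_region_leaves_coding_flags_na(self):
        ref = make_reference(200, seed=4)
        region = tiny_region(ref)
        p = annotate_impact([Variant("DEL", 100, 101, ref[99:101], "")], region, ref, RunConfig())
        assert p.SM is True and p.CODING is None and p.WT is None


class TestStrandSymmetry:
    def mirror(self, ref, region, variants):
        L = len(ref)
        m_ref = revcomp(ref)
        m_region = GeneRegion(
            name=region.name, chrom=region.chrom,
            region_start=L - region.region_end + 1, region_end=L - region.region_start + 1,
            strand="-" if region.strand == "+" else "+",
            cut_sites=tuple(L - c + 1 for c in region.cut_sites),
            window_start=L - region.window_end + 1, window_end=L - region.window_start + 1,
            cds_start=L - region.cds_end + 1, cds_end=L - region.cds_start + 1,
        )
        m_vs = []
        for v in variants:
            if v.kind == "SNP":
                m_vs.append(Variant("SNP", L - v.start + 1, L - v.start + 1,
                                    revcomp(v.ref_bases), revcomp(v.alt_bases)))
            elif v.kind == "DEL":
                m_vs.append(Variant("DEL", L - v.end + 1, L - v.start + 1,
                                    revcomp(v.ref_bases), ""))
            else:
                m_vs.append(Variant("INS", L - v.start, L - v.start, "", revcomp(v.alt_bases)))
        return m_ref, m_region, m_vs

    @pytest.mark.parametrize("case", ["del1", "del3", "snp", "ins", "startdel"])
    def test_mirrored_profiles_identical(self, gene, case):
        ref, region = gene
        variants = {
            "del1": [Variant("DEL", 200, 200, ref[199], "")],
            "del3": [Variant("DEL", 200, 202, ref[199:202], "")],
            "snp": [Variant("SNP", 205, 205, ref[204], "A" if ref[204] != "A" else "C")],
            "ins": [Variant("INS", 210, 210, "", "GG")],
            "startdel": [Variant("DEL", 101, 110, ref[100:110], "")],
        }[case]
        m_ref, m_region, m_vs = self.mirror(ref, region, variants)
        m_region.validate(m_ref)
        p1 = annotate_impact(variants, region, ref, RunConfig()).as_dict()
        p2 = annotate_impact(m_vs, m_region, m_ref, RunConfig()).as_dict()
        assert p1 == p2


class TestCrypticOrfs:
    def test_start_deletion_exposes_downstream_atg(self):
        ref, region, dele = cryptic_start_analog(seed=0)
        cfg = RunConfig()
        p = annotate_impact([dele], region, region.region_sequence(ref), cfg)
        assert p.ATG is True and p.CODING is False and p.CRYPTIC is True and p.LG is True
        mut = apply_variants(region.region_sequence(ref), [dele], region)
        (orf,) = find_cryptic_orfs(mut, region, region.region_sequence(ref), cfg)
        # cryptic start sits one base downstream of the original start
        assert orf.mut_start == mut.ref_to_mut[0] + 1
        assert p.cds_length == orf.length == 147

    def test_unedited_reference_has_no_cryptic_orf(self):
        ref, region, _ = cryptic_start_analog(seed=0)
        cfg = RunConfig()
        mut = apply_variants(region.region_sequence(ref), [], region)
        assert find_cryptic_orfs(mut, region, region.region_sequence(ref), cfg) == []

    def test_no_atg_no_orfs(self):
        ref = "CCCCCCCCCCCCCCCCCCCC" * 5
        region = tiny_region(ref)
        mut = apply_variants(ref, [], region)
        assert find_cryptic_orfs(mut, region, ref, RunConfig(min_cryptic_codons=2)) == []


class TestFrameshiftGrid:
    def test_fs_equals_net_cds_indel_mod3_on_simulated_alleles(self, gene):
        ref, region = gene
        spec = SimSpec(region=region, reference=ref, n_reads=300,
                       class_weights={"WT": 0.3, "NHEJ": 0.7}, seed=6)
        cfg = RunConfig()
        seen = 0
        for read in simulate_reads(spec):
            p = annotate_impact(read.variants, region, ref, cfg)
            net = 0
            for v in read.variants:
                if v.kind == "INS" and region.cds_start <= v.start <= region.cds_end - 1:
                    net += v.length
                elif v.kind == "DEL":
                    net -= max(0, min(v.end, region.cds_end) - max(v.start, region.cds_start) + 1)
            assert p.FS == (net % 3 != 0), read.read_id
            seen += 1
        assert seen == 300
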