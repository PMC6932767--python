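"""Coding-impact annotation of alleles.

Variants are applied to the region sequence to build the mutant molecule,
and codon logic (start/stop codon integrity, frameshift, premature stops,
cryptic open reading frames) is evaluated on that molecule, on the coding
strand.  Each allele is scored on twelve three-state metrics::

    WT      mutant coding sequence identical to the reference CDS
    FS      net indel length within the CDS not a multiple of 3
    SNP     any single-base substitution present
    ATG     start codon destroyed (deleted, interrupted, or no longer ATG)
    CODING  start codon intact and translation reaches an in-frame stop
    STOP    stop codon destroyed
    PSTOP   first in-frame stop strictly upstream of the original stop
    SM      small indel present (length <= small_indel_max)
    LG      large indel present (length  > small_indel_max)
    UTR     indel wholly outside the CDS but inside the region
    CRYPTIC a qualifying cryptic ORF distinct from the normal CDS exists
    ERROR   the algorithm failed to make a determination

plus the mutant coding-sequence length in bases (stop codon included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .config import GeneRegion, STOP_CODONS, revcomp
from .errors import OverlapError
from .variants import Variant, sort_variants


@dataclass
class MutantSequence:
    """Region sequence with an allele applied, plus the coordinate map.

    ``ref_to_mut[i]`` gives the mutant index of region-relative (0-based)
    reference base ``i``, or ``None`` when that base was deleted;
    ``mut_to_ref`` is the inverse (``None`` for inserted bases).  Both maps
    are monotone.
    """

    sequence: str
    ref_to_mut: list[Optional[int]]
    mut_to_ref: list[Optional[int]]


def apply_variants(
    region_seq: str, variants: Sequence[Variant], region: GeneRegion
) -> MutantSequence:
    """Apply SNPs/insertions/deletions to the (forward-strand) region sequence.

    Raises :class:`OverlapError` when variants collide on the reference
    (intersecting substitution/deletion intervals, two insertions at one
    point, or an insertion point strictly inside a deletion).
    """
    L = len(region_seq)
    snp_at: dict[int, str] = {}
    deleted: set[int] = set()
    ins_after: dict[int, str] = {}
    vs = sort_variants(variants)
    for v in vs:
        s0 = v.start - region.region_start  # 0-based region-relative
        e0 = v.end - region.region_start
        if v.kind == "INS":
            if s0 in ins_after:
                raise OverlapError(f"two insertions at position {v.start}")
            ins_after[s0] = v.alt_bases
        else:
            if s0 < 0 or e0 >= L:
                raise OverlapError(f"variant {v.start}-{v.end} outside the region")
            for i in range(s0, e0 + 1):
                if i in deleted or i in snp_at:
                    raise OverlapError(f"variants overlap at reference position {i + region.region_start}")
                if v.kind == "DEL":
                    deleted.add(i)
                else:
                    snp_at[i] = v.alt_bases
    for p in ins_after:
        if p in deleted and (p + 1) in deleted:
            raise OverlapError("insertion point strictly inside a deletion")
    chars: list[str] = []
    mut_to_ref: list[Optional[int]] = []
    ref_to_mut: list[Optional[int]] = [None] * L
    for i in range(L):
        if i not in deleted:
            chars.append(snp_at.get(i, region_seq[i]))
            ref_to_mut[i] = len(chars) - 1
            mut_to_ref.append(i)
        if i in ins_after:
            for ch in ins_after[i]:
                chars.append(ch)
                mut_to_ref.append(None)
    return MutantSequence("".join(chars), ref_to_mut, mut_to_ref)


# ---------------------------------------------------------------------------
# coding-strand view

@dataclass
class CodingView:
    """Reference and mutant region sequences oriented to the coding strand,
    with the coordinate map reflected accordingly."""

    ref: str
    mut: str
    ref_to_mut: list[Optional[int]]
    mut_to_ref: list[Optional[int]]
    cds_lo: int  # 0-based CDS start within the coding-strand reference
    cds_len: int


def coding_view(region_seq: str, mutant: MutantSequence, region: GeneRegion) -> CodingView:
    L, Lm = len(region_seq), len(mutant.sequence)
    cds_len = (region.cds_end - region.cds_start + 1) if region.has_cds else 0
    if region.strand == "+":
        cds_lo = (region.cds_start - region.region_start) if region.has_cds else 0
        return CodingView(region_seq, mutant.sequence, list(mutant.ref_to_mut), list(mutant.mut_to_ref), cds_lo, cds_len)
    r2m = [
        (Lm - 1 - mutant.ref_to_mut[L - 1 - i]) if mutant.ref_to_mut[L - 1 - i] is not None else None
        for i in range(L)
    ]
    m2r = [
        (L - 1 - mutant.mut_to_ref[Lm - 1 - j]) if mutant.mut_to_ref[Lm - 1 - j] is not None else None
        for j in range(Lm)
    ]
    cds_lo = (region.region_end - region.cds_end) if region.has_cds else 0
    return CodingView(revcomp(region_seq), revcomp(mutant.sequence), r2m, m2r, cds_lo, cds_len)


# ---------------------------------------------------------------------------
# cryptic ORFs

@dataclass
class CrypticOrf:
    """ATG-initiated ORF on the mutant coding strand, distinct from the CDS."""

    mut_start: int  # 0-based position in the coding-strand mutant sequence
    ref_start: Optional[int]  # region-relative 1-based (coding strand), None if inserted
    length: int  # bases, stop codon included


def _scan_orfs(seq: str, min_codons: int) -> list[tuple[int, int]]:
    """(start, length) of every ATG-initiated ORF with an in-frame stop."""
    out = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i, len(seq) - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                length = j + 3 - i
                if length // 3 >= min_codons:
                    out.append((i, length))
                break
    return out


def find_cryptic_orfs(
    mutant: MutantSequence, region: GeneRegion, region_seq: str, config
) -> list[CrypticOrf]:
    """Scan the mutant coding-strand sequence for qualifying cryptic ORFs.

    ORFs belonging to the normal reading frame are excluded: the ORF starting
    at the (surviving) start codon, any ORF identical to the reference CDS,
    and in-frame internal ATGs nested inside the translated primary ORF
    (those are internal methionines, not cryptic starts).  The normal frame
    is scored by the CODING/PSTOP flags instead.  Sorted by descending
    length, ties by leftmost start.
    """
    view = coding_view(region_seq, mutant, region)
    ref_cds = view.ref[view.cds_lo : view.cds_lo + view.cds_len] if region.has_cds else ""
    normal_start_mut = view.ref_to_mut[view.cds_lo] if region.has_cds else None
    primary: Optional[tuple[int, int]] = None  # [start, stop_end] of the normal-frame ORF
    if normal_start_mut is not None and view.mut[normal_start_mut : normal_start_mut + 3] == "ATG":
        for j in range(normal_start_mut, len(view.mut) - 2, 3):
            if view.mut[j : j + 3] in STOP_CODONS:
                primary = (normal_start_mut, j + 2)
                break
    out = []
    for start, length in _scan_orfs(view.mut, config.min_cryptic_codons):
        orf_seq = view.mut[start : start + length]
        if region.has_cds and (orf_seq == ref_cds or start == normal_start_mut):
            continue
        if primary and primary[0] <= start <= primary[1] and (start - primary[0]) % 3 == 0:
            continue
        ref_start = view.mut_to_ref[start]
        out.append(
            CrypticOrf(
                mut_start=start,
                ref_start=(ref_start + 1) if ref_start is not None else None,
                length=length,
            )
        )
    out.sort(key=lambda o: (-o.length, o.mut_start))
    return out


# ---------------------------------------------------------------------------
# the impact profile

FLAG_ORDER = ("WT", "FS", "SNP", "ATG", "CODING", "STOP", "PSTOP", "SM", "LG", "UTR", "CRYPTIC", "ERROR")


@dataclass
class ImpactProfile:
    """Three-state (True/False/None=not-applicable) flags plus CDS length."""

    WT: Optional[bool] = None
    FS: Optional[bool] = None
    SNP: Optional[bool] = None
    ATG: Optional[bool] = None
    CODING: Optional[bool] = None
    STOP: Optional[bool] = None
    PSTOP: Optional[bool] = None
    SM: Optional[bool] = None
    LG: Optional[bool] = None
    UTR: Optional[bool] = None
    CRYPTIC: Optional[bool] = None
    ERROR: Optional[bool] = False
    cds_length: int = 0

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in FLAG_ORDER}
        d["cds_length"] = self.cds_length
        return d

    @classmethod
    def error_profile(cls) -> "ImpactProfile":
        return cls(ERROR=True)


def _codon_intact(view: CodingView, c0: int, allowed: set[str]) -> bool:
    ms = [view.ref_to_mut[c0 + k] for k in range(3)]
    if any(m is None for m in ms):
        return False
    if ms[1] != ms[0] + 1 or ms[2] != ms[0] + 2:
        return False
    return view.mut[ms[0] : ms[0] + 3] in allowed


def annotate_impact(
    variants: Optional[Sequence[Variant]],
    region: GeneRegion,
    region_seq: str,
    config,
) -> ImpactProfile:
    """Score one allele's variant set; ``variants=None`` (an unresolved read
    group) or any application failure yields the all-not-applicable ERROR
    profile."""
    if variants is None:
        return ImpactProfile.error_profile()
    vs = sort_variants(variants)
    try:
        mutant = apply_variants(region_seq, vs, region)
    except OverlapError:
        return ImpactProfile.error_profile()
    p = ImpactProfile()
    p.SNP = any(v.kind == "SNP" for v in vs)
    indels = [v for v in vs if v.kind in ("INS", "DEL")]
    p.SM = any(v.length <= config.small_indel_max for v in indels)
    p.LG = any(v.length > config.small_indel_max for v in indels)
    if not region.has_cds:
        p.cds_length = 0
        return p
    view = coding_view(region_seq, mutant, region)
    cs, ce = region.cds_start, region.cds_end
    # frameshift: net indel length landing inside the CDS
    net = 0
    for v in indels:
        if v.kind == "INS":
            if cs <= v.start <= ce - 1:
                net += v.length
        else:
            net -= max(0, min(v.end, ce) - max(v.start, cs) + 1)
    p.FS = net % 3 != 0
    p.UTR = any(
        (v.kind == "DEL" and (v.end < cs or v.start > ce))
        or (v.kind == "INS" and not (cs <= v.start <= ce - 1))
        for v in indels
    )
    c0 = view.cds_lo
    c_stop = view.cds_lo + view.cds_len - 3
    start_intact = _codon_intact(view, c0, {"ATG"})
    stop_intact = _codon_intact(view, c_stop, STOP_CODONS)
    p.ATG = not start_intact
    p.STOP = not stop_intact
    # translate the mutant molecule from the mapped start
    p.CODING = False
    p.PSTOP = False
    m_stop = None
    if start_intact:
        m0 = view.ref_to_mut[c0]
        for j in range(m0, len(view.mut) - 2, 3):
            if view.mut[j : j + 3] in STOP_CODONS:
                m_stop = j
                break
        p.CODING = m_stop is not None
        if p.CODING:
            orig_stop_mut = view.ref_to_mut[c_stop]
            if orig_stop_mut is None:
                survivors = [m for m in (view.ref_to_mut[k] for k in range(c_stop, len(view.ref))) if m is not None]
                orig_stop_mut = survivors[0] if survivors else len(view.mut)
            p.PSTOP = m_stop < orig_stop_mut
    # WT: mutant CDS identical to the reference CDS
    ref_cds = view.ref[c0 : c0 + view.cds_len]
    sm0, sm1 = view.ref_to_mut[c0], view.ref_to_mut[c0 + view.cds_len - 1]
    p.WT = sm0 is not None and sm1 is not None and view.mut[sm0 : sm1 + 1] == ref_cds
    orfs = find_cryptic_orfs(mutant, region, region_seq, config)
    p.CRYPTIC = bool(orfs)
    if p.CODING:
        p.cds_length = m_stop + 3 - view.ref_to_mut[c0]
    elif orfs:
        p.cds_length = orfs[0].length
    else:
        p.cds_length = 0
    return p
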