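"""Variant calling from CIGAR walks, canonical naming, and allele aggregation.

Variants are stored on absolute 1-based inclusive reference coordinates and
named relative to the configured region (position 1 = region start).  Indels
in repeat context are left-aligned before naming so that identical molecules
reported at different aligner placements collapse to one allele.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import NamingError, RegionBoundsError

_KIND_RANK = {"SNP": 0, "INS": 1, "DEL": 2}

#: CIGAR operations that consume the query sequence.
QUERY_OPS = set("MIS=X")
#: CIGAR operations that consume the reference.
REF_OPS = set("MDN=X")


@dataclass(frozen=True)
class Variant:
    """One edit event on absolute 1-based reference coordinates.

    ``start``/``end`` are inclusive.  For an insertion, ``start == end`` is
    the reference base immediately left of the insertion point and
    ``ref_bases`` is empty; for a deletion ``alt_bases`` is empty; a SNP has
    one base on each side.
    """

    kind: str
    start: int
    end: int
    ref_bases: str = ""
    alt_bases: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KIND_RANK:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError("variant start > end")
        if self.kind == "SNP" and not (
            self.start == self.end and len(self.ref_bases) == 1 and len(self.alt_bases) == 1
        ):
            raise ValueError("SNP must substitute exactly one base")
        if self.kind == "INS" and not (self.start == self.end and self.ref_bases == "" and self.alt_bases):
            raise ValueError("INS must have empty ref_bases and non-empty alt_bases")
        if self.kind == "DEL" and not (
            self.alt_bases == "" and len(self.ref_bases) == self.end - self.start + 1
        ):
            raise ValueError("DEL ref_bases must cover start..end")

    @property
    def length(self) -> int:
        """Event size in bases (1 for a SNP)."""
        if self.kind == "INS":
            return len(self.alt_bases)
        return self.end - self.start + 1

    def sort_key(self) -> tuple:
        return (self.start, _KIND_RANK[self.kind], self.end, self.alt_bases)


def sort_variants(variants: Iterable[Variant]) -> tuple[Variant, ...]:
    return tuple(sorted(set(variants), key=Variant.sort_key))


# ---------------------------------------------------------------------------
# normalization

def left_align(variant: Variant, reference: str, min_start: int = 1) -> Variant:
    """Shift an indel to the smallest reference coordinate (>= ``min_start``)
    that yields an identical alternate molecule.

    ``reference`` is the full chromosome sequence (0-based string indexing);
    SNPs are returned unchanged.
    """
    if variant.kind == "SNP":
        return variant
    if variant.kind == "DEL":
        start, end = variant.start, variant.end
        while start > min_start and reference[start - 2] == reference[end - 1]:
            start -= 1
            end -= 1
        if start == variant.start:
            return variant
        return Variant("DEL", start, end, reference[start - 1 : end], "")
    # INS: rotate the inserted sequence left through matching reference bases
    start = variant.start
    alt = variant.alt_bases
    while start > min_start and start >= 1 and reference[start - 1] == alt[-1]:
        alt = reference[start - 1] + alt[:-1]
        start -= 1
    if start == variant.start:
        return variant
    return Variant("INS", start, start, "", alt)


def normalize_variants(
    variants: Iterable[Variant], reference: str, region
) -> tuple[Variant, ...]:
    """Left-align every indel and sort.

    A shift never crosses the region start or another variant of the same
    set: sliding a junction deletion through its junction insertion point
    (or through a SNP) would change the molecule the set describes.
    """
    vs = sort_variants(variants)
    out: list[Variant] = []
    for v in vs:
        bound = region.region_start
        for o in out:  # already-normalized variants to the left
            bound = max(bound, (o.start if o.kind == "INS" else o.end) + 1)
        out.append(left_align(v, reference, min_start=bound))
    return sort_variants(out)


# ---------------------------------------------------------------------------
# CIGAR walking

def call_variants(segment, reference: str, region) -> list[Variant]:
    """Walk a segment's CIGAR against the reference and emit SNP/INS/DEL events.

    Soft/hard clips at the segment ends emit nothing (chimeric junctions are
    resolved separately); ``=``/``X`` runs are treated as M with the mismatch
    decided by base comparison; N in the query never calls a SNP.  Variants
    wholly outside the configured region are dropped and deletions straddling
    a region boundary are clipped to it.  Raises :class:`RegionBoundsError`
    when the alignment runs past the supplied reference.
    """
    ref_pos = segment.ref_start  # 0-based
    qpos = 0
    seq = segment.query_seq or ""
    out: list[Variant] = []
    span = ref_pos + sum(ln for op, ln in segment.cigar if op in REF_OPS)
    if span > len(reference) or ref_pos < 0:
        raise RegionBoundsError(
            f"read {segment.read_id}: alignment [{ref_pos}, {span}) exceeds "
            f"reference of length {len(reference)}"
        )
    for op, length in segment.cigar:
        if op in ("M", "=", "X"):
            for i in range(length):
                qb = seq[qpos + i].upper()
                rb = reference[ref_pos + i].upper()
                if qb != rb and qb != "N":
                    out.append(Variant("SNP", ref_pos + i + 1, ref_pos + i + 1, rb, qb))
            ref_pos += length
            qpos += length
        elif op == "I":
            alt = seq[qpos : qpos + length].upper()
            if ref_pos >= 1:
                out.append(Variant("INS", ref_pos, ref_pos, "", alt))
            qpos += length
        elif op in ("D", "N"):
            out.append(
                Variant("DEL", ref_pos + 1, ref_pos + length, reference[ref_pos : ref_pos + length].upper(), "")
            )
            ref_pos += length
        elif op == "S":
            qpos += length
        elif op in ("H", "P"):
            pass
        else:  # pragma: no cover - unknown op letters are rejected upstream
            raise ValueError(f"unsupported CIGAR op {op!r}")
    return _scope_to_region(out, region)


def _scope_to_region(variants: list[Variant], region) -> list[Variant]:
    lo, hi = region.region_start, region.region_end
    kept: list[Variant] = []
    for v in variants:
        if v.kind == "INS":
            if lo <= v.start <= hi - 1:
                kept.append(v)
        elif v.end < lo or v.start > hi:
            continue
        elif v.kind == "DEL" and (v.start < lo or v.end > hi):
            s, e = max(v.start, lo), min(v.end, hi)
            off = s - v.start
            kept.append(Variant("DEL", s, e, v.ref_bases[off : off + (e - s + 1)], ""))
        else:
            kept.append(v)
    return kept


# ---------------------------------------------------------------------------
# naming

def name_variant(variant: Variant, region) -> str:
    """Region-relative canonical name for one variant."""
    rs = variant.start - region.region_start + 1
    re_ = variant.end - region.region_start + 1
    n = region.region_end - region.region_start + 1
    if rs < 1 or re_ > n:
        raise NamingError(
            f"variant {variant.kind} {variant.start}-{variant.end} outside region {region.name}"
        )
    if variant.kind == "DEL":
        return f"{rs}del" if rs == re_ else f"{rs}-{re_}del"
    if variant.kind == "INS":
        return f"{rs}ins{variant.alt_bases}"
    return f"{rs}{variant.ref_bases}>{variant.alt_bases}"


def name_allele(variants: Sequence[Variant], region) -> str:
    """Canonical allele name: ';'-joined variant names in positional order,
    or ``"WT"`` for the empty set."""
    vs = sort_variants(variants)
    if not vs:
        return "WT"
    return ";".join(name_variant(v, region) for v in vs)


_NAME_RE = re.compile(
    r"^(?:(?P<ds>\d+)(?:-(?P<de>\d+))?del"
    r"|(?P<ip>\d+)ins(?P<iseq>[ACGTN]+)"
    r"|(?P<sp>\d+)(?P<sref>[ACGTN])>(?P<salt>[ACGTN]))$"
)


def parse_allele_name(name: str, region, reference: Optional[str] = None) -> tuple[Variant, ...]:
    """Inverse of :func:`name_allele` (DEL ref bases filled from ``reference``
    when provided, else ``'N'``)."""
    if name == "WT":
        return ()
    out = []
    for part in name.split(";"):
        m = _NAME_RE.match(part)
        if not m:
            raise NamingError(f"unparseable variant name {part!r}")
        off = region.region_start - 1
        if m.group("ds"):
            s = int(m.group("ds")) + off
            e = int(m.group("de") or m.group("ds")) + off
            ref = reference[s - 1 : e] if reference else "N" * (e - s + 1)
            out.append(Variant("DEL", s, e, ref.upper(), ""))
        elif m.group("ip"):
            p = int(m.group("ip")) + off
            out.append(Variant("INS", p, p, "", m.group("iseq")))
        else:
            p = int(m.group("sp")) + off
            out.append(Variant("SNP", p, p, m.group("sref"), m.group("salt")))
    return sort_variants(out)


# ---------------------------------------------------------------------------
# aggregation

#: sentinel variant list marking reads the algorithm could not resolve
ERROR_ALLELE_NAME = "ERROR"


@dataclass
class Allele:
    """A canonical variant set with its read support within one sample x gene."""

    variants: tuple[Variant, ...]
    name: str
    count: int
    frequency: float
    class_label: Optional[str] = None
    impact: Optional[object] = None
    reported: bool = True
    read_ids: tuple[str, ...] = field(default_factory=tuple, repr=False)


def strip_snps(variants: Sequence[Variant], protect: Sequence[Variant] = ()) -> tuple[Variant, ...]:
    """Remove SNP variants except those in ``protect`` (HDR template edits)."""
    keep = set(protect)
    return tuple(v for v in variants if v.kind != "SNP" or v in keep)


def aggregate_alleles(
    per_read_variants: Sequence[tuple[str, Optional[Sequence[Variant]]]],
    config,
    region,
) -> list[Allele]:
    """Group reads by canonical allele name and apply reporting filters.

    ``per_read_variants`` holds one entry per analyzable read; ``None``
    variants mark ERROR reads, grouped under the ``"ERROR"`` pseudo-allele.
    With ``ignore_snp``, SNPs (other than HDR-template edits) are removed
    from every read before naming, so SNP-only reads become WT.  ``cutoff``
    (percent) and ``ignore_single`` suppress alleles from the reported table
    but never shrink the analyzable-read denominator; allele counts always
    sum to the number of analyzable reads.
    """
    total = len(per_read_variants)
    protect = tuple(region.hdr_template or ())
    groups: dict[str, list] = {}
    for read_id, vs in per_read_variants:
        if vs is None:
            key = ERROR_ALLELE_NAME
            canon: tuple[Variant, ...] = ()
        else:
            canon = sort_variants(vs)
            if config.ignore_snp:
                canon = strip_snps(canon, protect)
            key = name_allele(canon, region)
        groups.setdefault(key, [canon, []])[1].append(read_id)
    alleles = []
    for key, (canon, ids) in groups.items():
        count = len(ids)
        freq = count / total if total else 0.0
        reported = True
        if config.ignore_single and count == 1:
            reported = False
        if freq * 100.0 < config.cutoff:
            reported = False
        alleles.append(
            Allele(
                variants=canon if key != ERROR_ALLELE_NAME else (),
                name=key,
                count=count,
                frequency=freq,
                reported=reported,
                read_ids=tuple(sorted(ids)),
            )
        )
    alleles.sort(key=lambda a: (-a.count, a.name))
    return alleles
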