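"""Alignment records for a region: CIGAR/clip structure and read selection.

Wraps pysam records into a light value type so the calling, chimera and
simulation code share one representation.  A read is *analyzable* when the
union of reference intervals covered by its alignment segments contains the
analysis window; a split pair flanking a deletion counts as covering the
deleted interval (otherwise no large deletion could ever be analyzable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pysam

from .errors import ReferenceLookupError

CIGAR_OPS = "MIDNSHP=X"
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_CLIP_OPS = set("SH")


@dataclass
class AlignedSegment:
    """One alignment record (primary or supplementary) in SAM orientation."""

    read_id: str
    ref_name: str
    ref_start: int  # 0-based
    cigar: tuple[tuple[str, int], ...]
    query_seq: str
    is_supplementary: bool = False
    is_reverse: bool = False
    mapq: int = 60

    def __post_init__(self) -> None:
        for op, ln in self.cigar:
            if op not in CIGAR_OPS or ln < 1:
                raise ValueError(f"bad CIGAR element ({op}, {ln})")

    @property
    def left_clip(self) -> int:
        """Soft+hard clipped bases at the left end of the record."""
        n = 0
        for op, ln in self.cigar:
            if op in _CLIP_OPS:
                n += ln
            else:
                break
        return n

    @property
    def right_clip(self) -> int:
        n = 0
        for op, ln in reversed(self.cigar):
            if op in _CLIP_OPS:
                n += ln
            else:
                break
        return n

    @property
    def hard_clipped(self) -> int:
        return sum(ln for op, ln in self.cigar if op == "H")

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the reference span."""
        return self.ref_start + sum(ln for op, ln in self.cigar if op in _REF_OPS)

    @property
    def aligned_query_length(self) -> int:
        """Query bases consumed by non-clip operations (M/I/=/X)."""
        return sum(ln for op, ln in self.cigar if op in "MI=X")

    @property
    def full_read_length(self) -> int:
        """Total read length including clipped-away (hard-clipped) bases."""
        return sum(ln for op, ln in self.cigar if op in _QUERY_OPS) + sum(
            ln for op, ln in self.cigar if op == "H"
        )

    @property
    def query_start(self) -> int:
        """Offset of the first aligned base within the full read (clip arithmetic)."""
        return self.left_clip

    @property
    def query_end(self) -> int:
        return self.left_clip + self.aligned_query_length

    def consistent(self) -> bool:
        """CIGAR query-consuming length must match the stored sequence (+hard clips)."""
        stored = len(self.query_seq) if self.query_seq else 0
        soft = sum(ln for op, ln in self.cigar if op in "MIS=X")
        return soft == stored

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "AlignedSegment":
        cig = tuple((CIGAR_OPS[op], ln) for op, ln in (rec.cigartuples or ()))
        return cls(
            read_id=rec.query_name,
            ref_name=rec.reference_name,
            ref_start=rec.reference_start,
            cigar=cig,
            query_seq=(rec.query_sequence or "").upper(),
            is_supplementary=rec.is_supplementary,
            is_reverse=rec.is_reverse,
            mapq=rec.mapping_quality,
        )


def fetch_segments(
    bam_path: str,
    region,
    min_mapq: int = 0,
    keep_duplicates: bool = False,
) -> list[AlignedSegment]:
    """All primary + supplementary records overlapping the configured region.

    Unmapped, secondary and (by default) duplicate-flagged records are
    excluded; output is sorted by (read_id, is_supplementary, ref_start) so
    downstream grouping is stable under BAM record order.
    """
    with pysam.AlignmentFile(bam_path) as bam:
        if region.chrom not in bam.references:
            raise ReferenceLookupError(f"chromosome {region.chrom!r} absent from {bam_path} header")
        out = []
        for rec in bam.fetch(region.chrom, region.region_start - 1, region.region_end):
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.is_duplicate and not keep_duplicates:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            out.append(AlignedSegment.from_pysam(rec))
    out.sort(key=lambda s: (s.read_id, s.is_supplementary, s.ref_start))
    return out


def group_by_read(segments: Iterable[AlignedSegment]) -> dict[str, list[AlignedSegment]]:
    groups: dict[str, list[AlignedSegment]] = {}
    for seg in segments:
        groups.setdefault(seg.read_id, []).append(seg)
    return groups


def spans_window(segments_of_read: Sequence[AlignedSegment], region) -> bool:
    """True iff the read's segments jointly cover [window_start, window_end].

    For a multi-segment (split) read on one chromosome the covered interval
    is the hull of the segment spans: the deleted interval between flanking
    segments counts as covered by the junction.
    """
    if not segments_of_read:
        return False
    if any(s.ref_name != region.chrom for s in segments_of_read):
        return False
    w_lo = region.window_start - 1  # 0-based half-open
    w_hi = region.window_end
    if len(segments_of_read) == 1:
        s = segments_of_read[0]
        return s.ref_start <= w_lo and s.ref_end >= w_hi
    start = min(s.ref_start for s in segments_of_read)
    end = max(s.ref_end for s in segments_of_read)
    return start <= w_lo and end >= w_hi
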