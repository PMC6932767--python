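"""Reassembly of split/chimeric alignment pairs into junction variants.

A large deletion makes the aligner emit the read as a primary plus a
supplementary record with complementary clips: in one record part of the
read is mapped and the rest clipped, in the other the clipped section is
mapped.  Grouping records by read name and doing clip-length arithmetic on
the query recovers the underlying event: one deletion between the two
reference spans, optionally with bases inserted at the junction (query bases
covered by neither record).  When the two records' query intervals overlap
(junction microhomology) the overlap is assigned to the upstream record and
the junction left-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .alignments import AlignedSegment, group_by_read
from .errors import ChimeraError
from .variants import Variant, call_variants, normalize_variants


@dataclass
class ChimericGroup:
    """All alignment records of one read, ordered by query offset."""

    read_id: str
    segments: list[AlignedSegment]
    error: Optional[str] = None

    @property
    def is_split(self) -> bool:
        return len(self.segments) > 1


@dataclass
class Junction:
    """The reassembled chimera-inducing event between two segments.

    Coordinates are 1-based: ``upstream_ref_end`` is the last reference base
    of the upstream segment, ``downstream_ref_start`` the first of the
    (microhomology-trimmed) downstream segment; the deleted interval is
    ``[upstream_ref_end+1, downstream_ref_start-1]``.
    """

    upstream_ref_end: int
    downstream_ref_start: int
    inserted_seq: str = ""
    microhomology_trim: int = 0
    upstream_segment: AlignedSegment = field(default=None, repr=False)
    downstream_segment: AlignedSegment = field(default=None, repr=False)

    @property
    def deletion_length(self) -> int:
        return self.downstream_ref_start - self.upstream_ref_end - 1


def group_segments(segments: Sequence[AlignedSegment]) -> list[ChimericGroup]:
    """Group records by read name (SA tags are not required) and order each
    group's segments by query start; structurally inconsistent groups
    (mixed chromosome or strand, nested query intervals) are marked ERROR."""
    out = []
    for read_id, segs in sorted(group_by_read(segments).items()):
        group = ChimericGroup(read_id=read_id, segments=segs)
        if len(segs) > 1:
            if len({s.ref_name for s in segs}) > 1:
                group.error = "segments on different chromosomes"
            elif len({s.is_reverse for s in segs}) > 1:
                group.error = "segments on different strands"
            else:
                segs.sort(key=lambda s: (s.query_start, s.ref_start))
                for a, b in zip(segs, segs[1:]):
                    if b.query_start <= a.query_start and b.query_end >= a.query_end:
                        group.error = "nested query intervals"
        out.append(group)
    return out


def _leading_hard_clip(seg: AlignedSegment) -> int:
    n = 0
    for op, ln in seg.cigar:
        if op == "H":
            n += ln
        elif op == "S":
            continue
        else:
            break
    return n


def _read_bases(group: ChimericGroup, start: int, end: int) -> str:
    """Bases of the full read at offsets [start, end); taken from any record
    whose stored sequence covers them (soft clips retain sequence)."""
    for seg in group.segments:
        off = _leading_hard_clip(seg)
        if off <= start and end - off <= len(seg.query_seq):
            return seg.query_seq[start - off : end - off]
    raise ChimeraError(
        f"read {group.read_id}: junction bases [{start},{end}) hard-clipped from every record"
    )


def _trim_leading_query(seg: AlignedSegment, h: int) -> AlignedSegment:
    """Remove the first ``h`` aligned query bases of a segment (convert them
    to soft clip), advancing ref_start past reference bases they consumed and
    dropping any deletion left dangling at the new edge."""
    ops = list(seg.cigar)
    i = 0
    # keep leading clips untouched
    while i < len(ops) and ops[i][0] in "SH":
        i += 1
    ref_adv = 0
    soft_added = 0
    remaining = h
    while remaining > 0:
        if i >= len(ops):
            raise ChimeraError("microhomology overlap exceeds the segment's aligned length")
        op, ln = ops[i]
        if op in "M=X":
            take = min(ln, remaining)
            ref_adv += take
            soft_added += take
            remaining -= take
            if take == ln:
                ops.pop(i)
            else:
                ops[i] = (op, ln - take)
        elif op == "I":
            take = min(ln, remaining)
            soft_added += take
            remaining -= take
            if take == ln:
                ops.pop(i)
            else:
                ops[i] = (op, ln - take)
        elif op == "D":
            ref_adv += ln
            ops.pop(i)
        else:
            raise ChimeraError("cannot trim through clip operations")
    # a deletion at the new alignment edge carries no query evidence: drop it
    while i < len(ops) and ops[i][0] == "D":
        ref_adv += ops[i][1]
        ops.pop(i)
    if not any(op in "M=X" for op, _ in ops):
        raise ChimeraError("microhomology overlap consumed the whole segment")
    if soft_added:
        # trimmed bases stay in the stored sequence, so they become soft clip
        ops.insert(i, ("S", soft_added))
    merged: list[tuple[str, int]] = []
    for op, ln in ops:
        if merged and op in "SH" and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return replace(seg, ref_start=seg.ref_start + ref_adv, cigar=tuple(merged))


def resolve_junction(group: ChimericGroup, reference: str) -> Junction:
    """Deconvolute a two-segment chimera into its junction event."""
    if group.error:
        raise ChimeraError(f"read {group.read_id}: {group.error}")
    if len(group.segments) != 2:
        raise ChimeraError(
            f"read {group.read_id}: {len(group.segments)} segments; only pairs are deconvoluted"
        )
    up, down = group.segments
    overlap = up.query_end - down.query_start
    inserted = ""
    trim = 0
    if overlap > 0:
        trim = overlap
        down = _trim_leading_query(down, overlap)
    elif overlap < 0:
        inserted = _read_bases(group, up.query_end, down.query_start).upper()
    upstream_ref_end = up.ref_end  # 0-based exclusive == 1-based last base
    downstream_ref_start = down.ref_start + 1
    if downstream_ref_start <= upstream_ref_end:
        raise ChimeraError(
            f"read {group.read_id}: segments overlap on the reference after trimming"
        )
    return Junction(
        upstream_ref_end=upstream_ref_end,
        downstream_ref_start=downstream_ref_start,
        inserted_seq=inserted,
        microhomology_trim=trim,
        upstream_segment=up,
        downstream_segment=down,
    )


def merge_chimeric_variants(
    group: ChimericGroup, junction: Junction, reference: str, region
) -> tuple[Variant, ...]:
    """Intra-segment variants plus the junction deletion (and insertion),
    normalized exactly like plain gapped-record calls."""
    for seg in (junction.upstream_segment, junction.downstream_segment):
        if seg.ref_end <= region.region_start - 1 or seg.ref_start >= region.region_end:
            raise ChimeraError(
                f"read {group.read_id}: segment maps outside the configured region"
            )
    out: list[Variant] = []
    out.extend(call_variants(junction.upstream_segment, reference, region))
    out.extend(call_variants(junction.downstream_segment, reference, region))
    s, e = junction.upstream_ref_end + 1, junction.downstream_ref_start - 1
    if e >= s:
        cs, ce = max(s, region.region_start), min(e, region.region_end)
        if ce >= cs:
            out.append(Variant("DEL", cs, ce, reference[cs - 1 : ce].upper(), ""))
    else:
        raise ChimeraError(f"read {group.read_id}: empty junction deletion")
    if junction.inserted_seq:
        p = junction.upstream_ref_end
        if region.region_start <= p <= region.region_end - 1:
            out.append(Variant("INS", p, p, "", junction.inserted_seq))
    return normalize_variants(out, reference, region)


def call_read(
    group: ChimericGroup, reference: str, region
) -> tuple[Variant, ...]:
    """Variant set for one read group: plain CIGAR walk for singletons,
    junction reassembly for split pairs.  Raises :class:`ChimeraError` for
    groups outside the two-segment single-deletion model."""
    if group.error:
        raise ChimeraError(f"read {group.read_id}: {group.error}")
    if not group.is_split:
        return normalize_variants(
            call_variants(group.segments[0], reference, region), reference, region
        )
    junction = resolve_junction(group, reference)
    return merge_chimeric_variants(group, junction, reference, region)
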