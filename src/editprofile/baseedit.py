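"""Per-position base-editing quantification over the analysis window.

Base-editor outcomes are quantified at the level of individual base
conversions rather than whole alleles, because bystander bases neighboring
the on-target position may also be edited; an allele-level tally would
conflate the two.  Counts feed conversion-rate estimates and the sequence
logo position-frequency matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignments import AlignedSegment
from .chimera import ChimericGroup, resolve_junction
from .config import GeneRegion, revcomp
from .errors import ChimeraError, ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

BASE_COLUMNS = ("A", "C", "G", "T", "N", "del")


@dataclass
class BaseCountMatrix:
    """Nucleotide counts per window position (forward reference strand).

    ``table`` is indexed by 1-based reference position with columns
    A/C/G/T/N/del plus ``ref`` and ``depth``; per position the base counts
    sum to depth, and depth never exceeds the analyzable read count.
    """

    table: pd.DataFrame

    @property
    def positions(self) -> list[int]:
        return list(self.table.index)

    def ref_base(self, position: int) -> str:
        return self.table.at[position, "ref"]

    def depth(self, position: int) -> int:
        return int(self.table.at[position, "depth"])

    def count(self, position: int, base: str) -> int:
        return int(self.table.at[position, base])


def _segment_window_events(seg: AlignedSegment, w_lo: int, w_hi: int):
    """Yield (1-based position, base-or-'del') for window positions covered."""
    ref_pos = seg.ref_start
    qpos = 0
    seq = seg.query_seq
    for op, ln in seg.cigar:
        if op in "M=X":
            for i in range(ln):
                p = ref_pos + i + 1
                if w_lo <= p <= w_hi:
                    yield p, seq[qpos + i].upper()
            ref_pos += ln
            qpos += ln
        elif op in "DN":
            for i in range(ln):
                p = ref_pos + i + 1
                if w_lo <= p <= w_hi:
                    yield p, "del"
            ref_pos += ln
        elif op == "I" or op == "S":
            qpos += ln
        # H/P consume nothing


def count_bases(
    reads: Sequence[ChimericGroup | AlignedSegment],
    region: GeneRegion,
    reference: str,
) -> BaseCountMatrix:
    """Tally the base each analyzable read aligns to every window position.

    M runs contribute the read base, D runs (and the deleted interval of a
    resolved chimeric junction) contribute ``del``; insertions consume no
    reference position and contribute nothing.  Unresolvable split groups
    are skipped.  Counting is allele-agnostic: only per-read aligned bases
    matter, never the allele grouping.
    """
    if not reads:
        raise EmptyInputError("no reads to count")
    w_lo, w_hi = region.window_start, region.window_end
    positions = list(range(w_lo, w_hi + 1))
    idx = {p: i for i, p in enumerate(positions)}
    counts = np.zeros((len(positions), len(BASE_COLUMNS)), dtype=np.int64)
    col = {b: j for j, b in enumerate(BASE_COLUMNS)}
    for item in reads:
        if isinstance(item, AlignedSegment):
            group = ChimericGroup(read_id=item.read_id, segments=[item])
        else:
            group = item
        events: dict[int, str] = {}
        try:
            if group.is_split:
                junction = resolve_junction(group, reference)
                segs = [junction.upstream_segment, junction.downstream_segment]
                for p in range(junction.upstream_ref_end + 1, junction.downstream_ref_start):
                    if w_lo <= p <= w_hi:
                        events[p] = "del"
            else:
                segs = group.segments
        except ChimeraError:
            continue
        for seg in segs:
            for p, b in _segment_window_events(seg, w_lo, w_hi):
                events.setdefault(p, b)
        for p, b in events.items():
            if b not in col:
                b = "N"
            counts[idx[p], col[b]] += 1
    table = pd.DataFrame(counts, index=pd.Index(positions, name="position"), columns=list(BASE_COLUMNS))
    table.insert(0, "ref", [reference[p - 1].upper() for p in positions])
    table["depth"] = counts.sum(axis=1)
    return BaseCountMatrix(table)


def conversion_rate(
    matrix: BaseCountMatrix, position: int, from_base: str, to_base: str
) -> float:
    """Fraction of reads carrying ``to_base`` at ``position`` among reads with
    evidence there (N excluded from the denominator, deletions included)."""
    if position not in matrix.table.index:
        raise ConfigurationError(f"position {position} outside the analysis window")
    if matrix.ref_base(position) != from_base.upper():
        raise ConfigurationError(
            f"reference base at {position} is {matrix.ref_base(position)}, not {from_base}"
        )
    denom = matrix.depth(position) - matrix.count(position, "N")
    if denom == 0:
        return 0.0
    return matrix.count(position, to_base.upper()) / denom


def conversion_table(matrix: BaseCountMatrix) -> pd.DataFrame:
    """Per-position rates of every substitution away from the reference base."""
    rows = []
    for p in matrix.positions:
        ref = matrix.ref_base(p)
        denom = matrix.depth(p) - matrix.count(p, "N")
        for b in "ACGT":
            if b == ref:
                continue
            rows.append(
                {
                    "position": p,
                    "from": ref,
                    "to": b,
                    "rate": matrix.count(p, b) / denom if denom else 0.0,
                }
            )
    return pd.DataFrame(rows)


def logo_matrix(matrix: BaseCountMatrix, region: Optional[GeneRegion] = None) -> pd.DataFrame:
    """Position-frequency matrix over A/C/G/T (N and del excluded), columns
    summing to 1; zero-depth positions are dropped with a warning.  When a
    minus-strand region is given, positions are complemented and re-ordered
    so columns follow the coding strand."""
    rows = {}
    for p in matrix.positions:
        acgt = np.array([matrix.count(p, b) for b in "ACGT"], dtype=float)
        total = acgt.sum()
        if total == 0:
            logger.warning("position %d has zero A/C/G/T depth; dropped from logo", p)
            continue
        rows[p] = acgt / total
    pfm = pd.DataFrame(rows, index=list("ACGT")).T
    pfm.index.name = "position"
    if region is not None and region.strand == "-":
        pfm = pfm.iloc[::-1]
        pfm.columns = [revcomp(b) for b in pfm.columns]
        pfm = pfm[list("ACGT")]
    return pfm
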