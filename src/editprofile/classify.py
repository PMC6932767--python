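"""Read/allele classification into WT, NHEJ, HDR and HDR-NHEJ.

HDR is a *perfect* match to the donor-template variant set.  A read carrying
the full template plus any extra variant is HDR-NHEJ — reported separately
from HDR end to end, because only pure-HDR events measure the efficiency of
a knock-in protocol.  Every other non-empty variant set (including partial
template matches) is NHEJ.  Reads the algorithm could not resolve (e.g.
three-segment chimeras) stay in the analyzable denominator as ERROR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import EmptyInputError
from .variants import Variant, sort_variants

WT = "WT"
NHEJ = "NHEJ"
HDR = "HDR"
HDR_NHEJ = "HDR-NHEJ"
ERROR = "ERROR"

CLASS_ORDER = (WT, NHEJ, HDR, HDR_NHEJ, ERROR)


def classify_read(
    variants: Sequence[Variant], template: Optional[Sequence[Variant]] = None
) -> str:
    """Class label for one read's canonical variant set.

    Reads with N bases at template positions have no SNP call there (N is
    absence of evidence), so an otherwise perfect template match still
    classifies as HDR.
    """
    vs = set(sort_variants(variants))
    if not vs:
        return WT
    if template:
        t = set(sort_variants(template))
        if vs == t:
            return HDR
        if vs > t:
            return HDR_NHEJ
    return NHEJ


@dataclass
class ClassSummary:
    """Counts and proportions per class over the analyzable reads."""

    counts: dict[str, int]
    denominator: int

    @property
    def proportions(self) -> dict[str, float]:
        d = self.denominator or 1
        return {k: v / d for k, v in self.counts.items()}

    def as_rows(self) -> list[dict]:
        d = self.denominator or 1
        return [
            {"class": k, "count": self.counts.get(k, 0), "proportion": self.counts.get(k, 0) / d}
            for k in CLASS_ORDER
        ]


def summarize_classes(labels: Sequence[str]) -> ClassSummary:
    """Tally class labels; raises :class:`EmptyInputError` with no reads."""
    if not labels:
        raise EmptyInputError("no analyzable reads to summarize")
    counts = {k: 0 for k in CLASS_ORDER}
    for lab in labels:
        if lab not in counts:
            raise ValueError(f"unknown class label {lab!r}")
        counts[lab] += 1
    return ClassSummary(counts=counts, denominator=len(labels))
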