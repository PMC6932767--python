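"""In-silico editing experiments with exact per-read truth.

Generates synthetic reference fragments with a valid single-exon gene model,
edited amplicon reads drawn from a WT/NHEJ/HDR/HDR-NHEJ mixture (or a
deterministic event grid), and ready-made alignment records — either one
gapped record per read (exact M/I/D CIGAR) or, for reads carrying a large
deletion, a split primary/supplementary pair with complementary clips, the
representation a real aligner produces for chimeric reads.  Every read's
variant set and class are known by construction and written to a truth
table, so profiler output can be checked exactly.

The grid designs mirror the validation experiments the method was built
for: deletions of every size from 5 to 120 bases emitted as chimeric reads,
and a 120-base deletion with 1–120 scrambled bases inserted at the junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .classify import classify_read
from .config import GeneRegion, STOP_CODONS, revcomp
from .errors import ConfigurationError
from .impact import apply_variants
from .variants import Variant, name_allele, normalize_variants, sort_variants

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_NONSTOP = [c for c in _CODONS if c not in STOP_CODONS and c != "ATG"]


def make_reference(
    length: int = 500,
    seed: int = 0,
    cds: Optional[tuple[int, int]] = None,
    strand: str = "+",
    scrub_orfs: bool = True,
) -> str:
    """Random DNA fragment; when ``cds=(start, end)`` is given, a clean open
    reading frame (ATG, non-stop codons, terminal stop) is planted there on
    the requested strand.

    With ``scrub_orfs`` (default) every coding-strand ATG other than the
    planted start codon is mutated away, so the unedited fragment carries no
    background cryptic ORF and the CRYPTIC impact flag reflects only what an
    edit creates.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    if cds is None:
        return "".join(seq)
    s, e = cds
    if not (1 <= s < e <= length) or (e - s + 1) % 3 != 0:
        raise ConfigurationError("CDS bounds must be in range with length a multiple of 3")
    n_codons = (e - s + 1) // 3
    codons = ["ATG"] + [
        _NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), size=n_codons - 2)
    ] + [("TAA", "TAG", "TGA")[rng.integers(0, 3)]]
    cds_seq = "".join(codons)
    seq[s - 1 : e] = list(revcomp(cds_seq) if strand == "-" else cds_seq)
    if scrub_orfs:
        coding = list(revcomp("".join(seq))) if strand == "-" else seq
        cs = (length - e) if strand == "-" else (s - 1)  # 0-based start-codon index
        ce = cs + (e - s + 1) - 1
        _scrub_atg(coding, cs, ce, rng)
        seq = list(revcomp("".join(coding))) if strand == "-" else coding
    return "".join(seq)


def _scrub_atg(coding: list[str], cs: int, ce: int, rng: np.random.Generator) -> None:
    """Mutate away every coding-strand ATG except the start codon at ``cs``,
    preserving the CDS [cs, ce] (no new stop, no new ATG at codon boundaries,
    start/stop triplets untouched)."""
    protected = set(range(cs, cs + 3)) | set(range(ce - 2, ce + 1))
    breakers = {0: "A", 1: "T", 2: "G"}  # offset -> base that must change

    def creates_atg(p: int) -> bool:
        return any(
            "".join(coding[k : k + 3]) == "ATG" for k in range(max(0, p - 2), p + 1)
        )

    guard = 0
    while guard < 10000:
        guard += 1
        text = "".join(coding)
        j = text.find("ATG")
        while j == cs:
            j = text.find("ATG", j + 1)
        if j == -1:
            return
        fixed = False
        for off in (2, 1, 0):
            p = j + off
            if p in protected or p >= len(coding):
                continue
            for c in rng.permutation(list("ACGT")):
                if c == coding[p] or c == breakers[off]:
                    continue
                old = coding[p]
                coding[p] = c
                if cs <= p <= ce:
                    k = cs + 3 * ((p - cs) // 3)
                    codon = "".join(coding[k : k + 3])
                    if codon in STOP_CODONS or codon == "ATG":
                        coding[p] = old
                        continue
                if creates_atg(p):
                    coding[p] = old
                    continue
                fixed = True
                break
            if fixed:
                break
        if not fixed:  # pragma: no cover - all three positions protected
            raise ConfigurationError("cannot scrub an ATG overlapping protected codons")


@dataclass
class SimRead:
    """One simulated read spanning the whole region, with its truth."""

    read_id: str
    variants: tuple[Variant, ...]
    class_label: str


@dataclass
class EventMenu:
    """Distribution of NHEJ repair outcomes around the cut site."""

    small_del_sizes: tuple[int, ...] = tuple(range(1, 11))
    small_ins_sizes: tuple[int, ...] = tuple(range(1, 7))
    large_del_sizes: tuple[int, ...] = tuple(range(30, 121, 10))
    junction_ins_sizes: tuple[int, ...] = (0, 0, 3, 7)
    kind_weights: tuple[float, ...] = (0.45, 0.2, 0.25, 0.1)  # small_del, small_ins, large_del, snp


@dataclass
class SimSpec:
    """Conditions of one simulated experiment."""

    region: GeneRegion
    reference: str
    n_reads: int = 1000
    class_weights: dict = field(
        default_factory=lambda: {"WT": 0.6, "NHEJ": 0.25, "HDR": 0.1, "HDR-NHEJ": 0.05}
    )
    menu: EventMenu = field(default_factory=EventMenu)
    base_edit_probs: Optional[dict[int, tuple[str, str, float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("class mixture weights must sum to 1")


def _nhej_event(rng: np.random.Generator, region: GeneRegion, menu: EventMenu, reference: str) -> tuple[Variant, ...]:
    cut = region.cut_sites[0]
    kind = rng.choice(4, p=np.asarray(menu.kind_weights) / sum(menu.kind_weights))
    if kind == 0:
        d = int(rng.choice(menu.small_del_sizes))
        s = cut - d // 2
        vs: list[Variant] = [Variant("DEL", s, s + d - 1, reference[s - 1 : s + d - 1], "")]
    elif kind == 1:
        k = int(rng.choice(menu.small_ins_sizes))
        ins = "".join(rng.choice(list("ACGT"), size=k))
        vs = [Variant("INS", cut, cut, "", ins)]
    elif kind == 2:
        d = int(rng.choice(menu.large_del_sizes))
        s = cut - d // 2
        vs = [Variant("DEL", s, s + d - 1, reference[s - 1 : s + d - 1], "")]
        k = int(rng.choice(menu.junction_ins_sizes))
        if k:
            vs.append(Variant("INS", s - 1, s - 1, "", "".join(rng.choice(list("ACGT"), size=k))))
    else:
        p = cut + int(rng.integers(-5, 6))
        ref_b = reference[p - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref_b])
        vs = [Variant("SNP", p, p, ref_b, alt)]
    for v in vs:
        if v.start < region.region_start or v.end > region.region_end:
            raise ConfigurationError(f"simulated event {v} exceeds the region")
    return tuple(vs)


def _hdr_extra(region: GeneRegion, reference: str) -> Variant:
    """A small deletion that never collides with the template (for HDR-NHEJ)."""
    template = region.hdr_template or ()
    occupied = {p for v in template for p in range(v.start - 1, v.end + 2)}
    cut = region.cut_sites[0]
    for off in range(5, region.region_end - cut - 3):
        s = cut + off
        if all(p not in occupied for p in (s - 1, s, s + 1, s + 2, s + 3, s + 4)):
            return Variant("DEL", s, s + 2, reference[s - 1 : s + 2], "")
    raise ConfigurationError("no room for an HDR-NHEJ extra deletion")


def simulate_reads(spec: SimSpec) -> list[SimRead]:
    """Draw reads from the class mixture (or per-position base-edit model);
    deterministic under the spec seed, exact truth per read."""
    rng = np.random.default_rng(spec.seed)
    region, reference = spec.region, spec.reference
    reads: list[SimRead] = []
    template = region.hdr_template
    if spec.base_edit_probs is not None:
        for pos, (frm, _to, _p) in spec.base_edit_probs.items():
            if reference[pos - 1].upper() != frm.upper():
                raise ConfigurationError(f"reference base at {pos} is not {frm}")
        for i in range(spec.n_reads):
            vs = []
            for pos, (frm, to, p_conv) in sorted(spec.base_edit_probs.items()):
                if rng.random() < p_conv:
                    vs.append(Variant("SNP", pos, pos, frm.upper(), to.upper()))
            vs = normalize_variants(vs, reference, region)
            reads.append(SimRead(f"read{i:06d}", vs, classify_read(vs, template)))
        return reads
    labels = list(spec.class_weights)
    probs = np.asarray([spec.class_weights[k] for k in labels], dtype=float)
    # exact per-class construction: deterministic counts, not multinomial noise
    counts = np.floor(probs * spec.n_reads).astype(int)
    for k in np.argsort(-(probs * spec.n_reads - counts))[: spec.n_reads - counts.sum()]:
        counts[k] += 1
    i = 0
    for label, n in zip(labels, counts):
        for _ in range(n):
            if label == "WT":
                vs: tuple[Variant, ...] = ()
            elif label == "NHEJ":
                vs = _nhej_event(rng, region, spec.menu, reference)
            elif label == "HDR":
                if not template:
                    raise ConfigurationError("HDR reads require an HDR template on the region")
                vs = tuple(template)
            elif label == "HDR-NHEJ":
                vs = tuple(template) + (_hdr_extra(region, reference),)
            else:
                raise ConfigurationError(f"unknown class {label!r}")
            vs = normalize_variants(vs, reference, region)
            reads.append(SimRead(f"read{i:06d}", vs, classify_read(vs, template)))
            i += 1
    return reads


def cryptic_start_analog(seed: int = 0):
    """Synthetic analog of the classic two-guide knockout allele in which a
    large deletion removes the annotated start codon and exposes a cryptic
    ATG one base downstream of it on the mutant molecule.

    The fragment carries a CDS at region-relative 1..330 and the allele is a
    deletion of bases 2..183: base 1 (the A of the start codon) survives, the
    T and G are deleted, and the first bases brought in by the junction are a
    cryptic ATG at an internal codon boundary, so the residual C-terminal
    portion of the protein reads through to the original stop codon (a
    49-codon cryptic ORF).  Returns ``(reference, region, deletion_variant)``.
    """
    length = 400
    seq = list(make_reference(length, seed=seed, cds=(1, 330)))
    # cryptic ATG at 184..186: an in-frame internal codon of the CDS, so the
    # reference gene model stays valid and the cryptic frame ends at the
    # annotated stop codon
    seq[183:186] = list("ATG")
    # pin the deletion placement: base 183 must differ from base 1 ('A') so
    # the 2..183 deletion cannot left-align to 1..182
    if seq[182] == "A":
        for c in "CGT":
            seq[182] = c
            codon = "".join(seq[180:183])
            if codon not in STOP_CODONS and codon != "ATG":
                break
    reference = "".join(seq)
    region = GeneRegion(
        name="id_analog",
        chrom="frag",
        region_start=1,
        region_end=length,
        strand="+",
        cut_sites=(92, 277),
        window_start=1,
        window_end=length,
        cds_start=1,
        cds_end=330,
    )
    region.validate(reference)
    deletion = Variant("DEL", 2, 183, reference[1:183], "")
    return reference, region, deletion


# ---------------------------------------------------------------------------
# deterministic event grids

def deletion_sweep(
    region: GeneRegion,
    reference: str,
    sizes: Sequence[int] = range(5, 121),
    reads_per_event: int = 50,
) -> list[SimRead]:
    """One deletion of each size centered on the cut site."""
    reads = []
    cut = region.cut_sites[0]
    for d in sizes:
        s = cut - d // 2
        if s < region.region_start or s + d - 1 > region.region_end:
            raise ConfigurationError(f"deletion of {d} bp exceeds the region")
        v = Variant("DEL", s, s + d - 1, reference[s - 1 : s + d - 1], "")
        vs = normalize_variants([v], reference, region)
        for r in range(reads_per_event):
            reads.append(SimRead(f"del{d:03d}_{r:03d}", vs, classify_read(vs)))
    return reads


def insertion_sweep(
    region: GeneRegion,
    reference: str,
    del_size: int = 120,
    ins_sizes: Sequence[int] = range(1, 121),
    reads_per_event: int = 50,
    seed: int = 0,
) -> list[SimRead]:
    """A fixed large deletion with scrambled bases of each size inserted at
    the deletion site (drawn uniformly over A/C/G/T under the seed)."""
    rng = np.random.default_rng(seed)
    reads = []
    cut = region.cut_sites[0]
    s = cut - del_size // 2
    dele = Variant("DEL", s, s + del_size - 1, reference[s - 1 : s + del_size - 1], "")
    for k in ins_sizes:
        ins = Variant("INS", s - 1, s - 1, "", "".join(rng.choice(list("ACGT"), size=k)))
        vs = normalize_variants([dele, ins], reference, region)
        for r in range(reads_per_event):
            reads.append(SimRead(f"ins{k:03d}_{r:03d}", vs, classify_read(vs)))
    return reads


# ---------------------------------------------------------------------------
# emission

def _read_ops(read: SimRead, region: GeneRegion) -> tuple[list[tuple[str, int]], str]:
    """Exact CIGAR (absolute walk over the region span) and query sequence."""
    ops: list[tuple[str, int]] = []

    def add(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + ln)
        else:
            ops.append((op, ln))

    cur = region.region_start
    for v in sort_variants(read.variants):
        if v.kind == "SNP":
            continue
        if v.kind == "INS":
            add("M", v.start - cur + 1)
            cur = v.start + 1
            add("I", len(v.alt_bases))
        else:
            add("M", v.start - cur)
            add("D", v.end - v.start + 1)
            cur = v.end + 1
    add("M", region.region_end - cur + 1)
    return ops, None  # query filled by caller


def _query_sequence(read: SimRead, region: GeneRegion, reference: str) -> str:
    return apply_variants(region.region_sequence(reference), read.variants, region).sequence


def emit_alignments(
    reads: Sequence[SimRead],
    region: GeneRegion,
    reference: str,
    path: str | Path,
    mode: str = "gapped",
    split_threshold: int = 30,
    hard_clip: bool = False,
    error_rate: float = 0.0,
    seed: int = 0,
) -> str:
    """Write a coordinate-sorted, indexed BAM (or plain SAM when ``path``
    ends in ``.sam``).

    ``mode="gapped"`` writes one record per read with the exact M/I/D CIGAR.
    ``mode="split"`` re-encodes every read whose truth contains a deletion of
    at least ``split_threshold`` bases the way an aligner reports a chimeric
    read: a primary record mapping the upstream part (downstream soft-
    clipped) plus a supplementary record (flag 0x800) mapping the downstream
    part, with soft or hard clips per ``hard_clip``; bases inserted at the
    junction appear only inside the clips.
    """
    if mode not in ("gapped", "split"):
        raise ConfigurationError(f"unknown emission mode {mode!r}")
    path = Path(path)
    rng = np.random.default_rng(seed)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": region.chrom, "LN": len(reference)}],
    }
    records = []
    for read in reads:
        ops, _ = _read_ops(read, region)
        seq = _query_sequence(read, region, reference)
        if error_rate > 0:
            chars = list(seq)
            for i in range(len(chars)):
                if rng.random() < error_rate:
                    chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
            seq = "".join(chars)
        records.extend(
            _encode_read(read, ops, seq, region, mode, split_threshold, hard_clip)
        )
    records.sort(key=lambda r: (r["pos"], r["name"], r["flag"]))
    out_sam = path.suffix == ".sam"
    tmp = path.with_suffix(".unsorted.bam") if not out_sam else path
    with pysam.AlignmentFile(str(tmp), "w" if out_sam else "wb", header=header) as fh:
        for r in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r["name"]
            a.flag = r["flag"]
            a.reference_id = 0
            a.reference_start = r["pos"]
            a.mapping_quality = 60
            a.cigarstring = r["cigar"]
            a.query_sequence = r["seq"]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r["seq"]))
            fh.write(a)
    if not out_sam:
        pysam.sort("-o", str(path), str(tmp))
        tmp.unlink()
        pysam.index(str(path))
    return str(path)


def _encode_read(
    read: SimRead,
    ops: list[tuple[str, int]],
    seq: str,
    region: GeneRegion,
    mode: str,
    split_threshold: int,
    hard_clip: bool,
) -> list[dict]:
    pos0 = region.region_start - 1
    gapped = [
        {
            "name": read.read_id,
            "flag": 0,
            "pos": pos0,
            "cigar": "".join(f"{ln}{op}" for op, ln in ops),
            "seq": seq,
        }
    ]
    if mode == "gapped":
        return gapped
    dels = [
        (i, ln) for i, (op, ln) in enumerate(ops) if op == "D" and ln >= split_threshold
    ]
    if not dels:
        return gapped
    split_i, _ = max(dels, key=lambda t: t[1])
    up_ops = ops[:split_i]
    down_ops = ops[split_i + 1 :]
    junction_ins = 0
    if up_ops and up_ops[-1][0] == "I":  # junction insertion lives in the clips
        junction_ins = up_ops[-1][1]
        up_ops = up_ops[:-1]
    qlen = lambda o: sum(ln for op, ln in o if op in "MI=X")
    qu, qd = qlen(up_ops), qlen(down_ops)
    total = len(seq)
    assert qu + junction_ins + qd == total
    del_len = ops[split_i][1]
    down_pos = pos0 + sum(ln for op, ln in up_ops if op in "MD=X") + del_len
    primary = {
        "name": read.read_id,
        "flag": 0,
        "pos": pos0,
        "cigar": "".join(f"{ln}{op}" for op, ln in up_ops) + f"{total - qu}S",
        "seq": seq,
    }
    clip_op = "H" if hard_clip else "S"
    supp = {
        "name": read.read_id,
        "flag": 0x800,
        "pos": down_pos,
        "cigar": f"{total - qd}{clip_op}" + "".join(f"{ln}{op}" for op, ln in down_ops),
        "seq": seq[qu + junction_ins :] if hard_clip else seq,
    }
    return [primary, supp]


def emit_fastq(reads: Sequence[SimRead], region: GeneRegion, reference: str, path: str | Path) -> str:
    """Plain FASTQ with uniform qualities; read names match the truth table."""
    path = Path(path)
    with open(path, "w") as fh:
        for read in reads:
            seq = _query_sequence(read, region, reference)
            fh.write(f"@{read.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    return str(path)


def write_truth(reads: Sequence[SimRead], region: GeneRegion, path: str | Path) -> str:
    """Truth CSV: read_id, canonical allele name, class."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "allele": [name_allele(r.variants, region) for r in reads],
            "class": [r.class_label for r in reads],
        }
    )
    df.to_csv(path, index=False)
    return str(path)


def write_reference_fasta(reference: str, chrom: str, path: str | Path) -> str:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(reference), 70):
            fh.write(reference[i : i + 70] + "\n")
    return str(path)
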