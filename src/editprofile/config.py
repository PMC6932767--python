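"""Run configuration: reference FASTA, gene/region table, sample discovery.

Coordinates in configuration files and all user-facing output are 1-based
inclusive; rows may be written high-to-low (minus-strand loci are often
listed that way) and are normalized so ``region_start <= region_end``.
Internally the package converts to 0-based half-open only at alignment I/O
boundaries.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import (
    ConfigurationError,
    FormatError,
    GeneModelError,
    ReferenceLookupError,
    RegionBoundsError,
)
from .variants import Variant, parse_allele_name, sort_variants

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
_DNA_RE = re.compile(r"^[ACGTN]+$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneRegion:
    """One profiled locus on forward reference coordinates (1-based inclusive).

    ``strand`` is consulted only for translation and display; ``cut_sites``
    must lie inside the analysis window ``[window_start, window_end]``, the
    sub-interval a read must fully span to be analyzable.
    """

    name: str
    chrom: str
    region_start: int
    region_end: int
    strand: str = "+"
    cut_sites: tuple[int, ...] = ()
    window_start: int = 0
    window_end: int = 0
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    hdr_template: Optional[tuple[Variant, ...]] = None
    base_edit: bool = False

    def __post_init__(self) -> None:
        if self.region_start > self.region_end:
            self.region_start, self.region_end = self.region_end, self.region_start
        if self.cds_start is not None and self.cds_end is not None and self.cds_start > self.cds_end:
            self.cds_start, self.cds_end = self.cds_end, self.cds_start
        if self.window_start > self.window_end:
            self.window_start, self.window_end = self.window_end, self.window_start
        if not self.window_start:
            self.window_start, self.window_end = self.region_start, self.region_end
        self.cut_sites = tuple(self.cut_sites)
        if self.strand not in "+-":
            raise GeneModelError(f"{self.name}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.region_end - self.region_start + 1

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    def rel(self, pos: int) -> int:
        """Absolute 1-based position -> region-relative 1-based position."""
        return pos - self.region_start + 1

    def validate(self, reference: Optional[str] = None) -> None:
        """Check window/cut-site invariants and (given a reference) the CDS model."""
        if not (self.region_start <= self.window_start <= self.window_end <= self.region_end):
            raise GeneModelError(f"{self.name}: window outside region bounds")
        for c in self.cut_sites:
            if not (self.window_start <= c <= self.window_end):
                raise GeneModelError(f"{self.name}: cut site {c} outside analysis window")
        if not self.cut_sites:
            raise GeneModelError(f"{self.name}: at least one cut site is required")
        if reference is not None:
            if self.region_end > len(reference) or self.region_start < 1:
                raise RegionBoundsError(
                    f"{self.name}: region exceeds reference of length {len(reference)}"
                )
            if self.has_cds:
                self._validate_cds(reference)

    def _validate_cds(self, reference: str) -> None:
        cs, ce = self.cds_start, self.cds_end
        if not (self.region_start <= cs < ce <= self.region_end):
            raise GeneModelError(f"{self.name}: CDS outside region bounds")
        cds = reference[cs - 1 : ce].upper()
        if len(cds) % 3 != 0:
            raise GeneModelError(f"{self.name}: CDS length {len(cds)} not a multiple of 3")
        if self.strand == "-":
            cds = revcomp(cds)
        if cds[:3] != "ATG":
            raise GeneModelError(f"{self.name}: CDS does not begin with a start codon on {self.strand}")
        if cds[-3:] not in STOP_CODONS:
            raise GeneModelError(f"{self.name}: CDS does not end with a stop codon on {self.strand}")

    def region_sequence(self, reference: str) -> str:
        return reference[self.region_start - 1 : self.region_end].upper()


@dataclass
class Sample:
    """One sequenced sample: a directory name and its alignment/read files."""

    name: str
    files: tuple[str, ...]

    @property
    def bam_path(self) -> str:
        return self.files[0]


@dataclass
class RunConfig:
    """Batch run settings mirroring the setup parameters of the profiler.

    ``cutoff`` is the minimum percentage occurrence required for an allele to
    be reported; ``ignore_snp``/``ignore_single`` drop SNPs / singleton
    alleles from reports.  ``small_indel_max`` separates the SM and LG impact
    flags; ``min_cryptic_codons`` is the minimum cryptic-ORF length in codons
    (stop included).
    """

    samples: tuple[Sample, ...] = ()
    genes: tuple[GeneRegion, ...] = ()
    index_path: str = ""
    cutoff: float = 0.0
    ignore_snp: bool = False
    ignore_single: bool = False
    small_indel_max: int = 25
    min_cryptic_codons: int = 25
    min_mapq: int = 0
    keep_duplicates: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.cutoff <= 100.0):
            raise ConfigurationError("cutoff must be in [0, 100]")
        if self.small_indel_max < 1:
            raise ConfigurationError("small_indel_max must be >= 1")
        if self.min_cryptic_codons < 1:
            raise ConfigurationError("min_cryptic_codons must be >= 1")


# ---------------------------------------------------------------------------
# loaders

REQUIRED_GENE_COLUMNS = ("name", "chrom", "start", "end", "strand", "cut_sites", "window_start", "window_end")
OPTIONAL_GENE_COLUMNS = ("cds_start", "cds_end", "hdr_template", "base_edit")


def load_reference(path: str | Path, chrom: str) -> str:
    """Return the uppercase sequence of one FASTA record."""
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id == chrom:
            seq = str(rec.seq).upper()
            if not _DNA_RE.match(seq):
                raise FormatError(f"{chrom}: non-ACGTN characters in reference")
            return seq
    raise ReferenceLookupError(f"record {chrom!r} not found in {path}")


def _parse_template(value: str, region: GeneRegion, reference: Optional[str]) -> tuple[Variant, ...]:
    """HDR template: either a full-region sequence (diffed base-by-base
    against the reference) or a ';'-joined list of canonical variant names."""
    value = value.strip()
    if _DNA_RE.match(value.upper()) and not _NAMELIKE_RE.search(value):
        if reference is None:
            raise ConfigurationError(f"{region.name}: sequence template requires the reference")
        ref_seq = region.region_sequence(reference)
        if len(value) != len(ref_seq):
            raise ConfigurationError(
                f"{region.name}: HDR template length {len(value)} != region length {len(ref_seq)}"
            )
        diffs = [
            Variant("SNP", region.region_start + i, region.region_start + i, r, a)
            for i, (r, a) in enumerate(zip(ref_seq, value.upper()))
            if r != a
        ]
        if not diffs:
            raise ConfigurationError(f"{region.name}: HDR template is identical to the reference")
        return sort_variants(diffs)
    return parse_allele_name(value, region, reference)


_NAMELIKE_RE = re.compile(r"\d")


def load_gene_table(path: str | Path, reference_path: Optional[str | Path] = None) -> list[GeneRegion]:
    """Load the gene/region CSV (plain CSV with a header; multiple cut sites
    as a ';'-separated list in one cell), normalize coordinates, and validate
    every region against the reference when one is supplied."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"gene table {path} does not exist")
    df = pd.read_csv(path, dtype=str)
    for col in REQUIRED_GENE_COLUMNS:
        if col not in df.columns:
            raise ConfigurationError(f"gene table missing required column {col!r}")
    regions: list[GeneRegion] = []
    for _, row in df.iterrows():
        def get(col):
            if col in df.columns and pd.notna(row[col]) and str(row[col]).strip() != "":
                return str(row[col]).strip()
            return None

        region = GeneRegion(
            name=get("name"),
            chrom=get("chrom"),
            region_start=int(get("start")),
            region_end=int(get("end")),
            strand=get("strand"),
            cut_sites=tuple(int(x) for x in get("cut_sites").split(";")),
            window_start=int(get("window_start")),
            window_end=int(get("window_end")),
            cds_start=int(get("cds_start")) if get("cds_start") else None,
            cds_end=int(get("cds_end")) if get("cds_end") else None,
            base_edit=(get("base_edit") or "").lower() in ("1", "true", "yes"),
        )
        reference = None
        if reference_path is not None:
            reference = load_reference(reference_path, region.chrom)
        template = get("hdr_template")
        if template:
            region.hdr_template = _parse_template(template, region, reference)
        region.validate(reference)
        regions.append(region)
    return regions


def write_gene_table(regions: Sequence[GeneRegion], path: str | Path) -> None:
    """Inverse of :func:`load_gene_table` (templates re-encoded as variant names)."""
    from .variants import name_allele

    rows = []
    for r in regions:
        rows.append(
            {
                "name": r.name,
                "chrom": r.chrom,
                "start": r.region_start,
                "end": r.region_end,
                "strand": r.strand,
                "cut_sites": ";".join(str(c) for c in r.cut_sites),
                "window_start": r.window_start,
                "window_end": r.window_end,
                "cds_start": r.cds_start if r.cds_start is not None else "",
                "cds_end": r.cds_end if r.cds_end is not None else "",
                "hdr_template": name_allele(r.hdr_template, r) if r.hdr_template else "",
                "base_edit": int(r.base_edit),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def discover_samples(root: str | Path, type: str = "bam") -> list[Sample]:
    """Enumerate per-sample subdirectories under ``<root>/files/input/``
    (or ``root`` itself when it already is the input directory); one sample
    per subdirectory holding at least one file of the requested type."""
    root = Path(root)
    base = root / "files" / "input"
    if not base.is_dir():
        base = root
    if not base.is_dir():
        raise IOError(f"sample root {root} does not exist")
    ext = {"bam": (".bam", ".sam"), "fastq": (".fastq", ".fq", ".fastq.gz", ".fq.gz")}[type]
    samples = []
    for sub in sorted(p for p in base.iterdir() if p.is_dir()):
        files = sorted(
            str(f) for f in sub.iterdir() if f.name.endswith(ext) and not f.name.endswith(".bai")
        )
        if not files:
            logger.warning("sample directory %s contains no %s files; skipped", sub, type)
            continue
        samples.append(Sample(name=sub.name, files=tuple(files)))
    return samples


def load_run_config(path: str | Path) -> RunConfig:
    """Load a JSON run-config file (keys: samples_root, genes, index, cutoff,
    ignore_snp, ignore_single, small_indel_max, min_cryptic_codons,
    min_mapq, keep_duplicates)."""
    with open(path) as fh:
        raw = json.load(fh)
    index = raw.get("index", "")
    genes = tuple(load_gene_table(raw["genes"], index or None)) if "genes" in raw else ()
    samples = tuple(discover_samples(raw["samples_root"], "bam")) if "samples_root" in raw else ()
    return RunConfig(
        samples=samples,
        genes=genes,
        index_path=index,
        cutoff=float(raw.get("cutoff", 0.0)),
        ignore_snp=bool(raw.get("ignore_snp", False)),
        ignore_single=bool(raw.get("ignore_single", False)),
        small_indel_max=int(raw.get("small_indel_max", 25)),
        min_cryptic_codons=int(raw.get("min_cryptic_codons", 25)),
        min_mapq=int(raw.get("min_mapq", 0)),
        keep_duplicates=bool(raw.get("keep_duplicates", False)),
    )
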