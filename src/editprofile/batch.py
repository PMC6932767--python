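"""Batch profiling over samples x genes with deterministic CSV outputs.

Each (sample, gene) pair is processed independently — fetch reads, resolve
split groups, call and normalize variants, classify, aggregate alleles,
annotate impact, tally base conversions — so results are identical whatever
the worker count; a failing pair is logged into a failures table without
aborting the batch.
"""

from __future__ import annotations

import logging
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .alignments import fetch_segments, spans_window
from .baseedit import BaseCountMatrix, conversion_table, count_bases, logo_matrix
from .chimera import call_read, group_segments
from .classify import ERROR, ClassSummary, classify_read, summarize_classes
from .config import GeneRegion, RunConfig, load_reference
from .errors import ChimeraError, EditProfileError, RegionBoundsError
from .impact import FLAG_ORDER, ImpactProfile, annotate_impact
from .variants import Allele, aggregate_alleles, strip_snps

logger = logging.getLogger(__name__)


@dataclass
class PairResult:
    """Profiling result for one sample x gene cell."""

    sample: str
    gene: str
    analyzable: int
    non_analyzable: int
    reads: pd.DataFrame
    alleles: list[Allele]
    class_summary: ClassSummary
    base_counts: Optional[BaseCountMatrix] = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class BatchResult:
    results: dict[tuple[str, str], PairResult]
    failures: list[tuple[str, str, str]]

    @property
    def ok(self) -> bool:
        return not self.failures


def profile_pair(
    bam_path: str,
    region: GeneRegion,
    config: RunConfig,
    reference: Optional[str] = None,
    sample_name: str = "",
) -> PairResult:
    """Profile one BAM against one gene region."""
    t0 = time.perf_counter()
    if reference is None:
        reference = load_reference(config.index_path, region.chrom)
    region.validate(reference)
    segments = fetch_segments(
        bam_path, region, min_mapq=config.min_mapq, keep_duplicates=config.keep_duplicates
    )
    groups = group_segments(segments)
    analyzable = [g for g in groups if spans_window(g.segments, region)]
    non_analyzable = len(groups) - len(analyzable)
    template = region.hdr_template
    per_read = []
    labels = []
    rows = []
    for g in analyzable:
        try:
            vs = call_read(g, reference, region)
        except (ChimeraError, RegionBoundsError) as exc:
            logger.debug("read %s marked ERROR: %s", g.read_id, exc)
            vs = None
        if vs is None:
            label = ERROR
        else:
            effective = strip_snps(vs, template or ()) if config.ignore_snp else vs
            label = classify_read(effective, template)
        per_read.append((g.read_id, vs))
        labels.append(label)
        rows.append(
            {
                "read_id": g.read_id,
                "class": label,
                "split": g.is_split,
                "n_segments": len(g.segments),
            }
        )
    alleles = aggregate_alleles(per_read, config, region)
    region_seq = region.region_sequence(reference)
    for a in alleles:
        if a.name == "ERROR":
            a.class_label = ERROR
            a.impact = ImpactProfile.error_profile()
        else:
            a.class_label = classify_read(a.variants, template)
            a.impact = annotate_impact(a.variants, region, region_seq, config)
    read_to_allele = {}
    for a in alleles:
        for rid in a.read_ids:
            read_to_allele[rid] = a.name
    for row in rows:
        row["allele"] = read_to_allele.get(row["read_id"], "")
    reads_df = pd.DataFrame(rows, columns=["read_id", "allele", "class", "split", "n_segments"])
    summary = summarize_classes(labels) if labels else ClassSummary({k: 0 for k in ("WT",)}, 0)
    base = None
    if region.base_edit and analyzable:
        base = count_bases(analyzable, region, reference)
    logger.info(
        "%s x %s: %d segments, %d analyzable reads, %d non-analyzable, %.2fs",
        sample_name or bam_path,
        region.name,
        len(segments),
        len(analyzable),
        non_analyzable,
        time.perf_counter() - t0,
    )
    return PairResult(
        sample=sample_name or Path(bam_path).stem,
        gene=region.name,
        analyzable=len(analyzable),
        non_analyzable=non_analyzable,
        reads=reads_df,
        alleles=alleles,
        class_summary=summary,
        base_counts=base,
    )


def _impact_row(profile: ImpactProfile) -> dict:
    def cell(v):
        return "" if v is None else ("TRUE" if v else "FALSE")

    d = {k: cell(getattr(profile, k)) for k in FLAG_ORDER}
    d["cds_length"] = profile.cds_length
    return d


def write_outputs(result: PairResult, output_root: str | Path, force: bool = False) -> list[str]:
    """Write the per-read, per-allele, class-summary and (for base-edit
    regions) base-count/conversion/logo CSVs under
    ``<output_root>/<sample>/<gene>.*.csv``."""
    outdir = Path(output_root) / result.sample
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(suffix: str, df: pd.DataFrame, index=False) -> None:
        path = outdir / f"{result.gene}.{suffix}.csv"
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists; use force=True to overwrite")
        df.to_csv(path, index=index)
        written.append(str(path))

    emit("reads", result.reads)
    allele_rows = []
    for a in result.alleles:
        row = {
            "allele": a.name,
            "count": a.count,
            "frequency": a.frequency,
            "class": a.class_label,
            "reported": a.reported,
        }
        row.update(_impact_row(a.impact))
        allele_rows.append(row)
    emit("alleles", pd.DataFrame(allele_rows))
    emit("classes", pd.DataFrame(result.class_summary.as_rows()))
    if result.base_counts is not None:
        emit("basecounts", result.base_counts.table, index=True)
        emit("conversions", conversion_table(result.base_counts))
        emit("logo", logo_matrix(result.base_counts), index=True)
    return written


def _run_cell(args) -> tuple[str, str, PairResult]:
    bam_path, region, config, sample_name = args
    res = profile_pair(bam_path, region, config, sample_name=sample_name)
    return sample_name, region.name, res


def batch_profile(
    config: RunConfig,
    subset: Optional[Sequence[str]] = None,
    workers: int = 1,
    output_root: Optional[str | Path] = None,
    force: bool = False,
) -> BatchResult:
    """Profile every configured (sample, gene) pair.

    ``subset`` filters by sample or gene name.  Cells are computed
    independently (optionally in a process pool) and gathered in sorted
    order, so outputs are byte-identical for any worker count.
    """
    cells = []
    for sample in config.samples:
        for gene in config.genes:
            if subset and sample.name not in subset and gene.name not in subset:
                continue
            cells.append((sample.bam_path, gene, config, sample.name))
    cells.sort(key=lambda c: (c[3], c[1].name))
    results: dict[tuple[str, str], PairResult] = {}
    failures: list[tuple[str, str, str]] = []
    outcomes = []
    if workers <= 1:
        for cell in cells:
            try:
                outcomes.append(_run_cell(cell))
            except Exception as exc:
                logger.error("cell %s x %s failed: %s", cell[3], cell[1].name, exc)
                failures.append((cell[3], cell[1].name, str(exc)))
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            futures = [(cell, pool.submit(_run_cell, cell)) for cell in cells]
            for cell, fut in futures:
                try:
                    outcomes.append(fut.result())
                except Exception as exc:
                    logger.error("cell %s x %s failed: %s", cell[3], cell[1].name, exc)
                    failures.append((cell[3], cell[1].name, str(exc)))
    for sample_name, gene_name, res in sorted(outcomes, key=lambda o: (o[0], o[1])):
        results[(sample_name, gene_name)] = res
        if output_root is not None:
            write_outputs(res, output_root, force=force)
    if output_root is not None and failures:
        pd.DataFrame(failures, columns=["sample", "gene", "error"]).to_csv(
            Path(output_root) / "failures.csv", index=False
        )
    return BatchResult(results=results, failures=failures)


def summarize_batch(batch: BatchResult) -> pd.DataFrame:
    """Merge class summaries across all cells into one tidy table."""
    rows = []
    for (sample, gene), res in sorted(batch.results.items()):
        for row in res.class_summary.as_rows():
            rows.append({"sample": sample, "gene": gene, "analyzable": res.analyzable, **row})
    return pd.DataFrame(rows)
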