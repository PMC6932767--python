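"""Figures: allele alignment plot, impact grid, sequence logo.

Every plot also exports its underlying data as CSV so pipelines can assert
on data rather than pixels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .baseedit import BaseCountMatrix, logo_matrix
from .config import GeneRegion
from .impact import FLAG_ORDER
from .variants import sort_variants


def allele_display(allele, region: GeneRegion, region_seq: str) -> str:
    """Gapped rendering of an allele against the reference: deleted bases as
    ``-``, SNPs lowercase, insertions marked with ``*`` on the left flank."""
    if allele.name == "ERROR":
        return "?" * len(region_seq)
    chars = list(region_seq)
    for v in sort_variants(allele.variants):
        s0 = v.start - region.region_start
        if v.kind == "DEL":
            for i in range(s0, v.end - region.region_start + 1):
                chars[i] = "-"
        elif v.kind == "SNP":
            chars[s0] = v.alt_bases.lower()
        else:
            chars[s0] = chars[s0] + "*"
    return "".join(chars)


def plot_alleles(
    result,
    region: GeneRegion,
    region_seq: str,
    top_n: int = 10,
    path: Optional[str | Path] = None,
):
    """Alignment of the ``top_n`` most frequent alleles against the reference
    with cut-site (purple), analysis-window (yellow) and codon guides."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if not result.alleles:
        raise ValueError("allele table is empty")
    top = [a for a in result.alleles if a.reported][:top_n] or result.alleles[:top_n]
    rows = [
        {
            "allele": a.name,
            "count": a.count,
            "frequency": a.frequency,
            "class": a.class_label,
            "display": allele_display(a, region, region_seq),
        }
        for a in top
    ]
    df = pd.DataFrame(rows)
    if path is not None:
        path = Path(path)
        df.to_csv(path.with_suffix(".csv"), index=False)
        fig, ax = plt.subplots(figsize=(max(8, len(region_seq) / 10), 1 + 0.4 * len(top)))
        for c in region.cut_sites:
            ax.axvline(region.rel(c) - 0.5, color="purple", lw=1.5)
        ax.axvline(region.rel(region.window_start) - 1, color="gold", lw=1.0)
        ax.axvline(region.rel(region.window_end), color="gold", lw=1.0)
        if region.has_cds:
            step = 3 if region.strand == "+" else -3
            start = region.rel(region.cds_start) - 1
            for x in range(start, region.rel(region.cds_end), 3):
                ax.axvline(x, color="grey", lw=0.3, ls="--")
        for y, row in enumerate(rows):
            for x, ch in enumerate(row["display"]):
                color = {"-": "red"}.get(ch, "black" if ch.isupper() else "blue")
                ax.text(x + 0.5, len(rows) - y, ch, ha="center", va="center", fontsize=5, color=color, family="monospace")
            ax.text(len(region_seq) + 2, len(rows) - y, f"{row['allele']} ({row['count']})", fontsize=6, va="center")
        ax.set_xlim(0, len(region_seq) + 30)
        ax.set_ylim(0, len(rows) + 1)
        ax.set_yticks([])
        ax.set_xlabel(f"{region.name} position (region-relative)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return df


def plot_impact_grid(result, path: Optional[str | Path] = None):
    """Allele x 12-metric three-state grid (blue=true, white=false,
    grey=not applicable) with CDS-length bars."""
    rows = []
    for a in result.alleles:
        d = a.impact.as_dict()
        d["allele"] = a.name
        rows.append(d)
    df = pd.DataFrame(rows)[["allele", *FLAG_ORDER, "cds_length"]]
    if path is not None:
        path = Path(path)
        df.to_csv(path.with_suffix(".csv"), index=False)
        n = len(df)
        fig, (ax, axb) = plt.subplots(
            1, 2, figsize=(8, 1 + 0.35 * n), width_ratios=[3, 1], sharey=True
        )
        for y, row in df.iterrows():
            for x, flag in enumerate(FLAG_ORDER):
                v = row[flag]
                color = "lightgrey" if v is None or v == "" else ("steelblue" if v else "white")
                ax.add_patch(plt.Rectangle((x, n - 1 - y), 1, 1, facecolor=color, edgecolor="black", lw=0.5))
            axb.barh(n - 1 - y + 0.5, row["cds_length"], color="steelblue", height=0.7)
        ax.set_xticks([x + 0.5 for x in range(len(FLAG_ORDER))])
        ax.set_xticklabels(FLAG_ORDER, rotation=90, fontsize=7)
        ax.set_yticks([n - 1 - y + 0.5 for y in range(n)])
        ax.set_yticklabels(df["allele"], fontsize=6)
        ax.set_xlim(0, len(FLAG_ORDER))
        ax.set_ylim(0, n)
        axb.set_xlabel("CDS length (bp)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return df


def plot_logo(
    matrix: BaseCountMatrix,
    region: Optional[GeneRegion] = None,
    path: Optional[str | Path] = None,
):
    """Sequence logo (stacked letters scaled by frequency) from the
    position-frequency matrix."""
    pfm = logo_matrix(matrix, region)
    if path is not None:
        path = Path(path)
        pfm.to_csv(path.with_suffix(".csv"))
        colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
        fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(pfm)), 2.5))
        for x, (pos, row) in enumerate(pfm.iterrows()):
            y = 0.0
            for base in sorted("ACGT", key=lambda b: row[b]):
                f = row[base]
                if f <= 0:
                    continue
                ax.text(
                    x + 0.5,
                    y + f / 2,
                    base,
                    ha="center",
                    va="center",
                    fontsize=14,
                    color=colors[base],
                    family="monospace",
                    transform=ax.transData,
                    clip_on=True,
                )
                y += f
        ax.set_xticks([x + 0.5 for x in range(len(pfm))])
        ax.set_xticklabels(pfm.index, rotation=90, fontsize=6)
        ax.set_xlim(0, len(pfm))
        ax.set_ylim(0, 1)
        ax.set_ylabel("frequency")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return pfm
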