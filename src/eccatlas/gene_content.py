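"""Classify circles by gene content and map genes to circles per tumor.

A circle "has genes" when at least one complete functional transcript lies
fully inside it (circle.start <= t.start and t.end <= circle.end, strand
ignored).  Transcripts crossing a breakpoint stay genomic.  Gene-to-circle
assignment is per gene per tumor and existential over that tumor's circles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import Circle, CircleCohort, Transcript


@dataclass
class ClassifiedCohort:
    with_genes: dict[str, list[Circle]]
    without_genes: dict[str, list[Circle]]
    circle_genes: dict[tuple[str, str], set[str]]  # (tumor, circle_id) -> genes
    genome_genes: dict[str, set[str]]  # tumor -> genes not on any circle
    all_genes: set[str] = field(default_factory=set)

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.with_genes)

    def circle_gene_union(self, tumor: str) -> set[str]:
        out: set[str] = set()
        for (t, _cid), genes in self.circle_genes.items():
            if t == tumor:
                out |= genes
        return out


def classify_circles(
    cohort: CircleCohort, transcripts: list[Transcript]
) -> ClassifiedCohort:
    functional = [t for t in transcripts if t.is_functional]
    all_genes = {t.gene_id for t in functional}

    # per-chromosome transcript table sorted by start, for containment lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {t.interval.chrom for t in functional}:
        sub = sorted(
            (t for t in functional if t.interval.chrom == chrom),
            key=lambda t: (t.interval.start, t.interval.end),
        )
        by_chrom[chrom] = (
            np.array([t.interval.start for t in sub]),
            np.array([t.interval.end for t in sub]),
            [t.gene_id for t in sub],
        )

    with_genes: dict[str, list[Circle]] = {}
    without_genes: dict[str, list[Circle]] = {}
    circle_genes: dict[tuple[str, str], set[str]] = {}
    genome_genes: dict[str, set[str]] = {}

    for tumor in cohort.tumor_ids:
        with_genes[tumor] = []
        without_genes[tumor] = []
        assigned: set[str] = set()
        for circle in cohort.circles_by_tumor[tumor]:
            genes = _contained_genes(circle, by_chrom)
            if genes:
                with_genes[tumor].append(circle)
                circle_genes[(tumor, circle.circle_id)] = genes
                assigned |= genes
            else:
                without_genes[tumor].append(circle)
        genome_genes[tumor] = all_genes - assigned

    return ClassifiedCohort(with_genes, without_genes, circle_genes,
                            genome_genes, all_genes)


def _contained_genes(circle: Circle, by_chrom) -> set[str]:
    iv = circle.interval
    entry = by_chrom.get(iv.chrom)
    if entry is None:
        return set()
    starts, ends, gene_ids = entry
    lo = int(np.searchsorted(starts, iv.start, side="left"))
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    return {gene_ids[i] for i in range(lo, hi) if ends[i] <= iv.end}


def cohort_summary(classified: ClassifiedCohort) -> pd.DataFrame:
    """Per-class circle-count and length statistics, per tumor and pooled."""
    rows = []
    for cls, mapping in (("with_genes", classified.with_genes),
                         ("without_genes", classified.without_genes)):
        per_tumor_n = [len(v) for v in mapping.values()]
        lengths = [c.length() for v in mapping.values() for c in v]
        rows.append({
            "class": cls,
            "n_tumors": len(mapping),
            "mean_n_per_tumor": float(np.mean(per_tumor_n)) if per_tumor_n else 0.0,
            "min_n_per_tumor": int(min(per_tumor_n)) if per_tumor_n else 0,
            "max_n_per_tumor": int(max(per_tumor_n)) if per_tumor_n else 0,
            "mean_length": float(np.mean(lengths)) if lengths else 0.0,
            "min_length": int(min(lengths)) if lengths else 0,
            "max_length": int(max(lengths)) if lengths else 0,
        })
    return pd.DataFrame(rows)


def write_gene_classes(
    classified: ClassifiedCohort, expr_genes: set[str] | None, path: str | Path
) -> None:
    """Long-format per-tumor gene class table (tumor, gene, circle|genome)."""
    with open(path, "w") as fh:
        fh.write("tumor_id\tgene_id\tclass\n")
        for tumor in classified.tumor_ids:
            on_circle = classified.circle_gene_union(tumor)
            for gene in sorted(classified.all_genes):
                if expr_genes is not None and gene not in expr_genes:
                    continue
                cls = "circle" if gene in on_circle else "genome"
                fh.write(f"{tumor}\t{gene}\t{cls}\n")
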