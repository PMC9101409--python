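"""Genome-binned circularization commonality and hotspot calling.

Each 1 kb bin (default) receives, per tumor, a binary indicator: 1 if at
least one of the tumor's circles overlaps the bin by >= 1 bp.  Summing the
indicator over tumors gives the commonality track; a locus is a hotspot
when more tumors carry a circle there than in the best bin of a matched
random-control track.  The real-vs-null distributional comparison uses a
two-sample Kolmogorov-Smirnov test, sample excess kurtosis, and QQ points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .io_formats import (
    CircleCohort,
    GenomeLayout,
    GenomicInterval,
    ValidationError,
)


@dataclass
class BinCountTrack:
    bin_size: int
    counts: dict[str, np.ndarray]
    n_tumors: int
    provenance: str = "real"

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in sorted(self.counts)])

    def max_count(self) -> int:
        return int(max(int(v.max(initial=0)) for v in self.counts.values()))


@dataclass
class HotspotRegion:
    interval: GenomicInterval
    max_tumor_count: int
    n_bins_merged: int


@dataclass
class DistributionComparison:
    ks_statistic: float
    ks_p: float
    kurtosis_real: float
    kurtosis_random: float
    qq_points: list[tuple[float, float]] = field(default_factory=list)


def binary_bin_counts(
    cohort: CircleCohort, layout: GenomeLayout, bin_size: int = 1000
) -> BinCountTrack:
    """Per-bin number of tumors with >= 1 overlapping circle.

    Excluded chromosomes are dropped; a tumor contributes 0 or 1 to a bin no
    matter how many of its circles land there.
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    chroms = layout.analysis_chroms()
    n_bins = {c: -(-layout.chrom_lengths[c] // bin_size) for c in chroms}
    counts = {c: np.zeros(n_bins[c], dtype=np.int32) for c in chroms}
    for tumor in cohort.tumor_ids:
        present = {c: np.zeros(n_bins[c], dtype=bool) for c in chroms}
        for circle in cohort.circles_by_tumor[tumor]:
            iv = circle.interval
            if iv.chrom not in present:
                continue
            lo = iv.start // bin_size
            hi = (iv.end - 1) // bin_size  # inclusive; half-open end excluded
            hi = min(hi, n_bins[iv.chrom] - 1)
            present[iv.chrom][lo : hi + 1] = True
        for c in chroms:
            counts[c] += present[c]
    return BinCountTrack(bin_size, counts, cohort.n_tumors(), cohort.provenance)


def compare_distributions(
    real: BinCountTrack, random: BinCountTrack, n_qq: int = 101
) -> DistributionComparison:
    """Two-sample KS + excess kurtosis + QQ points on the flattened counts."""
    if real.bin_size != random.bin_size:
        raise ValidationError("tracks have different bin sizes")
    x, y = real.flatten(), random.flatten()
    if x.size == 0 or y.size == 0:
        raise ValidationError("empty bin-count track")
    ks = stats.ks_2samp(x, y, method="asymp")
    qs = np.linspace(0, 100, n_qq)
    qq = list(zip(np.percentile(y, qs), np.percentile(x, qs)))
    return DistributionComparison(
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        kurtosis_real=float(stats.kurtosis(x, fisher=True, bias=False)),
        kurtosis_random=float(stats.kurtosis(y, fisher=True, bias=False)),
        qq_points=qq,
    )


def compare_distributions_per_chrom(
    real: BinCountTrack, random: BinCountTrack
) -> dict[str, tuple[float, float]]:
    """KS statistic and p restricted to each chromosome."""
    out = {}
    for chrom in real.counts:
        if chrom not in random.counts:
            continue
        ks = stats.ks_2samp(real.counts[chrom], random.counts[chrom], method="asymp")
        out[chrom] = (float(ks.statistic), float(ks.pvalue))
    return out


def call_hotspots(
    real: BinCountTrack,
    random: BinCountTrack,
    merge_distance: int = 1000,
    threshold: int | None = None,
) -> list[HotspotRegion]:
    """Bins whose tumor count exceeds the null maximum, merged into regions.

    ``threshold`` defaults to the maximum bin count of the random track (a
    property of the supplied null, recomputed per run, never a constant).
    Hotspot bins whose gap is <= merge_distance are reported as one region.
    """
    if threshold is None:
        threshold = random.max_count()
    bs = real.bin_size
    regions: list[HotspotRegion] = []
    for chrom in sorted(real.counts):
        vec = real.counts[chrom]
        hot = np.flatnonzero(vec > threshold)
        if hot.size == 0:
            continue
        run_start = prev = int(hot[0])
        bins_in_run = [int(hot[0])]
        for b in hot[1:]:
            b = int(b)
            gap = (b - prev - 1) * bs
            if gap <= merge_distance:
                bins_in_run.append(b)
            else:
                regions.append(_make_region(chrom, run_start, prev, bins_in_run, vec, bs))
                run_start = b
                bins_in_run = [b]
            prev = b
        regions.append(_make_region(chrom, run_start, prev, bins_in_run, vec, bs))
    return regions


def _make_region(chrom, first_bin, last_bin, bins, vec, bs):
    interval = GenomicInterval(chrom, first_bin * bs, (last_bin + 1) * bs)
    return HotspotRegion(
        interval=interval,
        max_tumor_count=int(max(vec[b] for b in bins)),
        n_bins_merged=len(bins),
    )


def write_hotspots_bed(regions: list[HotspotRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                     f"{r.max_tumor_count}\n")
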