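"""Synthetic genome, annotation, circle cohort, and expression matrix with
planted, recoverable structure.

Everything downstream of the readers can be exercised on this module's
output without any external download: hotspot loci recur across tumors at a
set penetrance; chosen circles carry homologous or microhomologous flanks
copied across their two breakpoints; PWM consensus sequences are written
near breakpoints; circle-resident genes get an expression boost.  All
randomness flows from one integer seed through named substreams, so every
output is byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_content import classify_circles
from .io_formats import (
    Circle,
    CircleCohort,
    GenomeLayout,
    GenomicInterval,
    Pfm,
    Transcript,
    ValidationError,
    write_circles_bed,
    write_fasta,
    write_fpkm,
    write_genome_layout,
    write_gmt,
    write_jaspar_pfm,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class CapacityError(RuntimeError):
    """Requested placements do not fit in the synthetic genome."""


def default_motif_pfm() -> Pfm:
    """A strong 10-bp synthetic motif (near-deterministic consensus)."""
    consensus = "TGACGTCATT"
    counts = np.full((4, len(consensus)), 1.0)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = 97.0
    return Pfm("SYN0001", counts)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the real cohort's structure at desk scale: tens of
    tumors with ~50 circles each (down from a mean of 521), circle lengths
    log-uniform across three orders of magnitude so every length filter
    (>200, >500, >1000 bp) sees traffic on both sides, recurrent hotspot
    loci, and an expression boost for circle-resident genes.
    """

    n_chroms: int = 2
    chrom_length: int = 300_000
    centromere_fraction: float = 0.1
    n_tumors: int = 20
    circles_per_tumor_mean: float = 50.0
    circles_per_tumor_dispersion: float = 0.15  # CV of the per-tumor count
    circle_length_range: tuple[int, int] = (300, 30_000)  # log-uniform
    n_hotspots: int = 5
    hotspot_penetrance: float = 0.9
    hotspot_length: int = 5000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (400, 1500)
    homology_plant_fraction: float = 0.0
    homology_plant_length: int = 100
    homology_plant_mismatch_rate: float = 0.0
    microhomology_plant_fraction: float = 0.0
    microhomology_plant_length: int = 12
    motif_plant_rate: float = 0.0
    motif_plant_offset: int = 0
    expressed_probability: float = 0.52
    fpkm_log_mean: float = 1.0
    fpkm_log_sd: float = 1.0
    expression_fpkm_boost: float = 2.0
    expression_prob_boost: float = 0.15
    n_random_gene_sets: int = 20
    gene_set_size: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("centromere_fraction", "hotspot_penetrance",
                     "homology_plant_fraction", "microhomology_plant_fraction",
                     "motif_plant_rate", "expressed_probability"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.circle_length_range[0] <= 0:
            raise ValidationError("circle lengths must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        ss = np.random.SeedSequence([self.seed, _STREAMS[stream]])
        return np.random.default_rng(ss)


_STREAMS = {name: i for i, name in enumerate(
    ["genome", "genes", "counts", "placement", "homology", "microhomology",
     "motif", "expression", "gene_sets"]
)}


@dataclass
class PlantedTruth:
    hotspot_loci: list[GenomicInterval] = field(default_factory=list)
    homologous_circle_ids: set[str] = field(default_factory=set)
    microhomologous_circle_ids: set[str] = field(default_factory=set)
    motif_circle_ids: set[str] = field(default_factory=set)
    boosted_genes_by_tumor: dict[str, set[str]] = field(default_factory=dict)
    planted_set_name: str = ""

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hotspot_loci": [
                [iv.chrom, iv.start, iv.end] for iv in self.hotspot_loci
            ],
            "homologous_circle_ids": sorted(self.homologous_circle_ids),
            "microhomologous_circle_ids": sorted(self.microhomologous_circle_ids),
            "motif_circle_ids": sorted(self.motif_circle_ids),
            "boosted_genes_by_tumor": {
                t: sorted(g) for t, g in self.boosted_genes_by_tumor.items()
            },
            "planted_set_name": self.planted_set_name,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


class MutableGenome:
    """In-memory editable genome; the single sequence source for planting."""

    def __init__(self, codes_by_chrom: dict[str, np.ndarray]):
        self.codes = codes_by_chrom

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return _BASES[self.codes[chrom][start:end]].tobytes().decode("ascii")

    def write_at(self, chrom: str, start: int, seq_codes: np.ndarray) -> None:
        arr = self.codes[chrom]
        if start < 0 or start + seq_codes.size > arr.size:
            raise IndexError(f"edit out of bounds on {chrom}")
        arr[start : start + seq_codes.size] = seq_codes

    def sequences(self) -> dict[str, str]:
        return {c: _BASES[v].tobytes().decode("ascii")
                for c, v in self.codes.items()}


def generate_genome(
    config: SyntheticConfig,
) -> tuple[GenomeLayout, MutableGenome, list[Transcript]]:
    """I.i.d. uniform-composition chromosomes with a centered centromere and
    uniformly placed non-overlapping genes outside centromeres."""
    rng = config.rng("genome")
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    codes = {c: rng.integers(0, 4, size=config.chrom_length, dtype=np.uint8)
             for c in chrom_names}
    centromeres = {}
    for c in chrom_names:
        half = int(config.chrom_length * config.centromere_fraction / 2)
        mid = config.chrom_length // 2
        if half > 0:
            centromeres[c] = GenomicInterval(c, mid - half, mid + half)
    layout = GenomeLayout({c: config.chrom_length for c in chrom_names},
                          centromeres)
    transcripts = _place_genes(config, layout)
    return layout, MutableGenome(codes), transcripts


def _place_genes(config: SyntheticConfig, layout: GenomeLayout) -> list[Transcript]:
    rng = config.rng("genes")
    chroms = list(layout.chrom_lengths)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    transcripts: list[Transcript] = []
    lo, hi = config.gene_length_range
    max_attempts = 200 * max(config.n_genes, 1)
    attempts = 0
    while len(transcripts) < config.n_genes:
        if attempts >= max_attempts:
            raise CapacityError(
                f"could not place {config.n_genes} genes (placed "
                f"{len(transcripts)}); genome too small"
            )
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(lo, hi + 1))
        arms = layout.arms(chrom)
        arm = arms[int(rng.integers(0, len(arms)))]
        if arm[1] - arm[0] < length:
            continue
        start = int(rng.integers(arm[0], arm[1] - length + 1))
        end = start + length
        if any(start < e and s < end for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        idx = len(transcripts)
        gid = f"G{idx:04d}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        transcripts.append(
            Transcript(gid, gid, GenomicInterval(chrom, start, end, strand), True)
        )
    transcripts.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return transcripts


def write_gtf(transcripts: Sequence[Transcript], path: str | Path) -> None:
    """GENCODE-style minimal GTF (gene + transcript features, 1-based)."""
    with open(path, "w") as fh:
        fh.write("##provider: eccatlas-synthetic\n")
        for t in transcripts:
            iv = t.interval
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.gene_id}.1"; '
                f'gene_name "{t.gene_name}"; gene_type "protein_coding"; '
                f'transcript_type "protein_coding"; tag "basic";'
            )
            for feature in ("gene", "transcript"):
                fh.write(
                    f"{iv.chrom}\tsynthetic\t{feature}\t{iv.start + 1}\t{iv.end}"
                    f"\t.\t{iv.strand if iv.strand != '.' else '+'}\t.\t{attrs}\n"
                )


def generate_circle_cohort(
    config: SyntheticConfig, layout: GenomeLayout
) -> tuple[CircleCohort, PlantedTruth]:
    """Per-tumor circle sets with recurrent hotspot circles plus uniformly
    placed background circles, all avoiding centromeres."""
    rng_counts = config.rng("counts")
    rng_place = config.rng("placement")
    truth = PlantedTruth()

    hotspots: list[GenomicInterval] = []
    guard = 0
    while len(hotspots) < config.n_hotspots:
        iv = _uniform_interval(rng_place, layout, config.hotspot_length)
        if iv is None or any(iv.overlaps(h) for h in hotspots):
            guard += 1
            if guard > 10_000:
                raise CapacityError("could not place hotspot loci")
            continue
        hotspots.append(iv)
    truth.hotspot_loci = list(hotspots)

    lo, hi = config.circle_length_range
    by_tumor: dict[str, list[Circle]] = {}
    for ti in range(config.n_tumors):
        tumor = f"T{ti:03d}"
        circles: list[Circle] = []
        for h in hotspots:
            if rng_counts.random() < config.hotspot_penetrance:
                circles.append(Circle(h, tumor, f"{tumor}_c{len(circles)}"))
        sd = config.circles_per_tumor_mean * config.circles_per_tumor_dispersion
        n_total = max(
            len(circles),
            int(round(rng_counts.normal(config.circles_per_tumor_mean, sd))),
        )
        while len(circles) < n_total:
            length = int(round(np.exp(rng_place.uniform(np.log(lo), np.log(hi)))))
            iv = _uniform_interval(rng_place, layout, length)
            if iv is None:
                continue
            circles.append(Circle(iv, tumor, f"{tumor}_c{len(circles)}"))
        by_tumor[tumor] = circles
    return CircleCohort(by_tumor), truth


def _uniform_interval(rng, layout: GenomeLayout, length: int) -> GenomicInterval | None:
    """One rejection draw: uniform over the genome, invalid -> None."""
    chroms = list(layout.chrom_lengths)
    lens = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    chrom = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
    chrom_len = layout.chrom_lengths[chrom]
    if chrom_len < length:
        return None
    start = int(rng.integers(0, chrom_len - length + 1))
    end = start + length
    cen = layout.centromeres.get(chrom)
    if cen is not None and start < cen.end and cen.start < end:
        return None
    return GenomicInterval(chrom, start, end)


def plant_flank_homology(
    genome: MutableGenome,
    circle: Circle,
    length: int,
    mismatch_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> None:
    """Copy the ``length``-bp sequence straddling the start breakpoint onto
    the region straddling the end breakpoint, with per-base substitutions at
    ``mismatch_rate``."""
    iv = circle.interval
    if iv.length() <= 2 * length:
        raise ValidationError(
            f"circle {circle.circle_id} too short ({iv.length()} bp) to plant "
            f"{length} bp of flank homology"
        )
    rng = rng or np.random.default_rng(0)
    half = length // 2
    if iv.start - half < 0 or iv.end - half + length > genome.codes[iv.chrom].size:
        raise IndexError("planted window would overlap a chromosome end")
    src = genome.codes[iv.chrom][iv.start - half : iv.start - half + length].copy()
    if mismatch_rate > 0:
        flip = rng.random(length) < mismatch_rate
        src[flip] = (src[flip] + rng.integers(1, 4, size=int(flip.sum()))) % 4
    genome.write_at(iv.chrom, iv.end - half, src)


def plant_motif(
    genome: MutableGenome,
    circle: Circle,
    pfm: Pfm,
    offset: int = 0,
    end: str = "start",
) -> None:
    """Write the PFM consensus at breakpoint + offset (both-end planting is
    two calls)."""
    if abs(offset) > 250:
        raise ValidationError("|offset| must be <= the 250 bp motif flank")
    iv = circle.interval
    breakpoint = iv.start if end == "start" else iv.end
    pos = breakpoint + offset
    codes = np.array(["ACGT".index(b) for b in pfm.consensus()], dtype=np.uint8)
    if pos < 0 or pos + codes.size > genome.codes[iv.chrom].size:
        raise IndexError("motif consensus would overlap a chromosome end")
    genome.write_at(iv.chrom, pos, codes)


def generate_expression(
    config: SyntheticConfig,
    transcripts: Sequence[Transcript],
    cohort: CircleCohort,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Gene x tumor FPKM matrix; circle-resident genes of a tumor get the
    configured expressed-probability and FPKM boost.  Returns the matrix and
    the per-tumor boosted gene sets."""
    rng = config.rng("expression")
    classified = classify_circles(cohort, list(transcripts))
    genes = sorted({t.gene_id for t in transcripts})
    tumors = cohort.tumor_ids
    mat = np.zeros((len(genes), len(tumors)))
    boosted: dict[str, set[str]] = {}
    gene_idx = {g: i for i, g in enumerate(genes)}
    for j, tumor in enumerate(tumors):
        on_circle = classified.circle_gene_union(tumor)
        boosted[tumor] = set(on_circle)
        p = np.full(len(genes), config.expressed_probability)
        boost = np.ones(len(genes))
        for g in on_circle:
            i = gene_idx[g]
            p[i] = min(1.0, p[i] + config.expression_prob_boost)
            boost[i] = config.expression_fpkm_boost
        expressed = rng.random(len(genes)) < p
        vals = rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd,
                             size=len(genes))
        mat[:, j] = np.where(expressed, vals * boost, 0.0)
    df = pd.DataFrame(mat, index=genes, columns=tumors).round(4)
    return df, boosted


def generate_gene_sets(
    config: SyntheticConfig,
    transcripts: Sequence[Transcript],
    truth: PlantedTruth,
) -> dict[str, set[str]]:
    """GMT collection: one planted set = genes inside hotspot loci (hence
    circle-resident in most tumors), plus random sets of comparable size."""
    rng = config.rng("gene_sets")
    genes = sorted({t.gene_id for t in transcripts})
    planted = {
        t.gene_id
        for t in transcripts
        if any(h.contains(t.interval) for h in truth.hotspot_loci)
    }
    sets: dict[str, set[str]] = {}
    if planted:
        sets["PLANTED_HOTSPOT_SET"] = planted
        truth.planted_set_name = "PLANTED_HOTSPOT_SET"
    for i in range(config.n_random_gene_sets):
        size = min(config.gene_set_size, len(genes))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"RANDOM_SET_{i:02d}"] = {genes[int(k)] for k in members}
    return sets


@dataclass
class SyntheticCohortFiles:
    layout: GenomeLayout
    fasta: Path
    layout_tsv: Path
    gtf: Path
    circles_bed: Path
    fpkm_tsv: Path
    gmt: Path
    pfm: Path
    truth_json: Path


def build_cohort(config: SyntheticConfig, outdir: str | Path) -> SyntheticCohortFiles:
    """Generate the full synthetic study into ``outdir`` (standard formats)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout, genome, transcripts = generate_genome(config)
    cohort, truth = generate_circle_cohort(config, layout)

    hotspot_ivs = set((h.chrom, h.start, h.end) for h in truth.hotspot_loci)

    def is_background(c: Circle) -> bool:
        iv = c.interval
        return (iv.chrom, iv.start, iv.end) not in hotspot_ivs

    # plant homology / microhomology / motifs on background circles only:
    # hotspot circles share coordinates across tumors, so planting there
    # would silently mark every co-located circle.
    rng_h = config.rng("homology")
    rng_m = config.rng("microhomology")
    rng_mo = config.rng("motif")
    pfm = default_motif_pfm()
    seen_coords: set[tuple[str, int, int]] = set()
    edited: dict[str, list[tuple[int, int]]] = {}

    def _reserve(chrom: str, spans: list[tuple[int, int]]) -> bool:
        """Claim genome spans for one plant; False when any span collides
        with an earlier edit (a later plant would corrupt it)."""
        taken = edited.setdefault(chrom, [])
        for s, e in spans:
            if any(s < te and ts < e for ts, te in taken):
                return False
        taken.extend(spans)
        return True

    def _plant_pair(circle: Circle, length: int, mismatch_rate: float, rng) -> bool:
        iv = circle.interval
        half = length // 2
        spans = [(iv.start - half, iv.start - half + length),
                 (iv.end - half, iv.end - half + length)]
        if not _reserve(iv.chrom, spans):
            return False
        try:
            plant_flank_homology(genome, circle, length, mismatch_rate, rng)
        except IndexError:  # breakpoint too close to a chromosome end
            return False
        return True

    for circle in cohort.iter_circles():
        if not is_background(circle):
            continue
        coords = (circle.interval.chrom, circle.interval.start, circle.interval.end)
        if coords in seen_coords:
            continue
        seen_coords.add(coords)
        if (circle.length() > max(1000, 2 * config.homology_plant_length)
                and rng_h.random() < config.homology_plant_fraction):
            if _plant_pair(circle, config.homology_plant_length,
                           config.homology_plant_mismatch_rate, rng_h):
                truth.homologous_circle_ids.add(circle.circle_id)
        elif (circle.length() > max(200, 2 * config.microhomology_plant_length)
                and rng_m.random() < config.microhomology_plant_fraction):
            if _plant_pair(circle, config.microhomology_plant_length, 0.0, rng_m):
                truth.microhomologous_circle_ids.add(circle.circle_id)
        if (circle.length() > 500 and rng_mo.random() < config.motif_plant_rate):
            iv = circle.interval
            pos = iv.start + config.motif_plant_offset
            if not _reserve(iv.chrom, [(pos, pos + pfm.width)]):
                continue
            try:
                plant_motif(genome, circle, pfm, config.motif_plant_offset, "start")
            except IndexError:
                continue
            truth.motif_circle_ids.add(circle.circle_id)

    fpkm, boosted = generate_expression(config, transcripts, cohort)
    truth.boosted_genes_by_tumor = boosted
    gene_sets = generate_gene_sets(config, transcripts, truth)

    paths = SyntheticCohortFiles(
        layout=layout,
        fasta=outdir / "genome.fa",
        layout_tsv=outdir / "layout.tsv",
        gtf=outdir / "annotation.gtf",
        circles_bed=outdir / "circles.bed",
        fpkm_tsv=outdir / "fpkm.tsv",
        gmt=outdir / "gene_sets.gmt",
        pfm=outdir / "motifs.pfm",
        truth_json=outdir / "truth.json",
    )
    write_fasta(genome.sequences(), paths.fasta)
    write_genome_layout(layout, paths.layout_tsv)
    write_gtf(transcripts, paths.gtf)
    write_circles_bed(cohort, paths.circles_bed)
    write_fpkm(fpkm, paths.fpkm_tsv)
    write_gmt(gene_sets, paths.gmt)
    write_jaspar_pfm([pfm], paths.pfm)
    truth.to_json(paths.truth_json)
    return paths
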