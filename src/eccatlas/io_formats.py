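"""Readers, writers and domain types for every external format the pipeline touches.

All coordinates are held in one frame: 0-based half-open (BED convention).
GTF input (1-based inclusive) is converted on read; nothing downstream ever
sees a 1-based coordinate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A file did not conform to its declared format."""


class ValidationError(ValueError):
    """A value violated a domain invariant."""


STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Full containment (closed on the half-open frame); strand ignored."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeLayout:
    """Chromosome lengths plus centromere exclusion zones.

    The coordinate frame for every placement, binning, and window operation.
    ``excluded_chroms`` (e.g. chrY in a mixed-sex cohort) are kept at read
    time but dropped from all binned analyses.
    """

    chrom_lengths: dict[str, int]
    centromeres: dict[str, GenomicInterval] = field(default_factory=dict)
    excluded_chroms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for chrom, cen in self.centromeres.items():
            if chrom not in self.chrom_lengths:
                raise ValidationError(f"centromere on unknown chromosome {chrom}")
            if cen.end > self.chrom_lengths[chrom]:
                raise ValidationError(
                    f"centromere {cen} exceeds {chrom} length "
                    f"{self.chrom_lengths[chrom]}"
                )

    def analysis_chroms(self) -> list[str]:
        return [c for c in self.chrom_lengths if c not in self.excluded_chroms]

    def arms(self, chrom: str) -> list[tuple[int, int]]:
        """Placement-eligible segments of a chromosome (outside the centromere)."""
        length = self.chrom_lengths[chrom]
        cen = self.centromeres.get(chrom)
        if cen is None:
            return [(0, length)]
        out = []
        if cen.start > 0:
            out.append((0, cen.start))
        if cen.end < length:
            out.append((cen.end, length))
        return out


@dataclass(frozen=True)
class Circle:
    """One eccDNA call: an interval plus its tumor of origin."""

    interval: GenomicInterval
    tumor_id: str
    circle_id: str

    def length(self) -> int:
        return self.interval.length()


@dataclass
class CircleCohort:
    """Per-tumor circle sets, real or matched random control."""

    circles_by_tumor: dict[str, list[Circle]]
    provenance: str = "real"

    def __post_init__(self) -> None:
        if self.provenance not in {"real", "random_control"}:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        for tumor, circles in self.circles_by_tumor.items():
            ids = [c.circle_id for c in circles]
            if len(ids) != len(set(ids)):
                raise ValidationError(f"duplicate circle ids in tumor {tumor}")

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.circles_by_tumor)

    def n_tumors(self) -> int:
        return len(self.circles_by_tumor)

    def n_circles(self) -> int:
        return sum(len(v) for v in self.circles_by_tumor.values())

    def iter_circles(self) -> Iterator[Circle]:
        for circles in self.circles_by_tumor.values():
            yield from circles

    def length_multiset(self, tumor_id: str) -> list[int]:
        return sorted(c.length() for c in self.circles_by_tumor[tumor_id])


@dataclass(frozen=True)
class Transcript:
    gene_id: str
    gene_name: str
    interval: GenomicInterval
    is_functional: bool = True


@dataclass
class Pfm:
    """Position frequency matrix: base counts, rows in A, C, G, T order."""

    motif_id: str
    counts: np.ndarray  # shape (4, width)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValidationError("PFM counts must be a 4 x width matrix")
        if self.counts.shape[1] < 1:
            raise ValidationError("PFM width must be >= 1")
        if np.any(self.counts < 0):
            raise ValidationError("PFM counts must be non-negative")
        if np.any(self.counts.sum(axis=0) == 0):
            raise ValidationError("PFM has an all-zero column")

    @property
    def width(self) -> int:
        return int(self.counts.shape[1])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


# ---------------------------------------------------------------------------
# BED circles


def read_circles_bed(
    path: str | Path,
    tumor_column: int = 3,
    provenance: str = "real",
) -> CircleCohort:
    """Read BED3+ circle calls; the tumor/sample id sits in ``tumor_column``
    (0-based; BED column 4 by default)."""
    circles_by_tumor: dict[str, list[Circle]] = {}
    counters: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) <= max(2, tumor_column):
                raise ParseError(f"{path}:{lineno}: expected >= "
                                 f"{max(3, tumor_column + 1)} fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            tumor = fields[tumor_column]
            k = counters.get(tumor, 0)
            counters[tumor] = k + 1
            circle = Circle(interval, tumor, f"{tumor}_c{k}")
            circles_by_tumor.setdefault(tumor, []).append(circle)
    return CircleCohort(circles_by_tumor, provenance=provenance)


def read_circles_dir(path: str | Path, provenance: str = "real") -> CircleCohort:
    """Directory layout: one BED file per tumor, filename stem = tumor id."""
    circles_by_tumor: dict[str, list[Circle]] = {}
    for bed in sorted(Path(path).glob("*.bed")):
        tumor = bed.stem
        circles: list[Circle] = []
        with open(bed) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                try:
                    interval = GenomicInterval(f[0], int(f[1]), int(f[2]))
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{bed}:{lineno}: malformed BED line") from exc
                circles.append(Circle(interval, tumor, f"{tumor}_c{len(circles)}"))
        circles_by_tumor[tumor] = circles
    return CircleCohort(circles_by_tumor, provenance=provenance)


def write_circles_bed(cohort: CircleCohort, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tumor in cohort.tumor_ids:
            for c in cohort.circles_by_tumor[tumor]:
                fh.write(f"{c.interval.chrom}\t{c.interval.start}\t"
                         f"{c.interval.end}\t{tumor}\n")


# ---------------------------------------------------------------------------
# GTF transcripts

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def default_functional_filter(attrs: Mapping[str, str]) -> bool:
    """Complete protein-coding transcript per GENCODE-style tagging.

    GENCODE tagging schemes vary across versions, so this is a replaceable
    predicate: transcript_type (or gene_type) equal to protein_coding when
    present, otherwise every transcript is accepted.
    """
    ttype = attrs.get("transcript_type") or attrs.get("transcript_biotype")
    if ttype is not None:
        return ttype == "protein_coding"
    gtype = attrs.get("gene_type") or attrs.get("gene_biotype")
    if gtype is not None:
        return gtype == "protein_coding"
    return True


def read_gtf_transcripts(
    path: str | Path,
    functional_filter: Callable[[Mapping[str, str]], bool] = default_functional_filter,
) -> list[Transcript]:
    """Extract transcript features; 1-based inclusive GTF coordinates become
    0-based half-open on read."""
    out: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF fields")
            if fields[2] != "transcript":
                continue
            attrs = dict(_ATTR_RE.findall(fields[8]))
            if "gene_id" not in attrs:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            start_1 = int(fields[3])
            end_1 = int(fields[4])
            interval = GenomicInterval(
                fields[0], start_1 - 1, end_1,
                fields[6] if fields[6] in STRANDS else ".",
            )
            out.append(
                Transcript(
                    gene_id=attrs["gene_id"],
                    gene_name=attrs.get("gene_name", attrs["gene_id"]),
                    interval=interval,
                    is_functional=bool(functional_filter(attrs)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# FASTA


class ReferenceSequence:
    """Random-access genome sequence; always returns uppercase A/C/G/T/N."""

    def __init__(self, path: str | Path):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True)

    def chroms(self) -> list[str]:
        return list(self._fasta.keys())

    def chrom_length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise KeyError(f"chromosome {chrom!r} not in FASTA")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta:
            raise KeyError(f"chromosome {chrom!r} not in FASTA")
        if start < 0 or end > len(self._fasta[chrom]) or start >= end:
            raise IndexError(
                f"interval {chrom}:{start}-{end} out of bounds "
                f"(length {len(self._fasta[chrom])})"
            )
        return str(self._fasta[chrom][start:end])

    def fetch_interval(self, interval: GenomicInterval) -> str:
        return self.fetch(interval.chrom, interval.start, interval.end)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Genome layout table (lengths + centromeres + exclusions)


def write_genome_layout(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\tcen_start\tcen_end\texcluded\n")
        for chrom, length in layout.chrom_lengths.items():
            cen = layout.centromeres.get(chrom)
            cs, ce = (cen.start, cen.end) if cen else (-1, -1)
            excl = int(chrom in layout.excluded_chroms)
            fh.write(f"{chrom}\t{length}\t{cs}\t{ce}\t{excl}\n")


def read_genome_layout(path: str | Path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "length"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: layout table needs columns {sorted(required)}")
    lengths = dict(zip(df["chrom"].astype(str), df["length"].astype(int)))
    centromeres = {}
    if {"cen_start", "cen_end"}.issubset(df.columns):
        for _, row in df.iterrows():
            if int(row["cen_start"]) >= 0:
                centromeres[str(row["chrom"])] = GenomicInterval(
                    str(row["chrom"]), int(row["cen_start"]), int(row["cen_end"])
                )
    excluded = set()
    if "excluded" in df.columns:
        excluded = set(df.loc[df["excluded"].astype(int) == 1, "chrom"].astype(str))
    return GenomeLayout(lengths, centromeres, excluded)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(set(genes))) + "\n")


# ---------------------------------------------------------------------------
# JASPAR PFM text


def read_jaspar_pfm(path: str | Path) -> list[Pfm]:
    """Read JASPAR 2016+ text PFMs (">ID NAME" then bracketed A/C/G/T rows).

    Row order is normalized to A, C, G, T regardless of how the file labels
    its rows.
    """
    from Bio import motifs as bio_motifs

    out: list[Pfm] = []
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
            for m in records:
                counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
                motif_id = m.matrix_id or m.name
                out.append(Pfm(motif_id=motif_id, counts=counts))
        except ValidationError:
            raise
        except Exception as exc:  # biopython raises bare Exception subclasses
            raise ParseError(f"{path}: not valid JASPAR PFM text ({exc})") from exc
    return out


def write_jaspar_pfm(pfms: Iterable[Pfm], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id} {pfm.motif_id}\n")
            for base, row in zip("ACGT", pfm.counts):
                vals = " ".join(f"{int(v):6d}" if float(v).is_integer() else f"{v:8.2f}"
                                for v in row)
                fh.write(f"{base}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# FPKM matrix


def read_fpkm(path: str | Path) -> pd.DataFrame:
    """Tab-delimited gene x tumor FPKM matrix; first column = gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative FPKM values")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_fpkm(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")
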