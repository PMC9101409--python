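"""Control ensembles: size/count-matched random circles and scrambled sequence.

The random ensemble re-places every real circle at a uniformly random
genomic position of identical length, redrawing any position that would
cross a centromere or run off a chromosome end; per-tumor circle counts and
the exact per-tumor length multiset are therefore preserved by construction.
The scrambled ensemble permutes nucleotides within a window, preserving
composition while destroying order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import (
    Circle,
    CircleCohort,
    GenomeLayout,
    GenomicInterval,
    ValidationError,
)


class PlacementError(RuntimeError):
    """No valid random placement exists (or was found) for a circle."""


@dataclass
class RandomizationSpec:
    max_attempts_per_circle: int = 1000
    seed: int = 0
    respect_excluded_chroms: bool = False

    def __post_init__(self) -> None:
        if self.max_attempts_per_circle < 1:
            raise ValidationError("max_attempts_per_circle must be >= 1")


def _placement_chroms(layout: GenomeLayout, spec: RandomizationSpec) -> list[str]:
    if spec.respect_excluded_chroms:
        return layout.analysis_chroms()
    return list(layout.chrom_lengths)


def generate_random_circles(
    cohort: CircleCohort,
    layout: GenomeLayout,
    spec: RandomizationSpec | None = None,
) -> CircleCohort:
    """One matched random circle per real circle, uniform over valid starts.

    A start is valid when [start, start+len) stays inside the chromosome and
    does not include or cross its centromere.  Placement is by rejection:
    draw a chromosome (weighted by length) and a start, redraw on violation.
    """
    spec = spec or RandomizationSpec()
    rng = np.random.default_rng(spec.seed)
    chroms = _placement_chroms(layout, spec)
    lengths = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    by_tumor: dict[str, list[Circle]] = {}
    for tumor in cohort.tumor_ids:
        placed: list[Circle] = []
        for circle in cohort.circles_by_tumor[tumor]:
            n = circle.length()
            interval = _place_one(rng, layout, chroms, probs, n,
                                  spec.max_attempts_per_circle)
            if interval is None:
                raise PlacementError(
                    f"could not place circle {circle.circle_id} "
                    f"(length {n}) after {spec.max_attempts_per_circle} attempts"
                )
            placed.append(Circle(interval, tumor, f"{circle.circle_id}_rand"))
        by_tumor[tumor] = placed
    return CircleCohort(by_tumor, provenance="random_control")


def _place_one(rng, layout, chroms, probs, n, max_attempts):
    for _ in range(max_attempts):
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        chrom_len = layout.chrom_lengths[chrom]
        if chrom_len < n:
            continue
        start = int(rng.integers(0, chrom_len - n + 1))
        end = start + n
        cen = layout.centromeres.get(chrom)
        if cen is not None and start < cen.end and cen.start < end:
            continue
        return GenomicInterval(chrom, start, end)
    return None


def scramble_sequence(seq: str, seed: int | np.random.Generator = 0) -> str:
    """Uniform random permutation of the characters of ``seq``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return rng.permutation(arr).tobytes().decode("ascii")
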