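"""Self-homology and microhomology between a circle's two breakpoint windows.

For each circle, the window straddling the start breakpoint (flank bp inside
the circle + flank bp of flanking genome) is aligned against the window
straddling the end breakpoint with an internal seed-and-extend local aligner.
Significance uses the Karlin-Altschul E-value E = K * m * n * exp(-lambda*S);
alignments with E < 1 count as homologous.  Two modes mirror the biology:

* homology      -- flank 500 bp, minimum seed word 28 bp, circles > 1000 bp;
                   the signature of homologous recombination.
* microhomology -- flank 100 bp, minimum seed word 4 bp, circles > 200 bp;
                   the substrate of microhomology-mediated end joining.

The identical scan is applied to three groups: real circles, matched random
circles, and scrambled (per-window nucleotide-permuted) real windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _swalign
from .io_formats import Circle, CircleCohort, ReferenceSequence, ValidationError
from .null_controls import scramble_sequence

logger = logging.getLogger(__name__)

#: Mode registry: (flank bp, seed word size, minimum circle length, exclusive).
MODES: dict[str, dict[str, int]] = {
    "homology": {"flank": 500, "word_size": 28, "min_circle_length": 1000},
    "microhomology": {"flank": 100, "word_size": 4, "min_circle_length": 200},
}


def karlin_altschul_lambda(
    match: int, mismatch: int, background: Sequence[float] = (0.25,) * 4
) -> float:
    """Ungapped Karlin-Altschul lambda for a match/mismatch scheme.

    Solves sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0.
    """
    p = np.asarray(background, dtype=float)
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise ValidationError("background must sum to 1")

    def f(lam: float) -> float:
        same = float((p * p).sum())
        return same * math.exp(lam * match) + (1 - same) * math.exp(lam * mismatch) - 1

    return float(optimize.brentq(f, 1e-9, 10.0))


@dataclass
class AlignerParams:
    """Scoring scheme, seeding word size, and E-value constants.

    Defaults follow the published NCBI constants for match +2 / mismatch -3
    with gap open 5 / extend 2 (lambda = 0.625, K = 0.41); both are
    configurable, as is the genome background feeding the lambda solver.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 28
    lambda_: float = 0.625
    K: float = 0.41
    e_threshold: float = 1.0
    both_strands: bool = True
    band_pad: int = 16

    def __post_init__(self) -> None:
        if self.word_size < 1:
            raise ValidationError("word size must be >= 1")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValidationError("lambda and K must be positive")

    @classmethod
    def homology(cls, **kw) -> "AlignerParams":
        return cls(word_size=MODES["homology"]["word_size"], **kw)

    @classmethod
    def microhomology(cls, **kw) -> "AlignerParams":
        return cls(word_size=MODES["microhomology"]["word_size"], **kw)

    @classmethod
    def for_mode(cls, mode: str, **kw) -> "AlignerParams":
        return cls(word_size=MODES[mode]["word_size"], **kw)

    def evalue(self, score: int, m: int, n: int) -> float:
        return float(self.K * m * n * math.exp(-self.lambda_ * score))


@dataclass(frozen=True)
class AlignmentHit:
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    length: int
    n_mismatch: int
    n_gap: int
    score: int
    evalue: float
    strand: str = "+"


@dataclass
class BreakpointWindowPair:
    circle: Circle
    start_window: str
    end_window: str
    flank: int

    def __post_init__(self) -> None:
        if len(self.start_window) != 2 * self.flank or len(self.end_window) != 2 * self.flank:
            raise ValidationError("breakpoint windows must have length 2*flank")


def extract_window_pair(
    circle: Circle, ref: ReferenceSequence, flank: int
) -> BreakpointWindowPair | None:
    """Window pair straddling the two breakpoints, or None when filtered.

    Circles not longer than 2*flank are filtered (the two windows would
    overlap inside the circle); windows running off the chromosome skip the
    circle with a logged reason.
    """
    iv = circle.interval
    if iv.length() <= 2 * flank:
        return None
    chrom_len = ref.chrom_length(iv.chrom)
    if iv.start - flank < 0 or iv.end + flank > chrom_len:
        logger.info("circle %s: breakpoint window out of chromosome bounds; skipped",
                    circle.circle_id)
        return None
    start_window = ref.fetch(iv.chrom, iv.start - flank, iv.start + flank)
    end_window = ref.fetch(iv.chrom, iv.end - flank, iv.end + flank)
    return BreakpointWindowPair(circle, start_window, end_window, flank)


def collect_window_pairs(
    cohort: CircleCohort, ref: ReferenceSequence, flank: int
) -> list[BreakpointWindowPair]:
    pairs = []
    for circle in cohort.iter_circles():
        pair = extract_window_pair(circle, ref, flank)
        if pair is not None:
            pairs.append(pair)
    return pairs


def scramble_window_pairs(
    pairs: Sequence[BreakpointWindowPair], seed: int
) -> list[BreakpointWindowPair]:
    """Scrambled control: each window independently nucleotide-permuted."""
    rng = np.random.default_rng(seed)
    return [
        BreakpointWindowPair(
            p.circle,
            scramble_sequence(p.start_window, rng),
            scramble_sequence(p.end_window, rng),
            p.flank,
        )
        for p in pairs
    ]


def local_align(query: str, subject: str, params: AlignerParams) -> list[AlignmentHit]:
    """All seeded, non-redundant local alignments, sorted ascending by E-value.

    Exact shared words of length >= word_size seed diagonal clusters; each
    cluster is extended with a banded affine Smith-Waterman.  When
    both_strands is set, the reverse complement of the subject is searched
    too, with subject coordinates reported in the original frame.  Hits
    overlapping a better hit in both query and subject are dropped.
    """
    m, n = len(query), len(subject)
    qc = _swalign.encode(query)
    raw: list[AlignmentHit] = []
    strands = ["+", "-"] if params.both_strands else ["+"]
    for strand in strands:
        subj = subject if strand == "+" else _swalign.revcomp(subject)
        sc = _swalign.encode(subj)
        diags = _swalign.seed_diagonals(qc, sc, params.word_size)
        for dlo, dhi in _swalign.cluster_diagonals(diags, params.band_pad):
            score, qs, qe, ss, se, n_mis, n_gap, length = _swalign.banded_sw(
                qc, sc, params.match, params.mismatch,
                params.gap_open, params.gap_extend, dlo, dhi,
            )
            if score <= 0 or length < params.word_size:
                continue
            if strand == "-":
                ss, se = n - se, n - ss
            raw.append(
                AlignmentHit(
                    q_start=qs, q_end=qe, s_start=ss, s_end=se,
                    length=length, n_mismatch=n_mis, n_gap=n_gap,
                    score=score, evalue=params.evalue(score, m, n),
                    strand=strand,
                )
            )
    raw.sort(key=lambda h: (h.evalue, -h.length, h.q_start, h.s_start))
    kept: list[AlignmentHit] = []
    for hit in raw:
        redundant = any(
            hit.q_start < k.q_end and k.q_start < hit.q_end
            and hit.s_start < k.s_end and k.s_start < hit.s_end
            for k in kept
        )
        if not redundant:
            kept.append(hit)
    return kept


def scan_windows(
    pairs: Sequence[BreakpointWindowPair], params: AlignerParams
) -> pd.DataFrame:
    """Best significant hit per window pair (start window = query, end = subject)."""
    rows = []
    for pair in pairs:
        hits = local_align(pair.start_window, pair.end_window, params)
        best = hits[0] if hits and hits[0].evalue < params.e_threshold else None
        rows.append({
            "tumor_id": pair.circle.tumor_id,
            "circle_id": pair.circle.circle_id,
            "has_hit": best is not None,
            "score": best.score if best else 0,
            "evalue": best.evalue if best else float("inf"),
            "length": best.length if best else 0,
            "n_mismatch": best.n_mismatch if best else 0,
            "n_gap": best.n_gap if best else 0,
            "q_start": best.q_start if best else -1,
            "q_end": best.q_end if best else -1,
            "s_start": best.s_start if best else -1,
            "s_end": best.s_end if best else -1,
            "strand": best.strand if best else ".",
        })
    return pd.DataFrame(
        rows,
        columns=["tumor_id", "circle_id", "has_hit", "score", "evalue", "length",
                 "n_mismatch", "n_gap", "q_start", "q_end", "s_start", "s_end",
                 "strand"],
    )


def scan_cohort(
    cohort: CircleCohort,
    ref: ReferenceSequence,
    mode: str = "homology",
    params: AlignerParams | None = None,
) -> pd.DataFrame:
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}")
    params = params or AlignerParams.for_mode(mode)
    pairs = collect_window_pairs(cohort, ref, MODES[mode]["flank"])
    return scan_windows(pairs, params)


@dataclass
class HomologyGroupSummary:
    group: str
    n_circles: int
    pct_with_hit: float
    mean_hit_length: float  # over circles with a hit; NaN when none


@dataclass
class GroupComparison:
    summaries: list[HomologyGroupSummary]
    anova_pct: tuple[float, float]  # (F, p) on per-tumor hit percentages
    tukey_pct: pd.DataFrame | None
    anova_length: tuple[float, float]  # (F, p) on per-circle best-hit lengths
    tukey_length: pd.DataFrame | None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.summaries])


def _anova(groups: list[np.ndarray], names: list[str]):
    """One-way ANOVA + Tukey HSD, with the degenerate all-equal-means case
    reported as F = 0, p = 1 rather than NaN."""
    means = [float(g.mean()) for g in groups]
    if max(means) == min(means):
        return (0.0, 1.0), None
    f, p = stats.f_oneway(*groups)
    tuk = stats.tukey_hsd(*groups)
    rows = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            rows.append({
                "group_a": names[a],
                "group_b": names[b],
                "mean_diff": means[a] - means[b],
                "p": float(tuk.pvalue[a, b]),
            })
    return (float(f), float(p)), pd.DataFrame(rows)


def summarize_groups(results: Mapping[str, pd.DataFrame]) -> GroupComparison:
    """Per-group summary plus omnibus ANOVA and Tukey HSD pairwise tests.

    The percentage test runs on per-tumor hit percentages; the length test
    on per-circle best-hit lengths of circles with a hit.  Groups with no
    eligible circles are excluded with a warning.
    """
    usable = {g: df for g, df in results.items() if len(df) > 0}
    for g in results:
        if g not in usable:
            logger.warning("group %s has no eligible circles; excluded", g)
    if len(usable) < 2:
        raise ValidationError("need >= 2 non-empty groups to compare")
    summaries = []
    pct_vectors, pct_names = [], []
    len_vectors, len_names = [], []
    for group, df in usable.items():
        with_hit = df.loc[df["has_hit"], "length"].to_numpy(dtype=float)
        summaries.append(
            HomologyGroupSummary(
                group=group,
                n_circles=len(df),
                pct_with_hit=100.0 * float(df["has_hit"].mean()),
                mean_hit_length=(float(with_hit.mean()) if with_hit.size
                                 else float("nan")),
            )
        )
        per_tumor = df.groupby("tumor_id")["has_hit"].mean() * 100.0
        pct_vectors.append(per_tumor.to_numpy(dtype=float))
        pct_names.append(group)
        if with_hit.size:
            len_vectors.append(with_hit)
            len_names.append(group)
    anova_pct, tukey_pct = _anova(pct_vectors, pct_names)
    if len(len_vectors) >= 2:
        anova_length, tukey_length = _anova(len_vectors, len_names)
    else:
        anova_length, tukey_length = (float("nan"), float("nan")), None
    return GroupComparison(summaries, anova_pct, tukey_pct,
                           anova_length, tukey_length)


@dataclass
class PositionTrace:
    flank: int
    values: np.ndarray  # index 0 .. 2*flank maps to offsets -flank .. +flank
    n_contributing: int

    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def value_at(self, offset: int) -> int:
        return int(self.values[offset + self.flank])


def position_trace(results: pd.DataFrame, flank: int) -> PositionTrace:
    """Sum, over circles with a hit, of an indicator covering the best hit's
    query-window positions, on the -flank..+flank breakpoint number line."""
    values = np.zeros(2 * flank + 1, dtype=np.int64)
    n = 0
    for _, row in results.loc[results["has_hit"]].iterrows():
        values[int(row["q_start"]) : int(row["q_end"])] += 1
        n += 1
    return PositionTrace(flank=flank, values=values, n_contributing=n)


def write_trace(trace: PositionTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tcount\n")
        for off, v in zip(trace.offsets(), trace.values):
            fh.write(f"{off}\t{int(v)}\n")
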