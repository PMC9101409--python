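"""PWM motif scanning in ±250 bp breakpoint windows, with per-tumor
Fisher's-exact enrichment against matched random-control windows.

A PFM becomes a log2-odds PWM against a background composition with a
pseudocount; a hit is any window position (either strand) whose summed
log-odds reaches the score threshold (default 80% of the maximal achievable
score).  Per tumor and motif, the fraction of real breakpoint windows with
>= 1 hit is compared to background windows drawn from the random-control
cohort's breakpoints by a one-sided Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._swalign import encode, revcomp
from .io_formats import (
    Circle,
    CircleCohort,
    Pfm,
    ReferenceSequence,
    ValidationError,
)

logger = logging.getLogger(__name__)

MOTIF_FLANK = 250  # bp on either side of the breakpoint
MIN_CIRCLE_LENGTH = 500  # exclusive; windows must not overlap inside the circle


@dataclass
class Pwm:
    motif_id: str
    log_odds: np.ndarray  # 4 x width, log2(p/q)
    score_threshold: float
    background: tuple[float, float, float, float]

    @property
    def width(self) -> int:
        return int(self.log_odds.shape[1])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    offset: int  # hit start relative to the breakpoint (window midpoint)
    strand: str
    score: float


def build_pwm(
    pfm: Pfm,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 1.0,
    threshold_fraction: float = 0.8,
) -> Pwm:
    """Log2-odds PWM: p = (count + pseudocount*q) / (total + pseudocount)."""
    q = np.asarray(background, dtype=float)
    if not np.isclose(q.sum(), 1.0):
        raise ValidationError("background must sum to 1")
    if pseudocount <= 0:
        if np.any(pfm.counts == 0):
            raise ValidationError(
                "pseudocount must be positive when the PFM has zero counts"
            )
        pseudocount = 0.0
    totals = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount * q[:, None]) / (totals + pseudocount)
    log_odds = np.log2(probs / q[:, None])
    pwm = Pwm(pfm.motif_id, log_odds, 0.0, tuple(q))
    pwm.score_threshold = threshold_fraction * pwm.max_score
    return pwm


def _strand_scores(pwm: Pwm, codes: np.ndarray) -> np.ndarray:
    """Summed log-odds at every start position; N positions kill the window."""
    w = pwm.width
    n = codes.shape[0] - w + 1
    if n <= 0:
        return np.empty(0)
    lo = np.vstack([pwm.log_odds, np.full(w, -np.inf)])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return lo[windows, np.arange(w)].sum(axis=1)


def scan_window(pwm: Pwm, seq: str) -> list[MotifHit]:
    """Hits on both strands; offsets relative to the window midpoint
    (the breakpoint), hit start given on the plus strand."""
    mid = len(seq) // 2
    hits: list[MotifHit] = []
    codes = encode(seq)
    plus = _strand_scores(pwm, codes)
    for i in np.flatnonzero(plus >= pwm.score_threshold):
        hits.append(MotifHit(pwm.motif_id, int(i) - mid, "+", float(plus[i])))
    minus = _strand_scores(pwm, encode(revcomp(seq)))
    L = len(seq)
    for j in np.flatnonzero(minus >= pwm.score_threshold):
        i = L - pwm.width - int(j)  # map back to plus-strand start
        hits.append(MotifHit(pwm.motif_id, i - mid, "-", float(minus[j])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def breakpoint_windows(
    cohort: CircleCohort, ref: ReferenceSequence, flank: int = MOTIF_FLANK
) -> dict[str, list[tuple[Circle, str, str]]]:
    """Per tumor: (circle, end label, sequence) for both breakpoints of every
    circle longer than 2*flank whose windows fit on the chromosome."""
    out: dict[str, list[tuple[Circle, str, str]]] = {}
    for tumor in cohort.tumor_ids:
        rows = []
        for circle in cohort.circles_by_tumor[tumor]:
            iv = circle.interval
            if iv.length() <= 2 * flank:
                continue
            chrom_len = ref.chrom_length(iv.chrom)
            if iv.start - flank < 0 or iv.end + flank > chrom_len:
                continue
            rows.append((circle, "start_breakpoint",
                         ref.fetch(iv.chrom, iv.start - flank, iv.start + flank)))
            rows.append((circle, "end_breakpoint",
                         ref.fetch(iv.chrom, iv.end - flank, iv.end + flank)))
        out[tumor] = rows
    return out


def tumor_motif_enrichment(
    real_windows: Sequence[str],
    background_windows: Sequence[str],
    pwms: Sequence[Pwm],
) -> pd.DataFrame:
    """One-sided Fisher's exact per motif: windows-with-hit, real vs background."""
    if not real_windows or not background_windows:
        raise ValidationError("need >= 1 real and >= 1 background window")
    rows = []
    real_codes = [encode(s) for s in real_windows]
    real_rc = [encode(revcomp(s)) for s in real_windows]
    bg_codes = [encode(s) for s in background_windows]
    bg_rc = [encode(revcomp(s)) for s in background_windows]
    for pwm in pwms:
        a = _n_windows_hit(pwm, real_codes, real_rc)
        b = _n_windows_hit(pwm, bg_codes, bg_rc)
        table = [[a, len(real_windows) - a], [b, len(background_windows) - b]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        rows.append({
            "motif_id": pwm.motif_id,
            "n_real_hit": a,
            "n_real": len(real_windows),
            "n_background_hit": b,
            "n_background": len(background_windows),
            "p": p,
        })
    return pd.DataFrame(rows)


def _n_windows_hit(pwm: Pwm, codes_list, rc_list) -> int:
    n = 0
    thr = pwm.score_threshold
    for c, rc in zip(codes_list, rc_list):
        if (_strand_scores(pwm, c) >= thr).any() or \
                (_strand_scores(pwm, rc) >= thr).any():
            n += 1
    return n


def cohort_motif_enrichment(
    real_by_tumor: Mapping[str, Sequence[tuple[Circle, str, str]]],
    background_by_tumor: Mapping[str, Sequence[tuple[Circle, str, str]]],
    pwms: Sequence[Pwm],
) -> pd.DataFrame:
    """Per-motif p-value matrix (rows = motifs, columns = tumors)."""
    cols = {}
    for tumor, rows in real_by_tumor.items():
        bg = background_by_tumor.get(tumor, [])
        if not rows or not bg:
            logger.warning("tumor %s lacks real or background windows; skipped", tumor)
            continue
        df = tumor_motif_enrichment([r[2] for r in rows], [b[2] for b in bg], pwms)
        cols[tumor] = df.set_index("motif_id")["p"]
    return pd.DataFrame(cols)


@dataclass
class MotifTally:
    motif_id: str
    group: str
    n_tumors_enriched: int
    n_tumors_total: int


def tally_and_compare(
    per_group_pvalues: Mapping[str, pd.DataFrame],
    alpha: float = 0.001,
    min_tumor_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Tally per-motif significance across tumors per group and form the
    common/unique motif sets between with_genes and without_genes.

    A motif is "enriched in a group" when significant at alpha in at least
    min_tumor_fraction of the group's tumors.
    """
    rows = []
    enriched: dict[str, set[str]] = {}
    for group, pmat in per_group_pvalues.items():
        n_tumors = pmat.shape[1]
        sig_counts = (pmat < alpha).sum(axis=1)
        enriched[group] = set(
            sig_counts.index[sig_counts >= min_tumor_fraction * n_tumors]
        )
        for motif_id, n_sig in sig_counts.items():
            rows.append(MotifTally(motif_id, group, int(n_sig), n_tumors))
    tally = pd.DataFrame([vars(r) for r in rows])
    sets: dict[str, set[str]] = {}
    if {"with_genes", "without_genes"} <= set(enriched):
        wg, wog = enriched["with_genes"], enriched["without_genes"]
        sets = {
            "common": wg & wog,
            "unique_with_genes": wg - wog,
            "unique_without_genes": wog - wg,
        }
    for group, motifs in enriched.items():
        sets[f"enriched_{group}"] = motifs
    return tally, sets


def motif_position_trace(
    hits: Sequence[MotifHit], width: int, flank: int = MOTIF_FLANK
) -> np.ndarray:
    """Indicator sum over hits on the -flank..+flank number line; each hit
    marks [offset, offset + width), clipped to the line."""
    values = np.zeros(2 * flank + 1, dtype=np.int64)
    for h in hits:
        lo = max(h.offset + flank, 0)
        hi = min(h.offset + width + flank, values.size)
        if hi > lo:
            values[lo:hi] += 1
    return values
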