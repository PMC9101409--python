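"""Seed-and-extend local alignment primitives.

Sequences are 2-bit encoded (A=0, C=1, G=2, T=3, N=4; N never matches).
Seeding finds exact shared words of length W; each cluster of nearby seed
diagonals is extended with a banded affine-gap Smith-Waterman (numba) whose
band covers the cluster's diagonals plus a pad.  A gap of length k costs
gap_open + k * gap_extend.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODES = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODES[_b] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    return _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _words(codes: np.ndarray, w: int, sentinel: int) -> np.ndarray:
    """2-bit packed w-mers; windows containing N get a unique sentinel."""
    n = codes.shape[0] - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for k in range(w):
        window = codes[k : k + n]
        vals = vals * 4 + np.minimum(window, 3)
        bad |= window == 4
    vals[bad] = sentinel
    return vals


def seed_diagonals(q_codes: np.ndarray, s_codes: np.ndarray, w: int) -> np.ndarray:
    """Sorted unique diagonals (s_pos - q_pos) carrying a shared exact w-mer."""
    if w > 31:
        raise ValueError("word size > 31 not supported by the 2-bit packing")
    qw = _words(q_codes, w, sentinel=-1)
    sw = _words(s_codes, w, sentinel=-2)
    if qw.size == 0 or sw.size == 0:
        return np.empty(0, dtype=np.int64)
    order = np.argsort(sw, kind="stable")
    sws = sw[order]
    lo = np.searchsorted(sws, qw, side="left")
    hi = np.searchsorted(sws, qw, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    s_pos = np.concatenate(
        [order[l:h] for l, h, c in zip(lo, hi, counts) if c > 0]
    )
    q_pos = np.repeat(np.arange(qw.size), counts)
    return np.unique(s_pos - q_pos)


def cluster_diagonals(diags: np.ndarray, pad: int) -> list[tuple[int, int]]:
    """Group nearby seed diagonals; each group yields one search band."""
    if diags.size == 0:
        return []
    bands = []
    start = prev = int(diags[0])
    for d in diags[1:]:
        d = int(d)
        if d - prev <= pad:
            prev = d
        else:
            bands.append((start - pad, prev + pad))
            start = prev = d
    bands.append((start - pad, prev + pad))
    return bands


@njit(cache=False)
def banded_sw(q, s, match, mismatch, gap_open, gap_extend, dlo, dhi):  # pragma: no cover
    """Best local alignment within diagonal band dlo <= (j - i) <= dhi.

    Returns (score, q_start, q_end, s_start, s_end, n_mismatch, n_gap, length);
    score 0 means no positive-scoring alignment in the band.
    """
    m = q.shape[0]
    n = s.shape[0]
    NEG = np.int64(-(10 ** 9))
    H = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    ptr_h = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 restart, 1 diag, 2 E, 3 F
    ptr_e = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 open, 1 extend
    ptr_f = np.zeros((m + 1, n + 1), dtype=np.uint8)
    H[0, :] = 0
    H[:, 0] = 0
    best = np.int64(0)
    bi = 0
    bj = 0
    go_ge = gap_open + gap_extend
    for i in range(1, m + 1):
        j0 = i + dlo
        j1 = i + dhi
        if j0 < 1:
            j0 = 1
        if j1 > n:
            j1 = n
        for j in range(j0, j1 + 1):
            e_open = H[i, j - 1] - go_ge
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptr_e[i, j] = 0
            else:
                E[i, j] = e_ext
                ptr_e[i, j] = 1
            f_open = H[i - 1, j] - go_ge
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptr_f[i, j] = 0
            else:
                F[i, j] = f_ext
                ptr_f[i, j] = 1
            qa = q[i - 1]
            sb = s[j - 1]
            if qa == sb and qa < 4:
                sub = match
            else:
                sub = mismatch
            diag = H[i - 1, j - 1] + sub
            h = np.int64(0)
            p = np.uint8(0)
            if diag > h:
                h = diag
                p = np.uint8(1)
            if E[i, j] > h:
                h = E[i, j]
                p = np.uint8(2)
            if F[i, j] > h:
                h = F[i, j]
                p = np.uint8(3)
            H[i, j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return (0, 0, 0, 0, 0, 0, 0, 0)
    # traceback
    i = bi
    j = bj
    n_mis = 0
    n_gap = 0
    length = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                qa = q[i - 1]
                sb = s[j - 1]
                if not (qa == sb and qa < 4):
                    n_mis += 1
                i -= 1
                j -= 1
                length += 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            came = ptr_e[i, j]
            j -= 1
            n_gap += 1
            length += 1
            state = 0 if came == 0 else 1
        else:
            came = ptr_f[i, j]
            i -= 1
            n_gap += 1
            length += 1
            state = 0 if came == 0 else 2
    return (int(best), i, bi, j, bj, n_mis, n_gap, length)


def smith_waterman_score(q: str, s: str, match: int, mismatch: int,
                         gap_open: int, gap_extend: int) -> int:
    """Unbanded optimal local-alignment score (thin wrapper over the kernel)."""
    qc, sc = encode(q), encode(s)
    res = banded_sw(qc, sc, match, mismatch, gap_open, gap_extend,
                    -len(q), len(s))
    return int(res[0])
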