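"""PWM construction, log-odds scanning, and exact null score distributions.

Scores are in bits.  Per-window p-values come from the exact distribution of
the window score under an i.i.d. background, computed by convolving the
discretized per-position score distributions (default bin: 0.01 bits).  A
motif is called present in a sequence when its best window beats the
per-window p-value threshold (default 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binomtest

from .io_formats import BASES, MotifCountMatrix

__all__ = [
    "PWM",
    "MotifHit",
    "NullScorePMF",
    "UNIFORM_BACKGROUND",
    "DEFAULT_P_THRESHOLD",
    "build_pwm",
    "empirical_background",
    "scan_sequence",
    "null_pmf",
    "motif_present",
    "central_enrichment",
    "reverse_complement",
]

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
DEFAULT_P_THRESHOLD = 1e-4  # MAST's default per-hit threshold
DEFAULT_BIN_WIDTH = 0.01

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One scored window: offset in the sequence, strand, score, p-value."""

    position: int
    strand: str
    score: float
    p_value: float


@dataclass(frozen=True)
class NullScorePMF:
    """Discretized distribution of the window score under background.

    Bin ``k`` covers scores near ``k * bin_width``; ``offset`` is the index
    of the first bin.  ``p_ge(s)`` returns the exact tail mass at the bin
    resolution (clamped into (0, 1]).
    """

    bin_width: float
    offset: int
    masses: np.ndarray
    _tail: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        total = float(self.masses.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"null PMF masses sum to {total}, not 1")
        tail = np.cumsum(self.masses[::-1])[::-1]
        object.__setattr__(self, "_tail", tail)

    def p_ge(self, score: float) -> float:
        k = int(np.rint(score / self.bin_width)) - self.offset
        k = min(max(k, 0), len(self.masses) - 1)
        return float(self._tail[k])


@dataclass(frozen=True)
class PWM:
    """Log-odds position weight matrix (bits) with its background model."""

    motif_id: str
    log_odds: np.ndarray  # L x 4, A,C,G,T order
    background: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "_null_by_bin", {})

    def __len__(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=1))

    def null(self, bin_width: float = DEFAULT_BIN_WIDTH) -> NullScorePMF:
        """Exact null distribution, cached per bin width."""
        cache = self._null_by_bin  # type: ignore[attr-defined]
        if bin_width not in cache:
            cache[bin_width] = null_pmf(self, bin_width)
        return cache[bin_width]


def build_pwm(
    counts: MotifCountMatrix,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    pseudocount: float = 1.0,
) -> PWM:
    """Build a log-odds PWM from a count matrix.

    ``log_odds[i, j] = log2(((c[i,j] + pc*bg[j]) / (total_i + pc)) / bg[j])``
    — a total pseudocount of ``pseudocount`` per column, distributed by
    background (the MEME convention).
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 positive probabilities")
    if abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError(f"background sums to {bg.sum()}, not 1")
    arr = counts.to_array()
    totals = arr.sum(axis=1, keepdims=True)
    if pseudocount <= 0:
        if np.any(totals == 0):
            raise ValueError("zero-total column with pseudocount 0")
        if np.any(arr == 0):
            raise ValueError("zero count with pseudocount 0 gives -inf score")
    probs = (arr + pseudocount * bg) / (totals + pseudocount)
    return PWM(
        motif_id=counts.motif_id,
        log_odds=np.log2(probs / bg),
        background=bg,
        pseudocount=float(pseudocount),
    )


def empirical_background(seqs: Sequence[str]) -> tuple[float, ...]:
    """Mononucleotide frequencies over the supplied sequences (N ignored)."""
    counts = np.zeros(4)
    for seq in seqs:
        for base, i in _BASE_INDEX.items():
            counts[i] += seq.upper().count(base)
    if counts.sum() == 0:
        raise ValueError("no A/C/G/T bases in supplied sequences")
    return tuple(counts / counts.sum())


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


def _window_scores(pwm_matrix: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Score every window; windows containing N (code -1) become -inf."""
    L = pwm_matrix.shape[0]
    n_win = codes.size - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n_win, -np.inf)
    if valid.any():
        w = windows[valid]
        scores[valid] = pwm_matrix[np.arange(L), w].sum(axis=1)
    return scores


def scan_sequence(pwm: PWM, seq: str, bin_width: float = DEFAULT_BIN_WIDTH) -> list[MotifHit]:
    """Score every window of ``seq`` on both strands.

    Minus-strand windows are scored on the reverse complement; the reported
    position is always the window's left offset on the input sequence.
    Windows containing N are skipped.  Hits are sorted by position, plus
    strand first.
    """
    L = len(pwm)
    if len(seq) < L:
        return []
    codes = _encode(seq)
    null = pwm.null(bin_width)
    fwd = _window_scores(pwm.log_odds, codes)
    # scanning '-' strand == scanning the reverse-complemented PWM forward
    rc_matrix = pwm.log_odds[::-1, ::-1]
    rev = _window_scores(rc_matrix, codes)
    hits: list[MotifHit] = []
    for pos in range(len(fwd)):
        if np.isfinite(fwd[pos]):
            s = float(fwd[pos])
            hits.append(MotifHit(pos, "+", s, null.p_ge(s)))
        if np.isfinite(rev[pos]):
            s = float(rev[pos])
            hits.append(MotifHit(pos, "-", s, null.p_ge(s)))
    return hits


def null_pmf(pwm: PWM, bin_width: float = DEFAULT_BIN_WIDTH) -> NullScorePMF:
    """Exact distribution of the window score under the background model.

    Each position contributes one of four scores with background
    probability; the window score distribution is their convolution over
    bins of ``bin_width`` bits.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    per_pos_bins = np.rint(pwm.log_odds / bin_width).astype(np.int64)
    acc = np.array([1.0])
    acc_off = 0
    for i in range(len(pwm)):
        pos_bins = per_pos_bins[i]
        b_lo, b_hi = int(pos_bins.min()), int(pos_bins.max())
        step = np.zeros(b_hi - b_lo + 1)
        for j in range(4):
            step[pos_bins[j] - b_lo] += pwm.background[j]
        acc = np.convolve(acc, step)
        acc_off += b_lo
    return NullScorePMF(bin_width=bin_width, offset=acc_off, masses=acc)


def motif_present(
    pwm: PWM,
    seq: str,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> tuple[bool, MotifHit | None]:
    """MAST-style presence call: best window p-value beats the threshold.

    Returns ``(present, best_hit)``; ``best_hit`` is None when no window is
    scorable.  A threshold of 1 declares presence whenever any scorable
    window exists (p-values never exceed 1).
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    hits = scan_sequence(pwm, seq, bin_width)
    if not hits:
        return False, None
    best = min(hits, key=lambda h: (h.p_value, -h.score, h.position))
    present = best.p_value < p_threshold or p_threshold >= 1.0
    return present, best


def central_enrichment(
    hit_midpoints: Sequence[float],
    region_width: int,
    central_fraction: float = 0.2,
) -> tuple[float, float]:
    """Enrichment of best-hit motif midpoints in the central window.

    The central window is the middle ``central_fraction`` of the region.
    Returns ``(ratio, p)`` where ratio = observed central fraction /
    ``central_fraction`` and p is a one-sided exact binomial tail.  With no
    hits the ratio is NaN and p is 1.
    """
    if not 0 < central_fraction < 1:
        raise ValueError("central_fraction must be in (0, 1)")
    offsets = np.asarray(hit_midpoints, dtype=float)
    if offsets.size == 0:
        return float("nan"), 1.0
    half_window = central_fraction * region_width / 2.0
    centre = region_width / 2.0
    k = int(np.sum(np.abs(offsets - centre) <= half_window))
    n = int(offsets.size)
    ratio = (k / n) / central_fraction
    p = binomtest(k, n, p=central_fraction, alternative="greater").pvalue
    return ratio, float(p)
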