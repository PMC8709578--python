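"""Peak-set statistics: tag distributions, fold enrichment, permutation test.

The overlap permutation test keeps one peak set fixed and repositions the
other uniformly on its own chromosomes (lengths preserved), counting how
often the randomized overlap reaches the observed one.  The p-value uses the
add-one estimator ``(1 + #{perm >= obs}) / (1 + n_perm)``, which never
returns zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomeSpec, center, common_sites_one, randomize_peaks
from .io_formats import PeakRecord

__all__ = [
    "PeakSetSummary",
    "OverlapTestResult",
    "summarize_peaks",
    "fold_enrichment",
    "count_common_a_peaks",
    "overlap_permutation_test",
]


@dataclass(frozen=True)
class PeakSetSummary:
    n_peaks: int
    tags_mean: float
    tags_q1: float
    tags_median: float
    tags_q3: float
    width_q1: float
    width_median: float
    width_q3: float

    def to_dict(self) -> dict[str, float]:
        return {
            "n_peaks": self.n_peaks,
            "tags_mean": self.tags_mean,
            "tags_q1": self.tags_q1,
            "tags_median": self.tags_median,
            "tags_q3": self.tags_q3,
            "width_q1": self.width_q1,
            "width_median": self.width_median,
            "width_q3": self.width_q3,
        }


def summarize_peaks(peaks: Sequence[PeakRecord]) -> PeakSetSummary:
    """Tags-per-peak and width quartiles (linear-interpolation quantiles)."""
    if not peaks:
        raise ValueError("empty peak set")
    if any(p.tags is None for p in peaks):
        raise ValueError("all peaks must carry tag counts")
    tags = np.array([p.tags for p in peaks], dtype=float)
    widths = np.array([p.width for p in peaks], dtype=float)
    tq = np.quantile(tags, [0.25, 0.5, 0.75])
    wq = np.quantile(widths, [0.25, 0.5, 0.75])
    return PeakSetSummary(
        n_peaks=len(peaks),
        tags_mean=float(tags.mean()),
        tags_q1=float(tq[0]),
        tags_median=float(tq[1]),
        tags_q3=float(tq[2]),
        width_q1=float(wq[0]),
        width_median=float(wq[1]),
        width_q3=float(wq[2]),
    )


def fold_enrichment(
    treat_tags: int,
    ctrl_tags: int,
    treat_libsize: int,
    ctrl_libsize: int,
    pseudocount: float = 1.0,
) -> float:
    """Treatment/control ratio of counts-per-million, pseudocount-guarded."""
    if treat_libsize <= 0 or ctrl_libsize <= 0:
        raise ValueError("library sizes must be > 0")
    treat_cpm = treat_tags / treat_libsize * 1e6
    ctrl_cpm = ctrl_tags / ctrl_libsize * 1e6
    return (treat_cpm + pseudocount) / (ctrl_cpm + pseudocount)


def count_common_a_peaks(
    set_a: Sequence[PeakRecord], set_b: Sequence[PeakRecord]
) -> int:
    """Number of distinct A-peaks common with B under the one-center rule.

    Vectorized equivalent of counting distinct first elements of
    ``common_sites_one(set_a, set_b)``; used in the permutation inner loop.
    """
    count = 0
    chroms = {p.chrom for p in set_a}
    b_by_chrom: dict[str, list[PeakRecord]] = {}
    for p in set_b:
        b_by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in chroms:
        a_peaks = [p for p in set_a if p.chrom == chrom]
        b_peaks = b_by_chrom.get(chrom, [])
        if not b_peaks:
            continue
        a_centers = np.array([center(p) for p in a_peaks])
        a_starts = np.array([p.start for p in a_peaks])
        a_ends = np.array([p.end for p in a_peaks])
        b_centers = np.sort(np.array([center(p) for p in b_peaks]))
        b_starts = np.sort(np.array([p.start for p in b_peaks]))
        b_ends = np.sort(np.array([p.end for p in b_peaks]))
        # center of a inside some b: coverage depth at a_center > 0
        depth = np.searchsorted(b_starts, a_centers, side="right") - np.searchsorted(
            b_ends, a_centers, side="right"
        )
        covered = depth > 0
        # some b center inside [a_start, a_end)
        n_inside = np.searchsorted(b_centers, a_ends - 1, side="right") - np.searchsorted(
            b_centers, a_starts, side="left"
        )
        count += int(np.sum(covered | (n_inside > 0)))
    return count


@dataclass(frozen=True)
class OverlapTestResult:
    observed_overlap: int
    permuted_overlaps: tuple[int, ...]
    p_value: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_overlap": self.observed_overlap,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "permuted_mean": float(np.mean(self.permuted_overlaps)),
        }


def overlap_permutation_test(
    set_a: Sequence[PeakRecord],
    set_b: Sequence[PeakRecord],
    genome: GenomeSpec,
    n_perm: int = 1000,
    seed: int = 0,
) -> OverlapTestResult:
    """Significance of the A/B overlap against randomized B placement."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = count_common_a_peaks(set_a, set_b)
    root = np.random.SeedSequence(seed)
    perms = []
    for child in root.spawn(n_perm):
        rng = np.random.default_rng(child)
        shuffled = randomize_peaks(set_b, genome, rng=rng)
        perms.append(count_common_a_peaks(set_a, shuffled))
    perms_arr = np.array(perms)
    p = (1 + int(np.sum(perms_arr >= observed))) / (1 + n_perm)
    return OverlapTestResult(
        observed_overlap=observed,
        permuted_overlaps=tuple(int(x) for x in perms),
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )
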