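"""Interval algebra: overlap rules, anchor reduction, TSS annotation.

Two overlap conventions are implemented, both phrased in terms of peak
*centers* (summit when available, midpoint otherwise):

``one-center``
    two peaks are common if the center of at least one lies inside the other.
``each-center``
    two features overlap only if the center of each lies inside the other;
    this is the stricter rule used when combining anchors with peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import Interval, PeakRecord, TssRecord

__all__ = [
    "GenomeSpec",
    "IntervalIndex",
    "RegionEvidence",
    "center",
    "center_in",
    "common_sites_one",
    "common_sites_each",
    "reduce_merge",
    "three_way_overlap",
    "nearest_tss",
    "randomize_peaks",
    "UNASSIGNED",
]

UNASSIGNED = ("", 0)  # sentinel for regions with no same-chromosome TSS


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome names and lengths; bounds random placement."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must have at least one chromosome")
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be > 0")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeSpec":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass
class RegionEvidence:
    """One candidate regulatory region with its accumulated evidence flags."""

    region_id: str
    interval: Interval
    anchor_present: bool = False
    er_present: bool = False
    hsf1_present: bool = False
    ere_present: bool = False
    hse_present: bool = False
    mode: object | None = None  # set by classify.classify_regions


class IntervalIndex:
    """Per-chromosome stabbing/overlap queries over a fixed interval set.

    Results are independent of insertion order.  Backed by sorted numpy
    arrays; queries scan a start-sorted window, which is ample at the scales
    this package targets.
    """

    def __init__(self, intervals: Sequence) -> None:
        self._items = list(intervals)
        by_chrom: dict[str, list[int]] = {}
        for i, iv in enumerate(self._items):
            by_chrom.setdefault(iv.chrom, []).append(i)
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, idxs in by_chrom.items():
            starts = np.array([self._items[i].start for i in idxs])
            ends = np.array([self._items[i].end for i in idxs])
            order = np.argsort(starts, kind="stable")
            self._chrom[chrom] = (
                starts[order],
                ends[order],
                np.array(idxs)[order],
            )

    def containing_point(self, chrom: str, pos: int) -> list:
        """Intervals whose half-open span contains ``pos``."""
        entry = self._chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, idxs = entry
        hit = (starts <= pos) & (pos < ends)
        return [self._items[i] for i in idxs[hit]]

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        entry = self._chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, idxs = entry
        hit = (starts < end) & (ends > start)
        return [self._items[i] for i in idxs[hit]]


def center(feature) -> int:
    """Center of a feature: summit position when present, else midpoint."""
    offset = getattr(feature, "summit_offset", None)
    if offset is not None:
        return feature.start + offset
    return (feature.start + feature.end) // 2


def center_in(a, b) -> bool:
    """True iff ``a`` and ``b`` share a chromosome and center(a) lies in b."""
    return a.chrom == b.chrom and b.start <= center(a) < b.end


def common_sites_one(
    set_a: Sequence[PeakRecord], set_b: Sequence[PeakRecord]
) -> list[tuple[PeakRecord, PeakRecord]]:
    """Pairs (a, b) common under the one-center rule, each emitted once."""
    index_b = IntervalIndex(set_b)
    pos_b: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in set_b}:
        members = [p for p in set_b if p.chrom == chrom]
        centers = np.array([center(p) for p in members])
        order = np.argsort(centers, kind="stable")
        pos_b[chrom] = (centers[order], np.array(members, dtype=object)[order])

    pairs: list[tuple[PeakRecord, PeakRecord]] = []
    seen: set[tuple[int, int]] = set()
    for a in set_a:
        partners = list(index_b.containing_point(a.chrom, center(a)))
        entry = pos_b.get(a.chrom)
        if entry is not None:
            centers, members = entry
            lo = np.searchsorted(centers, a.start, side="left")
            hi = np.searchsorted(centers, a.end - 1, side="right")
            partners.extend(members[lo:hi])
        for b in partners:
            key = (id(a), id(b))
            if key not in seen:
                seen.add(key)
                pairs.append((a, b))
    return pairs


def common_sites_each(a: PeakRecord, b: PeakRecord) -> bool:
    """Strict overlap: the center of each feature lies within the other."""
    return center_in(a, b) and center_in(b, a)


def reduce_merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping *and adjacent* intervals per chromosome.

    Output is sorted by (chrom, start) and pairwise disjoint; total covered
    base pairs are conserved.
    """
    items = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[Interval] = []
    for iv in items:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def _attached(peak: PeakRecord, anchor: Interval) -> bool:
    # each-center rule between a peak and an anchor (anchor center = midpoint)
    return center_in(peak, anchor) and center_in(anchor, peak.interval)


def three_way_overlap(
    anchors: Sequence[Interval],
    er_peaks: Sequence[PeakRecord],
    hsf1_peaks: Sequence[PeakRecord],
    peak_rule: str = "each",
) -> list[RegionEvidence]:
    """Combine reduced anchors with two ChIP peak sets into evidence regions.

    Every anchor becomes a region; a factor is flagged present when one of
    its peaks and the anchor mutually contain each other's centers.  Peaks
    attached to no anchor are emitted as peak-only regions, with ER/HSF1
    cobinding between the two ChIP sets resolved by ``peak_rule``
    (``"each"``, the default, or the laxer ``"one"``).

    ``anchors`` must already be reduced; overlapping anchors are an
    invariant breach and raise ``AssertionError``.
    """
    if peak_rule not in ("each", "one"):
        raise ValueError(f"unknown peak rule {peak_rule!r}")
    anchors = sorted(anchors, key=lambda iv: (iv.chrom, iv.start))
    for prev, cur in zip(anchors, anchors[1:]):
        assert not (
            prev.chrom == cur.chrom and cur.start < prev.end
        ), f"anchors not reduced: {prev} overlaps {cur}"

    regions: list[RegionEvidence] = []
    attached_er: set[int] = set()
    attached_hsf1: set[int] = set()

    for i, anchor in enumerate(anchors):
        ev = RegionEvidence(
            region_id=f"anchor_{i:05d}", interval=anchor, anchor_present=True
        )
        for j, p in enumerate(er_peaks):
            if _attached(p, anchor):
                ev.er_present = True
                attached_er.add(j)
        for j, p in enumerate(hsf1_peaks):
            if _attached(p, anchor):
                ev.hsf1_present = True
                attached_hsf1.add(j)
        regions.append(ev)

    free_er = [p for j, p in enumerate(er_peaks) if j not in attached_er]
    free_hsf1 = [p for j, p in enumerate(hsf1_peaks) if j not in attached_hsf1]

    if peak_rule == "each":
        cobound = [
            (a, b)
            for a in free_er
            for b in free_hsf1
            if common_sites_each(a, b)
        ]
    else:
        cobound = common_sites_one(free_er, free_hsf1)
    in_pair_er = {id(a) for a, _ in cobound}
    in_pair_hsf1 = {id(b) for _, b in cobound}

    for k, (a, b) in enumerate(cobound):
        span = Interval(a.chrom, min(a.start, b.start), max(a.end, b.end))
        regions.append(
            RegionEvidence(
                region_id=f"pair_{k:05d}",
                interval=span,
                er_present=True,
                hsf1_present=True,
            )
        )
    n = 0
    for p in free_er:
        if id(p) not in in_pair_er:
            regions.append(
                RegionEvidence(
                    region_id=f"er_{n:05d}", interval=p.interval, er_present=True
                )
            )
            n += 1
    n = 0
    for p in free_hsf1:
        if id(p) not in in_pair_hsf1:
            regions.append(
                RegionEvidence(
                    region_id=f"hsf1_{n:05d}",
                    interval=p.interval,
                    hsf1_present=True,
                )
            )
            n += 1
    return regions


def nearest_tss(
    region: Interval, tss_table: Sequence[TssRecord]
) -> tuple[str, int]:
    """Gene with the TSS nearest the region midpoint, with signed distance.

    Distance is signed by gene strand (negative = upstream of the TSS).
    Ties are broken by lexicographically smaller gene_id.  Returns the
    ``UNASSIGNED`` sentinel when no same-chromosome TSS exists; raises
    ``ValueError`` on an empty table.
    """
    if not tss_table:
        raise ValueError("empty TSS table")
    mid = region.midpoint
    best: TssRecord | None = None
    best_dist = 0
    for rec in tss_table:
        if rec.chrom != region.chrom:
            continue
        d = abs(mid - rec.tss)
        if (
            best is None
            or d < best_dist
            or (d == best_dist and rec.gene_id < best.gene_id)
        ):
            best, best_dist = rec, d
    if best is None:
        return UNASSIGNED
    signed = mid - best.tss if best.strand == "+" else best.tss - mid
    return best.gene_id, signed


def randomize_peaks(
    peaks: Sequence[PeakRecord],
    genome: GenomeSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[PeakRecord]:
    """Reposition each peak uniformly on its own chromosome, width preserved.

    Summit offsets stay fixed relative to the new start.  Deterministic for
    a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths = genome.lengths
    out: list[PeakRecord] = []
    for p in peaks:
        if p.chrom not in lengths:
            raise ValueError(f"chromosome {p.chrom!r} not in genome spec")
        room = lengths[p.chrom] - p.width
        if room < 0:
            raise ValueError(
                f"peak {p.name} ({p.width} bp) longer than {p.chrom} "
                f"({lengths[p.chrom]} bp)"
            )
        start = int(rng.integers(0, room + 1))
        out.append(
            PeakRecord(
                p.chrom,
                start,
                start + p.width,
                p.name,
                p.score,
                p.summit_offset,
                p.tags,
                p.fold_enrichment,
            )
        )
    return out
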