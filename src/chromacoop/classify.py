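"""Binding-mode decision table, gene aggregation, and gene-set comparison.

A region with both factors and both motifs is *cobinding*; with both factors
but a single motif it is *tethering* (the factor lacking its motif is the
tethered one); with both factors and no motif it is *indirect*.  A single
factor sitting on its own motif is *canonical*; anything else is
*unclassified*.  Indirect regions are kept in the output table for audit but
never counted among the three cooperation categories.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .intervals import RegionEvidence, UNASSIGNED, nearest_tss, three_way_overlap
from .io_formats import Interval, PeakRecord, TssRecord
from .motifs import DEFAULT_P_THRESHOLD, PWM, motif_present

__all__ = [
    "BindingMode",
    "GeneModeRow",
    "GeneModeTable",
    "ModeSummary",
    "classify_region",
    "classify_regions",
    "annotate_motifs",
    "aggregate_by_gene",
    "summarize_modes",
    "compare_gene_sets",
    "run_pipeline",
    "PipelineResult",
]


class BindingMode(enum.Enum):
    CANONICAL_ER = "canonical_ER"
    CANONICAL_HSF1 = "canonical_HSF1"
    COBINDING = "cobinding"
    TETHERING_ER = "tethering_ER_anchor"      # ERα lacks its motif, recruited by HSF1
    TETHERING_HSF1 = "tethering_HSF1_anchor"  # HSF1 lacks its motif, recruited by ERα
    INDIRECT = "indirect"
    UNCLASSIFIED = "unclassified"


TETHERING_MODES = frozenset({BindingMode.TETHERING_ER, BindingMode.TETHERING_HSF1})


def classify_region(ev: RegionEvidence) -> BindingMode:
    """Assign one binding mode from the evidence flags (total function)."""
    er, hsf1 = ev.er_present, ev.hsf1_present
    ere, hse = ev.ere_present, ev.hse_present
    if er and hsf1:
        if ere and hse:
            return BindingMode.COBINDING
        if ere:
            return BindingMode.TETHERING_HSF1
        if hse:
            return BindingMode.TETHERING_ER
        return BindingMode.INDIRECT
    if er:
        return BindingMode.CANONICAL_ER if ere else BindingMode.UNCLASSIFIED
    if hsf1:
        return BindingMode.CANONICAL_HSF1 if hse else BindingMode.UNCLASSIFIED
    return BindingMode.UNCLASSIFIED


def classify_regions(regions: Sequence[RegionEvidence]) -> list[RegionEvidence]:
    """Set ``mode`` on every region (in place) and return the list."""
    for ev in regions:
        ev.mode = classify_region(ev)
    return list(regions)


def annotate_motifs(
    regions: Sequence[RegionEvidence],
    genome: Mapping[str, str],
    ere_pwm: PWM,
    hse_pwm: PWM,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[RegionEvidence]:
    """Set the ERE/HSE presence flags by scanning each region's sequence.

    Sequences are taken from ``genome`` (chromosome name -> sequence) over
    the full region interval, clamped to chromosome bounds.
    """
    for ev in regions:
        chrom_seq = genome.get(ev.interval.chrom)
        if chrom_seq is None:
            raise KeyError(f"chromosome {ev.interval.chrom!r} not in genome")
        seq = chrom_seq[max(0, ev.interval.start) : ev.interval.end]
        ev.ere_present = motif_present(ere_pwm, seq, p_threshold)[0]
        ev.hse_present = motif_present(hse_pwm, seq, p_threshold)[0]
    return list(regions)


@dataclass(frozen=True)
class GeneModeRow:
    gene_id: str
    mode: BindingMode
    evidence: RegionEvidence
    distance_to_tss: int


@dataclass
class GeneModeTable:
    """One row per (gene, mode, region); a gene may carry several modes."""

    rows: list[GeneModeRow] = field(default_factory=list)

    def genes_with_mode(self, *modes: BindingMode) -> set[str]:
        wanted = set(modes)
        return {r.gene_id for r in self.rows if r.mode in wanted}

    def mode_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.rows:
            out[r.mode.value] = out.get(r.mode.value, 0) + 1
        return out


def aggregate_by_gene(
    regions: Sequence[RegionEvidence], tss_table: Sequence[TssRecord]
) -> GeneModeTable:
    """Assign each classified region to its nearest-TSS gene.

    Unclassified regions and regions with no same-chromosome TSS are
    dropped; indirect regions are retained for audit.  Rows are
    deduplicated at (gene, mode, region) granularity.
    """
    rows: list[GeneModeRow] = []
    seen: set[tuple[str, BindingMode, str]] = set()
    for ev in regions:
        if ev.mode is None:
            raise ValueError(f"region {ev.region_id} not classified yet")
        if ev.mode is BindingMode.UNCLASSIFIED:
            continue
        gene_id, dist = nearest_tss(ev.interval, tss_table)
        if (gene_id, dist) == UNASSIGNED:
            continue
        key = (gene_id, ev.mode, ev.region_id)
        if key in seen:
            continue
        seen.add(key)
        rows.append(GeneModeRow(gene_id, ev.mode, ev, dist))
    return GeneModeTable(rows=rows)


@dataclass(frozen=True)
class ModeSummary:
    """Gene-level counts for the three cooperation categories."""

    canonical_er_genes: frozenset[str]
    canonical_hsf1_genes: frozenset[str]
    canonical_coregulated_genes: frozenset[str]
    cobinding_genes: frozenset[str]
    tethering_genes: frozenset[str]
    direct_cooperation_genes: frozenset[str]

    def counts(self) -> dict[str, int]:
        return {
            "canonical_ER_genes": len(self.canonical_er_genes),
            "canonical_HSF1_genes": len(self.canonical_hsf1_genes),
            "canonical_coregulated_genes": len(self.canonical_coregulated_genes),
            "cobinding_genes": len(self.cobinding_genes),
            "tethering_genes": len(self.tethering_genes),
            "direct_cooperation_genes": len(self.direct_cooperation_genes),
        }


def summarize_modes(table: GeneModeTable) -> ModeSummary:
    """Gene-level summary: canonical co-regulation, cobinding, tethering.

    Canonical co-regulation = genes carrying at least one canonical region
    for *each* factor; direct cooperation = union of the cobinding and
    tethering gene sets.
    """
    can_er = table.genes_with_mode(BindingMode.CANONICAL_ER)
    can_hsf1 = table.genes_with_mode(BindingMode.CANONICAL_HSF1)
    cobind = table.genes_with_mode(BindingMode.COBINDING)
    tether = table.genes_with_mode(*TETHERING_MODES)
    return ModeSummary(
        canonical_er_genes=frozenset(can_er),
        canonical_hsf1_genes=frozenset(can_hsf1),
        canonical_coregulated_genes=frozenset(can_er & can_hsf1),
        cobinding_genes=frozenset(cobind),
        tethering_genes=frozenset(tether),
        direct_cooperation_genes=frozenset(cobind | tether),
    )


def compare_gene_sets(
    set_a: set[str], set_b: set[str], set_c: set[str]
) -> dict[str, int]:
    """All seven Venn region counts for three gene sets.

    Keys: ``a_only``, ``b_only``, ``c_only``, ``ab``, ``ac``, ``bc``,
    ``abc``; the values sum to ``|A ∪ B ∪ C|``.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    ab = (a & b) - abc
    ac = (a & c) - abc
    bc = (b & c) - abc
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab": len(ab),
        "ac": len(ac),
        "bc": len(bc),
        "abc": len(abc),
    }


@dataclass
class PipelineResult:
    regions: list[RegionEvidence]
    table: GeneModeTable
    summary: ModeSummary


def run_pipeline(
    er_peaks: Sequence[PeakRecord],
    hsf1_peaks: Sequence[PeakRecord],
    anchors: Sequence[Interval],
    genome: Mapping[str, str],
    tss_table: Sequence[TssRecord],
    ere_pwm: PWM,
    hse_pwm: PWM,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    peak_rule: str = "each",
) -> PipelineResult:
    """Full classification: overlap -> motif flags -> modes -> gene table.

    ``anchors`` are raw anchor intervals (e.g. both sides of every
    interaction); they are reduced here before the three-way overlap.
    """
    from .intervals import reduce_merge

    reduced = reduce_merge(anchors)
    regions = three_way_overlap(reduced, er_peaks, hsf1_peaks, peak_rule)
    annotate_motifs(regions, genome, ere_pwm, hse_pwm, p_threshold)
    classify_regions(regions)
    table = aggregate_by_gene(regions, tss_table)
    return PipelineResult(regions=regions, table=table, summary=summarize_modes(table))
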