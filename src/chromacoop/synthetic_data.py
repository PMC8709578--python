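"""Ground-truth simulator for the whole pipeline.

Regions are laid out in well-separated slots (one per region, one gene per
slot) so every overlap, motif and nearest-TSS call is unambiguous by
construction.  Each requested binding mode is realized literally: a
cobinding region gets both factors' peaks over one anchor plus one planted
ERE and one planted HSE; a tethering region gets both peaks but a single
motif; decoys get a peak and no motif.  Background sequence for each region
is rejection-sampled until a scan at the configured threshold reproduces the
intended motif flags exactly, so planted truth is recovered at 100% when the
site mutation rate is zero.

All randomness flows from one seed through named substreams (placement,
sequence, tags), so reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import BindingMode
from .intervals import GenomeSpec
from .io_formats import (
    AnchorPairRecord,
    Interval,
    MotifCountMatrix,
    PeakRecord,
    TssRecord,
    load_builtin_motifs,
    write_anchor_pairs,
    write_fasta,
    write_genome_spec,
    write_peaks,
    write_tss,
)
from .motifs import DEFAULT_P_THRESHOLD, build_pwm, motif_present

__all__ = [
    "SimulationSpec",
    "NullPairSpec",
    "RegionTruth",
    "SimulatedDataset",
    "simulate",
    "simulate_null_pair",
    "write_dataset",
    "read_manifest",
]

BASES = "ACGT"
SLOT = 30_000  # per-region slot; regions and genes never interact across slots


@dataclass(frozen=True)
class SimulationSpec:
    """Everything the generator needs; all counts may be zero."""

    seed: int = 0
    genome: GenomeSpec | None = None  # auto-sized single chromosome if None
    n_canonical_er: int = 10
    n_canonical_hsf1: int = 10
    n_cobinding: int = 10
    n_tethering_er: int = 10
    n_tethering_hsf1: int = 10
    n_indirect: int = 10
    n_decoy: int = 5
    peak_width_min: int = 150
    peak_width_max: int = 400
    anchor_width_min: int = 600
    anchor_width_max: int = 1000
    loop_span_min: int = 8_000
    loop_span_max: int = 12_000
    gene_offset_min: int = 1_000
    gene_offset_max: int = 3_000
    mutation_rate: float = 0.0
    gc_fraction: float = 0.4
    tag_mean: float = 50.0
    tag_dispersion: float = 5.0
    enrichment_factor: float = 4.0
    frac_e2_responsive: float = 0.5
    scan_p_threshold: float = DEFAULT_P_THRESHOLD

    def __post_init__(self) -> None:
        counts = (
            self.n_canonical_er,
            self.n_canonical_hsf1,
            self.n_cobinding,
            self.n_tethering_er,
            self.n_tethering_hsf1,
            self.n_indirect,
            self.n_decoy,
        )
        if any(c < 0 for c in counts):
            raise ValueError("region counts must be >= 0")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be > 0")
        if not 0 <= self.frac_e2_responsive <= 1:
            raise ValueError("frac_e2_responsive must be in [0, 1]")
        if not 0 < self.peak_width_min <= self.peak_width_max:
            raise ValueError("bad peak width range")
        if self.anchor_width_min < self.peak_width_max:
            raise ValueError("anchors must be at least as wide as peaks")

    @property
    def n_regions(self) -> int:
        return (
            self.n_canonical_er
            + self.n_canonical_hsf1
            + self.n_cobinding
            + self.n_tethering_er
            + self.n_tethering_hsf1
            + self.n_indirect
            + self.n_decoy
        )

    def to_json(self) -> str:
        d = asdict(self)
        if self.genome is not None:
            d["genome"] = list(self.genome.chromosomes)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass(frozen=True)
class NullPairSpec:
    """Two unrelated peak sets, for permutation-test calibration."""

    seed: int
    genome: GenomeSpec
    n_a: int = 100
    n_b: int = 100
    width_min: int = 150
    width_max: int = 400


@dataclass(frozen=True)
class RegionTruth:
    region_id: str
    mode: BindingMode
    chrom: str
    start: int
    end: int
    anchor: bool
    er: bool
    hsf1: bool
    ere: bool
    hse: bool
    gene_id: str
    ere_pos: int | None
    ere_strand: str | None
    hse_pos: int | None
    hse_strand: str | None
    expected_tags_ctrl: float
    expected_tags_e2: float

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


@dataclass
class SimulatedDataset:
    spec: SimulationSpec
    genome: GenomeSpec
    genome_seqs: dict[str, str]
    er_peaks: list[PeakRecord]
    hsf1_peaks: list[PeakRecord]
    anchor_pairs: list[AnchorPairRecord]
    tss: list[TssRecord]
    tag_table: pd.DataFrame
    manifest: list[RegionTruth]


# mode -> (er peak, hsf1 peak, plant ere, plant hse, use anchor)
_MODE_PLAN: dict[BindingMode, tuple[bool, bool, bool, bool, bool]] = {
    BindingMode.CANONICAL_ER: (True, False, True, False, False),
    BindingMode.CANONICAL_HSF1: (False, True, False, True, False),
    BindingMode.COBINDING: (True, True, True, True, True),
    BindingMode.TETHERING_HSF1: (True, True, True, False, True),  # ERE only
    BindingMode.TETHERING_ER: (True, True, False, True, True),    # HSE only
    BindingMode.INDIRECT: (True, True, False, False, True),
}


def _consensus(counts: MotifCountMatrix) -> str:
    return "".join(BASES[i] for i in counts.to_array().argmax(axis=1))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=probs)])


def _mutate(site: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return site
    out = []
    for base in site:
        if rng.random() < rate:
            out.append(rng.choice([b for b in BASES if b != base]))
        else:
            out.append(base)
    return "".join(out)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate(
    spec: SimulationSpec,
    motif_counts: dict[str, MotifCountMatrix] | None = None,
) -> SimulatedDataset:
    """Generate a full dataset with a per-region truth manifest.

    ``motif_counts`` must provide ``ERE`` and ``HSE`` count matrices; the
    packaged toy matrices are used by default.
    """
    if motif_counts is None:
        motif_counts = load_builtin_motifs()
    ere_counts, hse_counts = motif_counts["ERE"], motif_counts["HSE"]
    ere_pwm = build_pwm(ere_counts)
    hse_pwm = build_pwm(hse_counts)
    consensus = {"ERE": _consensus(ere_counts), "HSE": _consensus(hse_counts)}

    root = np.random.SeedSequence(spec.seed)
    s_place, s_seq, s_tags = root.spawn(3)
    rng_place = np.random.default_rng(s_place)
    rng_seq = np.random.default_rng(s_seq)
    rng_tags = np.random.default_rng(s_tags)

    # --- slot layout across the genome -----------------------------------
    n_regions = spec.n_regions
    if spec.genome is None:
        genome = GenomeSpec.from_pairs([("chrS", max(1, n_regions) * SLOT)])
    else:
        genome = spec.genome
        capacity = sum(length // SLOT for _, length in genome.chromosomes)
        if capacity < n_regions:
            raise ValueError(
                f"genome too small for {n_regions} regions: need at least "
                f"{n_regions * SLOT} bp in {SLOT} bp slots, have capacity "
                f"for {capacity}"
            )
    slots: list[tuple[str, int]] = []  # (chrom, slot start)
    for chrom, length in genome.chromosomes:
        for k in range(length // SLOT):
            slots.append((chrom, k * SLOT))
            if len(slots) == n_regions:
                break
        if len(slots) == n_regions:
            break

    mode_sequence: list[BindingMode] = (
        [BindingMode.CANONICAL_ER] * spec.n_canonical_er
        + [BindingMode.CANONICAL_HSF1] * spec.n_canonical_hsf1
        + [BindingMode.COBINDING] * spec.n_cobinding
        + [BindingMode.TETHERING_ER] * spec.n_tethering_er
        + [BindingMode.TETHERING_HSF1] * spec.n_tethering_hsf1
        + [BindingMode.INDIRECT] * spec.n_indirect
        + [BindingMode.UNCLASSIFIED] * spec.n_decoy
    )

    # --- background genome ------------------------------------------------
    genome_seqs = {
        chrom: list(_random_seq(rng_seq, length, spec.gc_fraction))
        for chrom, length in genome.chromosomes
    }

    er_peaks: list[PeakRecord] = []
    hsf1_peaks: list[PeakRecord] = []
    anchor_pairs: list[AnchorPairRecord] = []
    tss: list[TssRecord] = []
    manifest: list[RegionTruth] = []
    tag_rows: list[dict] = []

    def make_peak(
        prefix: str, idx: int, chrom: str, centre: int
    ) -> tuple[PeakRecord, dict]:
        width = int(
            rng_place.integers(spec.peak_width_min, spec.peak_width_max + 1)
        )
        jitter = int(rng_place.integers(-(width // 4), width // 4 + 1))
        start = centre - width // 2 + jitter
        summit = centre - start  # summit sits on the region centre
        responsive = bool(rng_tags.random() < spec.frac_e2_responsive)
        e2_mean = spec.tag_mean * (spec.enrichment_factor if responsive else 1.0)
        ctrl = _nb_draw(rng_tags, spec.tag_mean, spec.tag_dispersion)
        e2 = _nb_draw(rng_tags, e2_mean, spec.tag_dispersion)
        peak = PeakRecord(
            chrom,
            start,
            start + width,
            f"{prefix}_{idx:05d}",
            score=float(e2),
            summit_offset=summit,
            tags=e2,
        )
        row = {
            "peak": peak.name,
            "factor": prefix,
            "tags_ctrl": ctrl,
            "tags_e2": e2,
            "e2_responsive": responsive,
            "mean_ctrl": spec.tag_mean,
            "mean_e2": e2_mean,
        }
        return peak, row

    def plant_region_sequence(
        region: Interval,
        want_ere: bool,
        want_hse: bool,
    ) -> tuple[tuple[int, str] | None, tuple[int, str] | None]:
        """(Re)write region background until motif flags match intent.

        Returns planted (offset, strand) per motif, offsets relative to the
        region start, before mutation.  Mutation is applied afterwards.
        """
        chrom_list = genome_seqs[region.chrom]
        width = region.width
        quarter = width // 4
        for _attempt in range(200):
            background = _random_seq(rng_seq, width, spec.gc_fraction)
            seq = list(background)
            ere_site = hse_site = None
            # plant inside the central 50%, ERE left of centre, HSE right,
            # so two planted sites can never collide
            if want_ere:
                span = quarter + width // 4 - len(consensus["ERE"])
                off = quarter + int(rng_seq.integers(0, max(1, span)))
                strand = "+" if rng_seq.random() < 0.5 else "-"
                site = consensus["ERE"]
                if strand == "-":
                    site = _revcomp(site)
                seq[off : off + len(site)] = site
                ere_site = (off, strand)
            if want_hse:
                span = width // 4 - len(consensus["HSE"]) - 1
                off = width // 2 + 1 + int(rng_seq.integers(0, max(1, span)))
                strand = "+" if rng_seq.random() < 0.5 else "-"
                site = consensus["HSE"]
                if strand == "-":
                    site = _revcomp(site)
                seq[off : off + len(site)] = site
                hse_site = (off, strand)
            candidate = "".join(seq)
            got_ere = motif_present(ere_pwm, candidate, spec.scan_p_threshold)[0]
            got_hse = motif_present(hse_pwm, candidate, spec.scan_p_threshold)[0]
            if got_ere == want_ere and got_hse == want_hse:
                final = list(candidate)
                for site_info, name in ((ere_site, "ERE"), (hse_site, "HSE")):
                    if site_info is not None:
                        off = site_info[0]
                        L = len(consensus[name])
                        mutated = _mutate(
                            candidate[off : off + L], spec.mutation_rate, rng_seq
                        )
                        final[off : off + L] = mutated
                chrom_list[region.start : region.end] = "".join(final)
                return ere_site, hse_site
        raise RuntimeError(
            f"could not realize motif flags (ere={want_ere}, hse={want_hse}) "
            f"in {region.chrom}:{region.start}-{region.end} after 200 tries"
        )

    n_er = n_hsf1 = 0
    for i, (mode, (chrom, slot_start)) in enumerate(zip(mode_sequence, slots)):
        centre = slot_start + 5_000
        gene_id = f"gene_{i:05d}"
        gene_offset = int(
            rng_place.integers(spec.gene_offset_min, spec.gene_offset_max + 1)
        )
        strand = "+" if rng_place.random() < 0.5 else "-"
        tss.append(TssRecord(gene_id, chrom, strand, centre + gene_offset))

        if mode is BindingMode.UNCLASSIFIED:
            want_er = i % 2 == 0  # alternate ER / HSF1 decoys
            want_hsf1 = not want_er
            want_ere = want_hse = False
            use_anchor = False
        else:
            want_er, want_hsf1, want_ere, want_hse, use_anchor = _MODE_PLAN[mode]
            if mode in (BindingMode.CANONICAL_ER, BindingMode.CANONICAL_HSF1):
                use_anchor = i % 2 == 0  # exercise both evidence paths

        region_peaks: list[PeakRecord] = []
        if want_er:
            p, row = make_peak("er", n_er, chrom, centre)
            n_er += 1
            er_peaks.append(p)
            region_peaks.append(p)
            tag_rows.append(row)
        if want_hsf1:
            p, row = make_peak("hsf1", n_hsf1, chrom, centre)
            n_hsf1 += 1
            hsf1_peaks.append(p)
            region_peaks.append(p)
            tag_rows.append(row)

        if use_anchor:
            aw = int(
                rng_place.integers(spec.anchor_width_min, spec.anchor_width_max + 1)
            )
            anchor = Interval(chrom, centre - aw // 2, centre - aw // 2 + aw)
            span = int(
                rng_place.integers(spec.loop_span_min, spec.loop_span_max + 1)
            )
            partner_w = int(
                rng_place.integers(spec.anchor_width_min, spec.anchor_width_max + 1)
            )
            partner = Interval(
                chrom, centre + span, centre + span + partner_w
            )
            anchor_pairs.append(AnchorPairRecord(anchor, partner))
            region = anchor
        elif len(region_peaks) == 2:
            region = Interval(
                chrom,
                min(p.start for p in region_peaks),
                max(p.end for p in region_peaks),
            )
        else:
            region = region_peaks[0].interval

        ere_site, hse_site = plant_region_sequence(region, want_ere, want_hse)
        manifest.append(
            RegionTruth(
                region_id=f"truth_{i:05d}",
                mode=mode,
                chrom=region.chrom,
                start=region.start,
                end=region.end,
                anchor=use_anchor,
                er=want_er,
                hsf1=want_hsf1,
                ere=want_ere,
                hse=want_hse,
                gene_id=gene_id,
                ere_pos=None if ere_site is None else ere_site[0],
                ere_strand=None if ere_site is None else ere_site[1],
                hse_pos=None if hse_site is None else hse_site[0],
                hse_strand=None if hse_site is None else hse_site[1],
                expected_tags_ctrl=spec.tag_mean,
                expected_tags_e2=float(
                    np.mean([r["mean_e2"] for r in tag_rows[-len(region_peaks):]])
                )
                if region_peaks
                else 0.0,
            )
        )

    tag_table = pd.DataFrame(
        tag_rows,
        columns=[
            "peak",
            "factor",
            "tags_ctrl",
            "tags_e2",
            "e2_responsive",
            "mean_ctrl",
            "mean_e2",
        ],
    )
    return SimulatedDataset(
        spec=spec,
        genome=genome,
        genome_seqs={c: "".join(s) for c, s in genome_seqs.items()},
        er_peaks=er_peaks,
        hsf1_peaks=hsf1_peaks,
        anchor_pairs=anchor_pairs,
        tss=tss,
        tag_table=tag_table,
        manifest=manifest,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_null_pair(spec: NullPairSpec) -> tuple[list[PeakRecord], list[PeakRecord]]:
    """Two peak sets placed independently and uniformly — no relationship."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    chroms = spec.genome.chromosomes
    total = spec.genome.total_length
    weights = np.array([l for _, l in chroms], dtype=float) / total

    def one_set(prefix: str, n: int) -> list[PeakRecord]:
        peaks = []
        for i in range(n):
            ci = int(rng.choice(len(chroms), p=weights))
            chrom, length = chroms[ci]
            width = int(rng.integers(spec.width_min, spec.width_max + 1))
            if width > length:
                raise ValueError(f"peak width {width} exceeds {chrom} length")
            start = int(rng.integers(0, length - width + 1))
            peaks.append(
                PeakRecord(chrom, start, start + width, f"{prefix}_{i:05d}")
            )
        return peaks

    return one_set("a", spec.n_a), one_set("b", spec.n_b)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_MANIFEST_HEADER = (
    "region_id\tmode\tchrom\tstart\tend\tanchor\ter\thsf1\tere\thse\t"
    "gene_id\tere_pos\tere_strand\thse_pos\thse_strand\t"
    "expected_tags_ctrl\texpected_tags_e2"
)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact as plain text; returns {label: path}."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "er_peaks": out / "er_peaks.narrowPeak",
        "hsf1_peaks": out / "hsf1_peaks.narrowPeak",
        "anchors": out / "anchors.bedpe",
        "genome_fasta": out / "genome.fa",
        "chrom_sizes": out / "chrom.sizes",
        "tss": out / "tss.tsv",
        "tags": out / "tags.tsv",
        "manifest": out / "manifest.tsv",
        "spec": out / "simulation_spec.json",
    }
    write_peaks(ds.er_peaks, paths["er_peaks"], "narrowPeak")
    write_peaks(ds.hsf1_peaks, paths["hsf1_peaks"], "narrowPeak")
    write_anchor_pairs(ds.anchor_pairs, paths["anchors"])
    write_fasta(ds.genome_seqs, paths["genome_fasta"])
    write_genome_spec(ds.genome.chromosomes, paths["chrom_sizes"])
    write_tss(ds.tss, paths["tss"])
    ds.tag_table.to_csv(paths["tags"], sep="\t", index=False)
    with open(paths["manifest"], "wt", encoding="utf-8") as fh:
        fh.write(_MANIFEST_HEADER + "\n")
        for t in ds.manifest:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        t.region_id,
                        t.mode.value,
                        t.chrom,
                        t.start,
                        t.end,
                        int(t.anchor),
                        int(t.er),
                        int(t.hsf1),
                        int(t.ere),
                        int(t.hse),
                        t.gene_id,
                        "." if t.ere_pos is None else t.ere_pos,
                        "." if t.ere_strand is None else t.ere_strand,
                        "." if t.hse_pos is None else t.hse_pos,
                        "." if t.hse_strand is None else t.hse_strand,
                        f"{t.expected_tags_ctrl:g}",
                        f"{t.expected_tags_e2:g}",
                    )
                )
                + "\n"
            )
    with open(paths["spec"], "wt", encoding="utf-8") as fh:
        fh.write(ds.spec.to_json() + "\n")
    return paths


def read_manifest(path: str | Path) -> list[RegionTruth]:
    truths = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        assert header.rstrip("\n") == _MANIFEST_HEADER, "unexpected manifest header"
        for line in fh:
            c = line.rstrip("\n").split("\t")
            truths.append(
                RegionTruth(
                    region_id=c[0],
                    mode=BindingMode(c[1]),
                    chrom=c[2],
                    start=int(c[3]),
                    end=int(c[4]),
                    anchor=bool(int(c[5])),
                    er=bool(int(c[6])),
                    hsf1=bool(int(c[7])),
                    ere=bool(int(c[8])),
                    hse=bool(int(c[9])),
                    gene_id=c[10],
                    ere_pos=None if c[11] == "." else int(c[11]),
                    ere_strand=None if c[12] == "." else c[12],
                    hse_pos=None if c[13] == "." else int(c[13]),
                    hse_strand=None if c[14] == "." else c[14],
                    expected_tags_ctrl=float(c[15]),
                    expected_tags_e2=float(c[16]),
                )
            )
    return truths
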