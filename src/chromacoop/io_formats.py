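"""Readers and writers for the plain-text formats the pipeline touches.

All internal coordinates are 0-based, half-open (BED convention).  GFF/GTF
inputs are converted at the boundary: 1-based starts have 1 subtracted, and
for minus-strand genes the TSS is the feature end.  Chromosome names are kept
verbatim — no ``chr`` prefix normalization is ever applied.

narrowPeak dialect notes
------------------------
Column 10 (the summit) is stored as an offset from the peak start.  Some peak
callers emit a 1-based *absolute* summit position instead; a value that cannot
be a valid offset but falls inside ``(start, end]`` is interpreted as absolute
and converted.  ``-1`` means "no summit".

When *writing* peaks in the narrowPeak dialect this package repurposes the
otherwise meaningless columns 8 and 9 (the -log10 p/q slots, which MACS fills
per-run and we never consume) as: column 8 = integer tags-per-peak (-1 if
absent), column 9 = -1.  Column 7 (signalValue) carries the fold enrichment
(-1 if absent).  This makes read -> write -> read the identity on every
field of :class:`PeakRecord`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Interval",
    "PeakRecord",
    "AnchorPairRecord",
    "TssRecord",
    "MotifCountMatrix",
    "FormatError",
    "read_peaks",
    "write_peaks",
    "read_anchor_pairs",
    "write_anchor_pairs",
    "read_jaspar",
    "write_jaspar",
    "load_builtin_motifs",
    "read_tss",
    "write_tss",
    "read_fasta",
    "write_fasta",
    "read_genome_spec",
    "write_genome_spec",
    "CLASSIFICATION_HEADER",
    "write_classification",
    "read_classification",
]

BASES = "ACGT"


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class PeakRecord:
    """A called peak: a span with optional summit and tag count.

    ``summit_offset`` is relative to ``start``; ``tags`` is the read count
    assigned to the peak (binding-strength proxy).
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    summit_offset: int | None = None
    tags: int | None = None
    fold_enrichment: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid peak {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if self.tags is not None and self.tags < 0:
            raise ValueError("tags must be >= 0")

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnchorPairRecord:
    """One ChIA-PET interaction: two anchors, normalized left-before-right."""

    left: Interval
    right: Interval
    pet_count: int = 1

    def __post_init__(self) -> None:
        if self.pet_count < 1:
            raise ValueError("pet_count must be >= 1")
        if (self.left.chrom, self.left.start, self.left.end) > (
            self.right.chrom,
            self.right.start,
            self.right.end,
        ):
            # normalize in place despite frozen=True
            left, right = self.right, self.left
            object.__setattr__(self, "left", left)
            object.__setattr__(self, "right", right)

    @property
    def intrachromosomal(self) -> bool:
        return self.left.chrom == self.right.chrom


@dataclass(frozen=True)
class TssRecord:
    """A gene transcription start site (0-based position)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass(frozen=True)
class MotifCountMatrix:
    """Position count matrix over A,C,G,T (one row per motif position)."""

    motif_id: str
    counts: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.counts) < 1:
            raise ValueError("empty count matrix")
        for i, col in enumerate(self.counts):
            if len(col) != 4:
                raise ValueError(f"position {i}: expected 4 counts")
            if any(c < 0 for c in col):
                raise ValueError(f"position {i}: negative count")
            if not any(c > 0 for c in col):
                raise ValueError(f"position {i}: all-zero column")

    @classmethod
    def from_array(cls, motif_id: str, arr) -> "MotifCountMatrix":
        a = np.asarray(arr, dtype=float)
        if a.ndim != 2 or a.shape[1] != 4:
            raise ValueError("count matrix must be L x 4")
        return cls(motif_id, tuple(tuple(row) for row in a))

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    def __len__(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# peaks (BED / narrowPeak)
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _intfield(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: non-integer {what}: {value!r}"
        ) from None


def _optnum(value: float | None) -> str:
    return "-1" if value is None else format(value, "g")


def read_peaks(path: str | Path, dialect: str = "narrowPeak") -> list[PeakRecord]:
    """Read peak calls from a BED (>=3 columns) or 10-column narrowPeak file.

    See the module docstring for the narrowPeak column conventions.  Raises
    :class:`FormatError` naming the offending line on malformed input.
    """
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks: list[PeakRecord] = []
    for lineno, cols in _data_lines(path):
        if dialect == "bed" and len(cols) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
        if dialect == "narrowPeak" and len(cols) != 10:
            raise FormatError(
                f"{path}:{lineno}: narrowPeak needs exactly 10 columns, "
                f"got {len(cols)}"
            )
        chrom = cols[0]
        start = _intfield(cols[1], path, lineno, "start")
        end = _intfield(cols[2], path, lineno, "end")
        if start >= end or start < 0:
            raise FormatError(
                f"{path}:{lineno}: invalid span {start}-{end}"
            )
        name = cols[3] if len(cols) > 3 else "."
        score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
        summit: int | None = None
        tags: int | None = None
        fe: float | None = None
        if dialect == "narrowPeak":
            fe_raw = float(cols[6])
            fe = None if fe_raw < 0 else fe_raw
            tags_raw = _intfield(cols[7], path, lineno, "tags (col 8)")
            tags = None if tags_raw < 0 else tags_raw
            s = _intfield(cols[9], path, lineno, "summit")
            if s == -1:
                summit = None
            elif s < end - start:
                summit = s
            elif start < s <= end:
                # 1-based absolute summit dialect
                summit = s - 1 - start
            else:
                raise FormatError(
                    f"{path}:{lineno}: summit {s} outside peak {start}-{end}"
                )
        peaks.append(
            PeakRecord(chrom, start, end, name, score, summit, tags, fe)
        )
    return peaks


def write_peaks(
    peaks: Sequence[PeakRecord], path: str | Path, dialect: str = "narrowPeak"
) -> None:
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "wt", encoding="utf-8") as fh:
        for p in peaks:
            if dialect == "bed":
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\n"
                )
            else:
                summit = -1 if p.summit_offset is None else p.summit_offset
                tags = -1 if p.tags is None else p.tags
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\t"
                    f"{_optnum(p.fold_enrichment)}\t{tags}\t-1\t{summit}\n"
                )


# ---------------------------------------------------------------------------
# anchor pairs (BEDPE)
# ---------------------------------------------------------------------------


def read_anchor_pairs(path: str | Path) -> list[AnchorPairRecord]:
    """Read BEDPE-like interaction records (6+ columns).

    Column 8 (the BEDPE score slot), when present, is taken as the PET count.
    Pairs are normalized so the left anchor precedes the right by
    (chrom, start); inter-chromosomal pairs are retained.
    """
    pairs: list[AnchorPairRecord] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 6:
            raise FormatError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
        c1, c2 = cols[0], cols[3]
        s1 = _intfield(cols[1], path, lineno, "start1")
        e1 = _intfield(cols[2], path, lineno, "end1")
        s2 = _intfield(cols[4], path, lineno, "start2")
        e2 = _intfield(cols[5], path, lineno, "end2")
        pet = 1
        if len(cols) >= 8 and cols[7] not in (".", ""):
            pet = max(1, _intfield(cols[7], path, lineno, "pet count"))
        try:
            pairs.append(
                AnchorPairRecord(Interval(c1, s1, e1), Interval(c2, s2, e2), pet)
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return pairs


def write_anchor_pairs(pairs: Sequence[AnchorPairRecord], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for i, p in enumerate(pairs):
            fh.write(
                f"{p.left.chrom}\t{p.left.start}\t{p.left.end}\t"
                f"{p.right.chrom}\t{p.right.start}\t{p.right.end}\t"
                f"loop_{i}\t{p.pet_count}\n"
            )


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------


def read_jaspar(path: str | Path) -> list[MotifCountMatrix]:
    """Read JASPAR PFM text (">ID NAME" headers, bracketed A/C/G/T rows)."""
    with open(path, "rt", encoding="utf-8") as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:  # Bio raises bare Exception on bad rows
            raise FormatError(f"{path}: {exc}") from exc
    out = []
    for m in parsed:
        counts = np.column_stack([list(m.counts[b]) for b in BASES])
        motif_id = m.matrix_id or m.name
        out.append(MotifCountMatrix.from_array(motif_id, counts))
    return out


def write_jaspar(matrices: Sequence[MotifCountMatrix], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for m in matrices:
            fh.write(f">{m.motif_id} {m.motif_id}\n")
            arr = m.to_array()
            for j, base in enumerate(BASES):
                row = " ".join(format(v, "g") for v in arr[:, j])
                fh.write(f"{base} [ {row} ]\n")


def load_builtin_motifs() -> dict[str, MotifCountMatrix]:
    """Toy estrogen-response-element and heat-shock-element count matrices.

    Shipped for simulation and testing only — real analyses should supply
    matrices from a motif database.
    Keys: ``ERE``, ``HSE``.
    """
    from importlib.resources import files

    path = files("chromacoop").joinpath("data/toy_motifs.jaspar")
    with path.open("rt", encoding="utf-8") as fh:  # type: ignore[union-attr]
        parsed = bio_motifs.parse(fh, "jaspar")
    out = {}
    for m in parsed:
        counts = np.column_stack([list(m.counts[b]) for b in BASES])
        out[m.matrix_id] = MotifCountMatrix.from_array(m.matrix_id, counts)
    return out


# ---------------------------------------------------------------------------
# TSS tables (TSV or GFF3/GTF)
# ---------------------------------------------------------------------------


def _gff_gene_id(attrs: str) -> str | None:
    # GFF3: key=value;...   GTF: key "value"; ...
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, val = part.partition("=")
            if key.strip() in ("ID", "gene_id", "Name"):
                return val.strip()
        else:
            bits = part.split(None, 1)
            if len(bits) == 2 and bits[0] == "gene_id":
                return bits[1].strip().strip('"')
    return None


def read_tss(path: str | Path, fmt: str = "tsv") -> list[TssRecord]:
    """Read a TSS table.

    ``tsv``: 4 columns gene_id, chrom, strand, tss (0-based).  ``gff``:
    GFF3/GTF lines with feature type ``gene`` (or ``transcript`` when no gene
    rows exist); the 1-based start (plus strand) or end (minus strand) becomes
    the 0-based TSS.
    """
    records: list[TssRecord] = []
    seen: set[str] = set()
    if fmt == "tsv":
        for lineno, cols in _data_lines(path):
            if cols[:4] == ["gene_id", "chrom", "strand", "tss"]:
                continue  # optional header row
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: TSS TSV needs 4 columns")
            gid, chrom, strand = cols[0], cols[1], cols[2]
            tss = _intfield(cols[3], path, lineno, "tss")
            if gid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            records.append(TssRecord(gid, chrom, strand, tss))
    elif fmt == "gff":
        rows = []
        for lineno, cols in _data_lines(path):
            if len(cols) < 9:
                continue
            rows.append((lineno, cols))
        types_present = {c[2] for _, c in rows}
        want = "gene" if "gene" in types_present else "transcript"
        for lineno, cols in rows:
            if cols[2] != want:
                continue
            chrom, start, end, strand = cols[0], cols[3], cols[4], cols[6]
            s = _intfield(start, path, lineno, "start")
            e = _intfield(end, path, lineno, "end")
            gid = _gff_gene_id(cols[8])
            if gid is None:
                raise FormatError(f"{path}:{lineno}: no gene identifier")
            tss = s - 1 if strand == "+" else e - 1
            if gid in seen:
                continue  # first transcript wins
            seen.add(gid)
            records.append(TssRecord(gid, chrom, strand, tss))
    else:
        raise ValueError(f"unknown TSS format {fmt!r}")
    return records


def write_tss(records: Sequence[TssRecord], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.strand}\t{r.tss}\n")


# ---------------------------------------------------------------------------
# FASTA and genome specs
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}``."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_spec(path: str | Path) -> list[tuple[str, int]]:
    """Read a two-column chrom-sizes TSV (name, length)."""
    out = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 2:
            raise FormatError(f"{path}:{lineno}: chrom sizes need 2 columns")
        out.append((cols[0], _intfield(cols[1], path, lineno, "length")))
    return out


def write_genome_spec(sizes: Iterable[tuple[str, int]], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, length in sizes:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# classification table
# ---------------------------------------------------------------------------

CLASSIFICATION_HEADER = (
    "gene_id",
    "mode",
    "region_id",
    "chrom",
    "start",
    "end",
    "anchor",
    "er_peak",
    "hsf1_peak",
    "ere",
    "hse",
    "distance_to_tss",
)


def write_classification(table, path: str | Path) -> None:
    """Write a gene/mode table as TSV (one row per gene, mode, region).

    ``table`` is a :class:`chromacoop.classify.GeneModeTable`.  Boolean
    evidence flags are serialized as 0/1.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(CLASSIFICATION_HEADER) + "\n")
        for row in table.rows:
            ev = row.evidence
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        row.gene_id,
                        row.mode.value,
                        ev.region_id,
                        ev.interval.chrom,
                        ev.interval.start,
                        ev.interval.end,
                        int(ev.anchor_present),
                        int(ev.er_present),
                        int(ev.hsf1_present),
                        int(ev.ere_present),
                        int(ev.hse_present),
                        row.distance_to_tss,
                    )
                )
                + "\n"
            )


def read_classification(path: str | Path):
    """Re-read a classification TSV written by :func:`write_classification`."""
    from .classify import BindingMode, GeneModeRow, GeneModeTable
    from .intervals import RegionEvidence

    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CLASSIFICATION_HEADER:
            raise FormatError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != len(CLASSIFICATION_HEADER):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            ev = RegionEvidence(
                region_id=cols[2],
                interval=Interval(cols[3], int(cols[4]), int(cols[5])),
                anchor_present=bool(int(cols[6])),
                er_present=bool(int(cols[7])),
                hsf1_present=bool(int(cols[8])),
                ere_present=bool(int(cols[9])),
                hse_present=bool(int(cols[10])),
            )
            rows.append(
                GeneModeRow(
                    gene_id=cols[0],
                    mode=BindingMode(cols[1]),
                    evidence=ev,
                    distance_to_tss=int(cols[11]),
                )
            )
    return GeneModeTable(rows=rows)
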