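import numpy as np
import pytest

from chromacoop.intervals import GenomeSpec, center, center_in
from chromacoop.io_formats import Interval, PeakRecord, TssRecord, load_builtin_motifs
from chromacoop.motifs import build_pwm


@pytest.fixture(scope="session")
def toy_motifs():
    return load_builtin_motifs()


@pytest.fixture(scope="session")
def ere_pwm(toy_motifs):
    return build_pwm(toy_motifs["ERE"])


@pytest.fixture(scope="session")
def hse_pwm(toy_motifs):
    return build_pwm(toy_motifs["HSE"])


@pytest.fixture
def small_genome():
    return GenomeSpec.from_pairs([("chr1", 1_000_000), ("chr2", 500_000)])


def random_peaks(rng, n, genome: GenomeSpec, width_lo=50, width_hi=300, prefix="p"):
    """Uniformly placed peaks, some with summits, for oracle comparisons."""
    chroms = genome.chromosomes
    peaks = []
    for i in range(n):
        chrom, length = chroms[int(rng.integers(0, len(chroms)))]
        width = int(rng.integers(width_lo, width_hi + 1))
        start = int(rng.integers(0, length - width + 1))
        summit = int(rng.integers(0, width)) if rng.random() < 0.5 else None
        peaks.append(
            PeakRecord(chrom, start, start + width, f"{prefix}{i}", 0.0, summit)
        )
    return peaks


def random_tss(rng, n, genome: GenomeSpec, prefix="g"):
    chroms = genome.chromosomes
    out = []
    for i in range(n):
        chrom, length = chroms[int(rng.integers(0, len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(TssRecord(f"{prefix}{i}", chrom, strand, int(rng.integers(0, length))))
    return out


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive)
# ---------------------------------------------------------------------------


def brute_common_one(set_a, set_b):
    return [
        (a, b)
        for a in set_a
        for b in set_b
        if center_in(a, b) or center_in(b, a)
    ]


def brute_common_each(a, b):
    return center_in(a, b) and center_in(b, a)


def brute_nearest_tss(region: Interval, tss_table):
    mid = (region.start + region.end) // 2
    candidates = [t for t in tss_table if t.chrom == region.chrom]
    if not candidates:
        return None
    best = min(candidates, key=lambda t: (abs(mid - t.tss), t.gene_id))
    signed = mid - best.tss if best.strand == "+" else best.tss - mid
    return best.gene_id, signed


def brute_scan(pwm, seq):
    """Naive per-window log-odds summation on both strands."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(pwm)
    seq = seq.upper()
    hits = []
    for pos in range(len(seq) - L + 1):
        window = seq[pos : pos + L]
        if any(b not in idx for b in window):
            continue
        fwd = sum(pwm.log_odds[i, idx[b]] for i, b in enumerate(window))
        rc = "".join(comp[b] for b in reversed(window))
        rev = sum(pwm.log_odds[i, idx[b]] for i, b in enumerate(rc))
        hits.append((pos, "+", fwd))
        hits.append((pos, "-", rev))
    return hits
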