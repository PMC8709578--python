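# chromacoop

Classification of how two transcription factors (ERα and HSF1) cooperate on
chromatin, from ChIP-seq peak calls, ChIA-PET interaction anchors and
PWM motif scans.

Regulatory regions are assembled by combining reduced interaction anchors
with the two peak sets (a factor attaches to an anchor only when the center
of each feature lies inside the other), scanned for ERE and HSE motifs with
an exact-null log-odds scanner, and classified:

| factors present | ERE | HSE | mode |
|---|---|---|---|
| ERα + HSF1 | + | + | cobinding |
| ERα + HSF1 | + | − | tethering (HSF1 recruited by ERα) |
| ERα + HSF1 | − | + | tethering (ERα recruited by HSF1) |
| ERα + HSF1 | − | − | indirect (kept for audit) |
| ERα only | + | · | canonical ERα |
| HSF1 only | · | + | canonical HSF1 |
| otherwise | | | unclassified |

Classified regions are annotated to the nearest gene TSS, and gene-level
summaries report canonical co-regulation (genes with canonical regions for
both factors), cobinding genes, tethering genes and their union
("direct cooperation").  Supporting statistics include tags-per-peak
summaries, CPM fold enrichment, a central-enrichment test for motif
positioning, and a chromosome- and length-preserving permutation test for
peak-set overlap.  A fully ground-truthed simulator generates every input
format with a per-region truth manifest.

## CLI

```sh
# synthetic dataset with a truth manifest
chromacoop simulate --seed 7 --outdir sim/

# full classification
chromacoop classify \
    --er-peaks sim/er_peaks.narrowPeak --hsf1-peaks sim/hsf1_peaks.narrowPeak \
    --anchors sim/anchors.bedpe --genome-fasta sim/genome.fa \
    --tss sim/tss.tsv --outdir results/
# -> results/classification.tsv, results/summary.json, results/run_config.json

# motif presence calls on per-region FASTA
chromacoop scan --fasta regions.fa --motifs motifs.jaspar --out hits.tsv

# overlap significance
chromacoop permtest --peaks-a a.narrowPeak --peaks-b b.narrowPeak \
    --chrom-sizes sim/chrom.sizes --n-perm 999 --seed 1 --out permtest.json

# peak statistics and fold enrichment
chromacoop summarize --peaks sim/er_peaks.narrowPeak \
    --tag-table sim/tags.tsv --out summary.json
```

All coordinates are 0-based half-open (BED convention).  Real analyses
should supply JASPAR matrices for the two motifs; the packaged `ERE`/`HSE`
matrices are toys for simulation and testing.

Note on the narrowPeak dialect: when writing peaks, columns 7/8 carry fold
enrichment and tags-per-peak (−1 when absent) so that read → write → read is
the identity; column 10 accepts both offset and 1-based absolute summits.

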