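# petloop

Chromatin loop calling and analysis from proximity-ligation-free paired-end
tags (PETs).  The package takes mapped PETs (BEDPE), discovers loops by
density-based clustering of the 2D PET coordinates with local-permutation
significance testing, and provides the downstream analyses that typically
accompany a loop call set:

- **preprocess** — linker trimming of FASTQ pairs, length filter,
  near-diagonal no-linker filter, PCR de-duplication, sub-sampling, QC stats
- **loopcall** — multi-eps DBSCAN candidate discovery, Poisson significance
  against shifted background windows, cross-eps merging, Bonferroni
  filtering, resolution estimation, loop-set overlap
- **aggregate** — APA-style 11×11 per-loop matrices, per-loop and global
  enrichment scores, normalized mean heatmap matrix
- **diffloops** — differential loops between two conditions: joint
  quantification, background-fit transform, MA cutoffs at a target FDR,
  Poisson test with Bonferroni correction
- **tfenrich** — transcription-factor loop-anchor association: binary
  binding matrices, co-binding consistency / ratio / peak-overlap attributes
  versus flanking false-loop backgrounds, permutation FDR, ranked report
- **profiles** — virtual 4C viewpoint profiles (bedGraph), profile
  correlation, montage interaction-density tables
- **netanno** — promoter/enhancer annotation, loop categorization
  (P-P/E-P/...), CTCF motif-orientation classes, enhancer-promoter network
  with degree statistics and a power-law fit
- **synthetic** — a generator of PET datasets with planted loops, power-law
  distance-decay background, PCR duplicates, linker flags, TF peak sets and
  per-loop fold changes, plus exact truth tables, so the whole stack is
  testable without downloads

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(oracle equivalences, loop recovery on the seeded reference fixture, null
calibration of the differential test, TF-enrichment power, conservation
laws).  The other files are per-module unit and property tests.

## CLI

Everything is wired through one entry point:

```sh
petloop sim --config sim.json --out simdir/          # synthetic dataset
petloop pre --fq1 r1.fq --fq2 r2.fq --bedpe pets.bedpe --out pre
petloop callLoops --bedpe pets.bedpe --eps 200,500,1000,2000 \
    --minpts 10 --cut 5000 --out loops
petloop agg --bedpe pets.bedpe --loops loops.loops.tsv --out agg
petloop callDiffLoops --bedpe-a a.bedpe --bedpe-b b.bedpe \
    --loops-a a.loops.tsv --loops-b b.loops.tsv --fdr 0.05 --out diff
petloop tfenrich --loops loops.loops.tsv --peaks tf_peaks.bed \
    --n-shuffle 1000 --seed 7 --out tf
petloop vfc --bedpe pets.bedpe --tss tss.bed --out v4c
petloop montage --bedpe pets.bedpe --regions regions.bed --out mont
petloop anno --loops loops.loops.tsv --regions elements.bed --tss tss.bed --out anno
petloop net --loops loops.loops.tsv --regions elements.bed --tss tss.bed --out net
petloop estRes --bedpe pets.bedpe --bins 200,1000,5000,10000 --out res
```

Each subcommand writes a `*.runlog.json` with the command, parameters, input
checksums and stage counts.  All text formats are standard: BEDPE (PETs,
with optional 11th/12th columns holding linker flags), BED3/BED6
(peaks/TSS/motifs), bedGraph (1D signal), TSV loop tables and washU
longrange tracks.

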