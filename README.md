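# shallowcn

Shallow whole-genome-sequencing (sWGS) analysis of cell-free DNA for
copy-number-based circulating tumor DNA detection and quantification.

The package implements the full informatic pipeline used in liquid-biopsy
sWGS studies:

- **Genome binning** — fixed-width bins (default 500 kb) and
  equal-mappable-base bins (fixed total count, default 5500), annotated
  with GC content and mappability, with low-mappability masking.
- **Coverage extraction** — per-bin fragment counts and fragment-length
  distributions from coordinate-sorted alignments (SAM/BAM via pysam), or
  from TSV depth tables.
- **Normalization** — lowess GC-bias correction and log2 depth ratios
  against a panel of normals built from healthy-plasma controls (per-bin
  median or merged-pool reference).
- **CBS arm** — circular binary segmentation with permutation testing,
  copy-state thresholds and same-state segment grouping; SEG output.
- **HMM arm** — a six-state hidden Markov model (clonal copies {0,1,2,3}
  plus subclonal {1,3}, ploidy fixed at 2) with Student-t emissions that
  infers per-bin copy states and the tumor fraction by EM, initialized
  from a grid of normal proportions {0.7, 0.8, 0.9, 0.95, 0.99}.
- **Method comparison** — segment counts, segment-length distributions and
  within-segment log2 SDs with a Mann-Whitney U comparison.
- **Recurrence** — cohort G-scores for gains and losses with a cyclic-shift
  permutation null and Benjamini-Hochberg q-values.
- **Fragmentomics** — size histograms, modal fragment size, nucleosome
  ladder modes (166/332/498 bp) and 10 bp periodicity scoring.
- **Cohort statistics** — rank-sum, signed-rank and Kruskal-Wallis tests
  plus ROC/AUC by pair counting.
- **Synthetic data** — a fully seeded simulator for every pipeline input
  (reference tracks, control panels, CNA-bearing case profiles at known
  tumor fraction, fragment lengths, cohort tables), used by the test suite
  and the demo.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(parameter-recovery simulations, null calibration, oracle equivalences);
the other files are fast per-module unit and property tests.

## Command line

All stages are exposed under one entry point:

```bash
# simulate a full cohort with known truth
shallowcn simulate --seed 7 --out-dir sim/

# build bin scaffolds
shallowcn make-bins --mode fixed --width 500000 \
    --genome sim/genome.tsv --mappability sim/mappability.bedgraph \
    --gc sim/gc.bedgraph --out bins.bed
shallowcn make-bins --mode adaptive --n-bins 5500 ...

# alignments -> per-bin depth / fragment lengths
shallowcn depth --bins bins.bed --bam sample.bam --out depth.tsv
shallowcn fragsize --bam sample.bam --out lengths.tsv

# panel of normals + log2 ratios
shallowcn normalize --depth sim/depth.tsv --bins sim/bins.bed \
    --panel pon.tsv --controls control_1,...,control_9 --out-dir norm/

# the two segmentation arms
shallowcn segment-cbs --norm norm/dog_01_pre.norm.tsv --bins sim/bins.bed --out cbs.seg
shallowcn estimate-tf --norm norm/dog_01_pre.norm.tsv --bins sim/bins.bed \
    --out tf.json --seg hmm.seg

# comparison metrics, recurrence, fragment profile, cohort statistics
shallowcn metrics --norm norm/dog_01_pre.norm.tsv --bins sim/bins.bed \
    --seg hmm.seg --seg cbs.seg --out metrics.json
shallowcn recurrence --seg cohort.seg --bins sim/bins.bed --direction loss \
    --n-perm 1000 --seed 7 --out loss.tsv
shallowcn fragprofile --lengths sim/lengths.tsv --out frag.json
shallowcn cohort --table cohort.tsv --out stats.json

# end-to-end
shallowcn pipeline demo --seed 7 --out demo/
shallowcn pipeline run --config run.yaml
```

`pipeline run` takes a single YAML config (paths, per-stage parameter
blocks, seed); unknown keys are rejected and every run writes a
`manifest.json` recording versions, seeds and all effective parameters.

## Conventions

Coordinates are 0-based half-open internally and in BED outputs; SEG files
are 1-based inclusive. Sex chromosomes are binned but excluded from
tumor-fraction fitting and log2 centering by default. The tumor fraction
reported is `1 − normal proportion`, with subclone prevalence estimated
separately.
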