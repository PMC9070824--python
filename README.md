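# nonbscan

Prediction of non-B-form DNA and centromere enrichment analysis for
genome assemblies, with a synthetic-genome generator that plants ground
truth for end-to-end validation.

## What it does

- **Inverted repeats (dyad symmetries)** — exhaustive maximal-occurrence
  finder (arm 5–100 bp, gap ≤ 20 bp, zero mismatches, overlaps allowed)
  and the *dyad density* statistic: the fraction of bases inside repeat
  arms.
- **Seven non-B motif classes** — A-phased repeats, G-quadruplexes,
  H-DNA, slipped DNA, STRs, TFO targets, and Z-DNA, each scanned on both
  strands by explicit sequence rules with 1–3 "asterisk" likelihoods.
  Per-base likelihoods take the within-class maximum and the
  across-class sum (bounded by 7 × 3 = 21).
- **G4Hunter-style scoring** — run-capped ±1..4 per-base G/C scores,
  25-bp sliding-window means, hit calling at |score| ≥ 1.0 or 1.5, and
  per-contig G4 density.
- **Windowed track plumbing** — 5,000-bp / 2,500-bp-step window plans
  for external structure-probability engines, per-base max reassembly,
  element-wise max combination, and ingestion of SIST-style TSV tables
  (melt / cruciform / Z-DNA at 18, 22, 25, 30, 35 °C).
- **Matched controls** — seeded rejection sampling of length-equal,
  GC-matched (±10 % relative by default) genomic segments, at most two
  overlapping pairs and ≤ 50 kb per overlap, with a post-hoc checker.
- **Statistics** — 1.5×IQR outlier trimming of control values,
  one-sample t-test of controls against the centromere value, two-sample
  Kolmogorov–Smirnov on per-base distributions, enrichment verdicts,
  temperature-sweep reports, and contig ranking by mean likelihood.
- **IPD validation** — 300-bp motif-centered windows over a per-base
  interpulse-duration track, lengthwise averaging with missing-data
  filtering, and center/flank fold enrichment.
- **Synthetic data** — deterministic (seeded NumPy PCG64) assemblies
  with satellite–island–satellite centromere architecture, planted
  motifs verified to be recoverable at exact coordinates, IPD tracks
  elevated over planted motifs, and per-temperature probability tables
  with configurable elevation.

Note: the Results and Methods of the source analysis disagree on which
motif class the IPD validation was centred on (G-quadruplexes vs
Z-DNA); the `ipd` module is therefore class-agnostic and profiles
whatever hit set the caller provides.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(oracle equivalence, planted-motif recall, statistical calibration,
determinism); the rest are per-module unit and property tests.

## CLI

```sh
nonbscan synth --seed 1 --plant G4=20 --plant STR=20 --with-ipd --out-dir demo
nonbscan scan demo/assembly.fasta --out-dir demo/scan
nonbscan enrich demo/assembly.fasta --centromere cen1 --n-controls 50 --seed 1 \
    --out-dir demo/enrich
nonbscan ipd demo/ipd.bg1.bedgraph demo/truth.motifs.bed demo/assembly.fasta \
    --out-dir demo/ipd
nonbscan rank demo/assembly.fasta --out demo/ranked.tsv
```

Each run writes a `manifest.json` recording the command line, seeds,
package version, and input checksums. Coordinates are 0-based
half-open everywhere (BED convention).

## Layout

```
src/nonbscan/
  seqio.py        FASTA/BED/TSV I/O, contigs, GC
  dyads.py        inverted repeats + dyad density
  nonb_motifs.py  seven-class motif prediction
  g4hunter.py     G4 propensity scoring
  tracks.py       per-base track plumbing, SIST-style tables
  controls.py     matched control sampling
  stats.py        enrichment statistics
  ipd.py          IPD meta-profiles
  synth.py        synthetic genomes with planted truth
  cli.py          command-line interface
```
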