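# risipipe

Strand-aware quantification of antisense ribosomal siRNAs (risiRNAs) in small-RNA
sequencing libraries, with synthetic-data generators for benchmarking.

The package models the rDNA transcription unit as a single representative repeat
(plus strand = sense pre-rRNA) tiled by the regions 5′ETS / 18S / ITS1 / 5.8S /
ITS2 / 26S / 3′ETS, and provides:

- **reference** (`risipipe.reference`) — unit + region annotation (FASTA/BED I/O),
  decoy transcriptome (5S rRNA, mRNAs), deterministic pseudo-random reference
  builder with an 18-mer uniqueness guarantee that makes exact-match
  classification unambiguous.
- **simulation** (`risipipe.simulate`) — FASTQ small-RNA libraries with
  genotype-specific region weights, a 22 nt-peaked length distribution and a
  configurable 5′-G probability, plus per-read truth tables; replicate qPCR Ct
  tables with known true enrichments.
- **classification** (`risipipe.classify`) — 3′-adapter trimming, the 18–30 nt
  clean-read filter, exact-match mapping on both strands of every target, and
  category assignment (risiRNA / sense rRNA / sense mRNA / antisense mRNA /
  unmapped) with a fixed class priority.
- **quantification** (`risipipe.quant`) — the bespoke normalization number
  (total mapped − sense rRNA − sense mRNA), risiRNA reads-per-million, region
  proportions by alignment midpoint, length histograms, 5′-nucleotide
  preference, and per-base antisense coverage (bedGraph).
- **qPCR arithmetic** (`risipipe.qpcr`) — percent-input (efficiency 2, input
  dilution-corrected), fold changes vs control, two-stage locus/reference and
  ±treatment ratios, ΔΔCt relative expression, and two-tailed pooled-variance
  Student's t-tests with replicate summaries.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (region-weight
recovery at ±1 percentage point, 22G structure, clean-read filter bounds, and
the property suites).

## CLI

```sh
# simulate a library (reference, FASTQ with adapters, truth table, manifest)
risipipe simulate --preset disl-2 --n-reads 100000 --seed 1 --out-dir runs/sim

# trim / filter / map / classify / quantify a FASTQ
risipipe profile --fastq runs/sim/library.fastq \
    --reference runs/sim/rdna_unit.fa --regions runs/sim/rdna_unit.bed \
    --decoys runs/sim/decoys.fa --out-dir runs/profile

# simulate a qPCR Ct table and compute enrichment reports
risipipe simulate-qpcr --design design.json --seed 1 --out-dir runs/qpcr
risipipe chip --ct-table runs/qpcr/ct_table.csv \
    --comparisons comparisons.json --out-dir runs/chip
```

Library presets (`--preset`): `default`, `wild-type`, `disl-2`, `dis-3`,
`exos-1`, `rrp-8`, `eri-1-rrp-8-ip`. They are JSON files in
`src/risipipe/presets/`; the category fractions, region weights, length
distribution and 5′-G probability are all editable parameters.

Every run writes a `manifest.json` with the package version, parameters, seed
and SHA-256 checksums of inputs and outputs.

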