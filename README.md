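# betascope

A desk-scale, document-oriented store and track-less SVG visualizer for
Illumina methylation-array beta values.

Samples are collected into *projects*; all beta values for one probe within
one project live in a single document, so the document count scales with
projects × probes rather than with the number of samples. Sample metadata is
schema-less key-value data (absent keys are truly absent — no nulls), with
repair utilities for misspelled keys and values. Probe annotation (CpG-island
density classes, SNP-in-probe / SNP-at-CpG flags, reliability) is joined into
every region query and drawn into every plot.

## Features

- **Store** — pluggable backends (`file`: JSON-lines on disk, no server
  needed; `memory`: ephemeral), genomic interval queries, locus resolution by
  coordinate / probe id / gene name, lossless JSON-lines dump/restore.
- **Importers** — beta CSV tables, GenomeStudio-style final reports
  (`*.AVG_Beta` columns, optional detection-p masking), JSON-lines sample
  metadata, BED12 gene models, annotation CSV.
- **Grouping** — up to three metadata keys within a project, or the reserved
  `project` / `tissuetype` keys across projects; samples lacking a grouping
  key are excluded from display.
- **Visualization** — three superimposed (track-less) SVG modes: raw
  `points`, per-group `distribution` glyphs (mean+range or box), and a
  per-group mean `trace` with optional moving-average smoothing. CpG-island
  background shading, below-axis SNP/reliability marker rows, and a gene
  track. Output is deterministic SVG 1.1.
- **Synthetic data** — seeded generators for annotation manifests (including
  a full-array-sized one), projects with planted group effects over a bimodal
  beta background, and a 46-sample X-inactivation demo fixture
  (22 female / 24 male, three X-linked loci).

## CLI walkthrough

```sh
# generate a demo fixture (deterministic per --seed)
betascope simulate --preset x_inactivation --seed 7 --out fixture/

# create a store and load the fixture
betascope --store db init
betascope --store db import-annotation fixture/annotation.csv
betascope --store db register-samples fixture/samples.jsonl
betascope --store db import-betas fixture/betas_xci_demo.csv --project xci_demo

# inspect a locus (coordinate, probe id, or gene name)
betascope --store db query XISTL --projects xci_demo --flank 200

# render: points | distribution | trace
betascope --store db render XISTL --projects xci_demo \
    --group-by sex --mode distribution --genes fixture/genes.bed \
    --out xist.svg

# repair misspelled metadata
betascope --store db fix-metadata --project xci_demo --rename-key sxe sex
```

`--group-by` accepts up to three comma-separated metadata keys; without it,
samples are grouped across projects by the reserved `project` key (or
`tissuetype` via `--cross-project-key`). `--hide SAMPLE` removes samples
before grouping. A `key=value` config file (`--config`) can set the store
path, default flank, and plot dimensions.

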