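# tilemark

Tiling-array ChIP analysis at desk scale: normalization of probe-level
IP/input signals, two-state HMM enriched-region calling, region-to-gene
linkage with gene-type enrichment statistics, 15-bin metagene positional
profiling, multi-mark K-means clustering, and expression/entropy
integration — plus a synthetic-data generator so the entire chain can be
exercised without real array data.

## Modules

| module | what it does |
| --- | --- |
| `tilemark.synthetic` | annotation, probe layouts, multi-mark ChIP signal matrices with planted enriched regions, expression matrices |
| `tilemark.normalization` | log2 transform with flooring, quantile normalization of replicates, IP/input common-mean scaling, log ratios, H3 adjustment |
| `tilemark.regions` | moderated probe t-statistics, two-state Gaussian-emission HMM posteriors, gap/run/cutoff region calling, size and coverage summaries |
| `tilemark.annotation` | region-to-gene linkage, gene-type representation tables with Fisher tests, set-overlap chi-square, eu/heterochromatin stratification, long-region TE-class composition |
| `tilemark.profiles` | gene-spacing filter, 15-bin positional profiles (promoter / TSS / proportional gene body / 3' end / 3' flank), group means, expression-decile profiles, mark-relative profiles |
| `tilemark.clustering` | K-means on concatenated multi-mark profiles, Shannon entropy tissue specificity, per-group expression quartiles |
| `tilemark.io` / `tilemark.pipeline` / `tilemark.cli` | GFF3/BED/bedGraph/TSV readers and writers, the end-to-end pipeline, the `tilemark` CLI |

Coordinates are 0-based half-open internally; conversion happens only at
the GFF3 boundary.

## CLI

```bash
# generate a synthetic dataset (annotation, signal table, expression)
tilemark simulate --config sim.yaml --outdir data/ --seed 42

# single stages
tilemark normalize --signal data/signal.tsv --mark me2 --out me2.bedgraph
tilemark callpeaks --signal data/signal.tsv --mark me2 --cutoff 0.5 \
    --max-gap 1000 --min-run 200 --out peaks.bed
tilemark annotate --peaks peaks.bed --gff data/genes.gff3 \
    --het data/heterochromatin.bed --out gene_types.tsv
tilemark profile --track me2.bedgraph --gff data/genes.gff3 \
    --min5 350 --min3 150 --out profiles.tsv
tilemark cluster --profiles me2.tsv --profiles me3.tsv --k 4 --seed 7 --out clusters/

# or everything at once from a YAML config
tilemark run --config pipeline.yaml
```

A minimal `pipeline.yaml`:

```yaml
signal_table: data/signal.tsv
gff3: data/genes.gff3
het_bed: data/heterochromatin.bed
expression: data/expression.tsv
outdir: out/
seed: 42
```

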