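# mascseq

Simulation and analysis toolkit for **microarray-based single-cell RNA
sequencing** (MASC-seq style) experiments, aimed at method developers and
analysts working on spot-based single-cell transcriptomics of microbial
eukaryotes and other small cells.

In these experiments, fixed cells are imaged on a glass array of ~2000
printed capture spots (1934 barcoded + 66 orientation frame spots, 150 µm
pitch) and then lysed in place. Each spot's oligo-dT probes carry an 18-nt
spot barcode and a 9-nt UMI, so a captured transcript's cDNA records *where*
it was captured and *which molecule* it came from. Sequencing reads the
barcode+UMI in R1 (31 nt) and a transcript fragment in R2 (121 nt). The key
analysis questions are: how many unique molecules and genes does each spot
show, do spots with cells stand out from empty (background) spots, and how
much of a single-cell spot's signal is really its own?

The package provides:

- **`mascseq.array_model`** — barcode-set design (minimum pairwise Hamming
  distance 3, so single-mismatch correction is unambiguous), lattice layout,
  layout TSV I/O.
- **`mascseq.synthetic_data`** — a ground-truthed simulator: cells on spots,
  per-cell mRNA budgets with overdispersed gene expression, ambient RNA
  leakage at rate λ, PCR duplicates, substitution errors, paired FASTQ with
  full per-read provenance.
- **`mascseq.demux_count`** — quality filter, barcode demultiplexing with
  1-mismatch correction, k-mer seed-and-extend transcript mapping (or SAM
  import), and UMI deduplication by the positional rule: reads of one
  (spot, gene, strand) are grouped when within 250 bp of each other, and
  UMIs within a group collapse at Hamming ≤ 1. Output is a spot × gene
  matrix in raw and unique layers, with rRNA genes excluded.
- **`mascseq.spot_stats`** — per-spot metrics, Wilcoxon rank-sum category
  comparisons (`**` p < 10⁻⁴, `*` p < 0.05), the precision statistic
  **precision = (SC − EC)/SC** (SC, EC: median unique transcripts of
  single-cell and empty spots), mRNA-per-cell estimates from extracted RNA
  mass, detection ratios, saturation curves under nested subsampling,
  per-gene correlations and top-gene rankings.
- **`mascseq` CLI** — `simulate`, `demux`, `stats`, `saturate`, `run-all`,
  `validate`, driven by one strict YAML config; every stage reads/writes
  only plain-text formats (FASTQ/FASTA/TSV/JSON).

## Worked example

Simulate a 400-spot experiment (120 single-cell spots, 30 doubles, 10
clusters, 5% leakage, PCR duplicate mean 2, error rate 10⁻³), run the full
pipeline, and compute the headline statistics:

```python
from mascseq import (
    ProbeSpec, SimConfig, build_layout, generate_barcodes, place_cells,
    draw_molecules, apply_leakage, synthesize_reads, simulate_transcriptome,
    default_expression_model, demultiplex, map_reads, annotate_reads,
    dedup_umis, build_count_matrix, quality_filter, spot_metrics, precision,
    compare_categories, placements_to_annotations,
)

barcodes = generate_barcodes(400, length=18, min_hamming=3, seed=7)
layout = build_layout(400, 20, 150.0, barcodes)
transcriptome = simulate_transcriptome(150, (300, 1200), rrna_fraction=0.05, seed=7)
model = default_expression_model(150, seed=7, cells_budget_range=(300, 600))
cfg = SimConfig(n_single=120, n_double=30, n_cluster=10,
                leakage_fraction=0.05, pcr_duplicate_mean=2.0,
                substitution_error_rate=0.001, seed=7)

placements = place_cells(layout, cfg)
truth = apply_leakage(draw_molecules(placements, transcriptome, model, seed=8),
                      cfg.leakage_fraction, seed=9)
r1, r2, provenance = synthesize_reads(truth, layout, ProbeSpec(), cfg, transcriptome)
print(f"simulated {truth.total_molecules()} molecules -> {len(r1)} read pairs")

pairs = [((a.read_id, a.sequence, a.quality), (b.read_id, b.sequence, b.quality))
         for a, b in zip(r1, r2)]
kept, _ = quality_filter(pairs)
assignments, _ = demultiplex([p[0] for p in kept], layout.barcode_set())
hits, _ = map_reads([p[1] for p in kept], transcriptome.sequences)
reads = annotate_reads(hits, assignments)
dedup = dedup_umis(reads, transcriptome.gene_map)
matrix = build_count_matrix(dedup, layout.barcoded_spot_ids,
                            transcriptome.gene_ids, transcriptome.rrna_gene_ids)
print(f"unique molecules counted: {matrix.unique.to_numpy().sum()}")

metrics = spot_metrics(matrix)
annotations = placements_to_annotations(placements)
prec = precision(metrics, annotations)
print(f"SC={prec.sc:.1f}  EC={prec.ec:.1f}  precision={prec.precision:.3f}")
comp = compare_categories(metrics, annotations, "unique_transcripts",
                          ("single", "background"))
print(f"singles vs background: rank-sum p = {comp.p_value:.3g} ({comp.star})")
```

Output:

```
simulated 99592 molecules -> 299349 read pairs
unique molecules counted: 95473
SC=411.5  EC=11.0  precision=0.973
singles vs background: rank-sum p = 4.29e-54 (**)
```

Reading the numbers: ~300k read pairs collapse back to ~95k unique
molecules (the missing ~4% are rRNA-gene molecules excluded from the matrix
plus a small error-rate loss). A median single-cell spot shows 411.5 unique
transcripts against a background median of 11, so 97.3% of a single-cell
spot's signal is attributable to its own cell at this leakage rate, and the
single-vs-background separation is highly significant.

The same experiment as a shell run:

```bash
mascseq run-all -c config.yaml -o runs/demo      # simulate + count + stats
mascseq validate config.yaml                     # strict config checking
```

`runs/demo/` then contains the layout, FASTQ pair, ground-truth molecule
table, count matrices (`counts_unique.tsv`, `counts_raw.tsv`), per-spot
metrics, category comparisons, precision, saturation curve, top genes, and
a `manifest.json` with the config hash and per-stage record counts.
Identical config + seed reproduce byte-identical outputs.

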