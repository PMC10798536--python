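# Methods

`mascseq` models a microarray-based single-cell RNA-seq experiment: fixed
cells are imaged on a printed array of ~100 µm oligo-dT capture spots, lysed
in place, and each captured transcript receives the spot's positional barcode
plus a unique molecular identifier (UMI) during reverse transcription.
Sequencing yields read pairs where R1 (31 nt) carries an 18-nt spot barcode
and a 9-nt UMI, and R2 (121 nt) carries a transcript fragment. The package
provides (i) a ground-truthed simulator of such experiments, (ii) the
demultiplex/map/deduplicate/count pipeline, and (iii) the spot-category
statistics used to judge data quality.

## Array model

The default array has 1934 barcoded capture spots and 66 non-capturing frame
spots (2000 total) on a centered-rectangular lattice with a 150 µm pitch:
rows are offset by half the pitch in alternating fashion. Coordinates are
metadata for image alignment only — nothing in counting uses them — so the
lattice parameterization is deliberately simple (a single pitch parameter).

Barcodes are drawn by seeded rejection sampling under a minimum pairwise
Hamming distance, default 3. With distance ≥ 3, any read whose barcode
carries at most one substitution has a unique nearest true barcode, so
single-mismatch correction can never mis-assign. Random 18-mers essentially
always satisfy this (the probability that two random 18-mers lie within
Hamming 2 is ~10⁻⁸), so generation is fast even at n = 1934; infeasible
requests (e.g. more barcodes than the space holds) fail with an explicit
message after a bounded number of attempts.

## Simulator

The simulator is first-class, tested code: it defines the conditions under
which the pipeline's correctness claims hold.

**Cell placement.** Configured numbers of single (1 cell), double (2 cells)
and cluster spots (uniform 3–6 cells) are placed on disjoint barcoded spots;
all remaining barcoded spots are background. The default occupancy (194
singles, 40 doubles, 20 clusters) mirrors a realistic smear of a few hundred
cells on a ~2000-spot array.

**Expression.** Each cell draws an integer molecule budget uniformly from a
configured range and splits it across genes with a gamma-mixed multinomial:
per-cell gene rates λ_g ~ Gamma(1/φ, m_g·φ) with relative means m_g
(log-normal across genes, σ = 1.2) and overdispersion φ (default 0.3,
negative-binomial-like cell-to-cell variability; φ = 0 gives a plain
multinomial). The default budget range, 1 250–6 250 molecules per cell, is
the low end of per-cell mRNA contents estimated for small phytoplankton;
ranges up to ~2.3×10⁵ (large ciliates) are configurable. Tests use smaller
budgets purely to keep problem sizes desk-scale; the generator itself is
unchanged.

**Leakage.** Permeabilized cells leak RNA that diffuses and is captured at
the wrong spot; this is the dominant background ("ambient") signal. Each
molecule is independently reassigned to a uniformly random barcoded spot
with probability λ (default 0.05), conserving totals exactly. The real
mechanism (pre-smearing suspension RNA vs. post-permeabilization diffusion)
is not identifiable from array data, so one rate covers both; λ is a free
simulation parameter, not an estimate from any experiment.

**Reads.** Each molecule emits 1 + D read pairs with D ~ Poisson(mean 2 by
default). R1 = barcode + UMI + poly-T padding to 31 nt; R2 is a 121-nt
sense-strand window whose start is drawn uniformly from the 250-bp window
ending at the transcript's 3′ end (clamped at zero for short transcripts).
Because all copies of one molecule start within a < 250 bp span, the
positional grouping rule recovers molecule identity exactly on error-free
data — the simulator's duplicates are, by construction, the dedup rule's
ground truth. Substitution errors are applied per base at a configurable
rate (default 10⁻³) to both mates; qualities are constant Q37, with a
separate option that injects a fraction of low-quality (Q2) R2s to exercise
the quality filter, and another that emits a fraction of molecules antisense
to exercise the strand key in dedup.

**UMI assignment.** UMIs are drawn uniformly over 9-mers, subject to one
constraint: within a single (spot, gene), UMIs of distinct molecules keep
pairwise Hamming distance ≥ 2. Without this, two molecules of the same gene
at the same spot collide under the 1-mismatch collapse rule with probability
~10⁻⁴ per pair — enough to break exact ground-truth equality at 10⁵
molecules, while telling us nothing about the pipeline. The constraint makes
"the pipeline recovers the molecule table exactly" a well-posed claim. Real
libraries do suffer UMI collisions; the simulator therefore slightly
understates the (small, downward) collision bias of real UMI counting.

**What the simulator does not model.** Indels, adapter read-through,
position- or motif-dependent error profiles, realistic duplicate-rate
distributions (a single Poisson mean only), transcript-specific capture
bias, isoforms (one transcript per gene), and cell segmentation errors in
the image annotation. Passing tests demonstrate algorithmic correctness
under these idealized conditions, not end-to-end fidelity on real libraries.

## Pipeline

**Quality filter.** Pairs are dropped when the R2 mean Phred quality falls
below 20; terminal homopolymer runs ≥ 15 nt are trimmed from R2 and the pair
dropped if < 30 nt remain. The thresholds are package defaults chosen in the
spirit of standard spatial-transcriptomics preprocessing.

**Demultiplexing.** Exact 18-nt prefix matches assign directly; otherwise
the read is assigned to the unique barcode within 1 mismatch (configurable).
Ambiguous best hits and unmatched reads are rejected with per-reason tallies.
Correction is guaranteed safe only when the barcode set's minimum pairwise
distance exceeds twice the allowed mismatch; the ambiguity rejection is
enforced at runtime, so permissive sets degrade to rejection rather than
mis-assignment.

**Mapping.** A deterministic k-mer seed-and-extend matcher (seed k = 17,
min 30 matching bases, substitutions only, both strands) replaces a spliced
aligner: in transcriptome mode with 3′-anchored tags there are no junctions
to cross, and the matcher is exact on the simulator's reads. Reads with a
tied best score on more than one transcript are discarded as multimappers,
never fractionally assigned. A SAM import hook accepts primary mapped
records from any external aligner instead.

**UMI deduplication.** Within each (spot, gene, strand), reads are sorted by
start position and chained into positional groups — a new group opens when
the gap to the previous read exceeds 250 bp. This chain formulation is
exactly the connected components of the graph joining reads within 250 bp of
each other. Within a positional group, UMIs are clustered by single-linkage
at Hamming ≤ 1 (no count-aware directionality), and the unique-molecule
count is the number of UMI clusters. The brute-force graph construction
serves as the test oracle; the production path is the sort-and-chain form.

**Counting.** Matrices cover every barcoded spot (zero rows included), with
genes on the rRNA exclusion list removed. Raw (pre-dedup) and unique
(post-dedup) layers are both emitted, and unique ≤ raw entrywise is enforced
as an invariant.

## Statistics

**Per-spot metrics** are genes detected (columns with ≥ 1 unique molecule)
and unique transcripts (row sum of the unique layer).

**Category comparisons** use the two-sided Wilcoxon rank-sum test between
spot categories (background / single / double / cluster from image review).
When both groups have ≤ 8 spots the p-value is computed by exact enumeration
of the rank-sum distribution (valid under ties); otherwise the tie-corrected
normal approximation is used. Stars: `**` for p < 10⁻⁴, `*` for p < 0.05,
else NS. If all pooled observations are identical the test degenerates and
p = 1 is reported.

**Precision** is (SC − EC)/SC with SC and EC the median unique-transcript
counts of single-cell and background spots: assuming single-cell spots
accumulate as much ambient signal as empty spots, it estimates the fraction
of a single-cell spot's signal that came from its own cell. It is
scale-invariant, equals 1 with a clean background, 0 when signal and
background are indistinguishable, and is undefined when SC = 0.

**mRNA per cell.** Total RNA molecules per cell are derived from extracted
RNA mass: mass is corrected for a 50% extraction efficiency, divided by the
molar mass of an average 1000-nt transcript (340.5 g/mol per nucleotide — a
standard constant, configurable), converted via Avogadro's number and
divided by the cell count. The mRNA range applies 1–5% mRNA-of-total-RNA
fractions, rounded to integers. The detection ratio (estimated molecules
over detected transcripts per cell) uses the floor, matching how such ratios
are conventionally quoted; mean transcripts per cell feed the ratio while
medians feed precision.

**Saturation.** One seeded permutation of the annotated read table defines
nested subsamples; each requested depth re-runs deduplication on its prefix.
Nesting makes curves non-decreasing on error-free data and guarantees the
full-depth point reproduces the standard pipeline output bit for bit. (With
sequencing errors, a subsampled UMI cluster can in principle split, so
monotonicity is an expectation, not a theorem.)

**Top genes / correlations.** Genes are ranked by unique counts summed over
a category's spots, ties broken lexicographically. Library-vs-library
comparisons use Pearson correlation on raw per-gene totals; no transform is
applied, since the choice of transform is a presentation decision left to
the caller.

## Workflow and reproducibility

`run-all` executes simulate → demux/count → stats into one run directory
containing only documented text formats (FASTQ, FASTA, TSV, JSON), so any
stage can be replaced by external tools. Per-stage seeds derive from the run
seed through `numpy` seed sequences; identical config + seed reproduce
byte-identical FASTQ and matrices. A manifest records the config hash, seed
and per-stage record counts. Config files are strict: unknown keys are
rejected and all constraint violations are reported at once.

## Numerical and degenerate-input choices

- Transcript coordinates are 0-based half-open everywhere internally;
  SAM positions are converted on import.
- Dedup tie-breaks: reads sort by (start, UMI, read id) with a stable sort,
  making group labels deterministic.
- Mapping ties within one transcript keep the smallest start; ties across
  transcripts discard the read.
- `estimate_mrna` uses round-half-even only at exact .5 boundaries (Python
  `round`); the published inputs produce exact integers, so this never
  matters for them.
- Empty read tables, all-zero matrices, and categories absent from a run are
  handled explicitly (empty matrices keep full spot row sets; comparisons
  and precision require non-empty categories and fail with named errors).

## Known limitations

- The mapper is exact-substring-biased: reads with errors inside every
  sampled seed k-mer go unmapped (at the default 10⁻³ error rate this is
  negligible; at high error rates use the SAM import path).
- Positional chaining can, in principle, merge reads > 250 bp apart through
  intermediates; the simulator never produces such chains, and on real data
  this matches the sort-then-group behaviour of standard spatial pipelines.
- The precision statistic assumes ambient contamination is spatially
  uniform; the simulator's uniform leakage satisfies this by construction,
  real arrays may not (droplet-edge effects).
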