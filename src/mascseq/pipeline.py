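"""End-to-end driver: simulate -> demux/count -> statistics.

Each stage reads and writes only documented plain-text formats (FASTQ, FASTA,
TSV, JSON) so stages can be swapped with external tools. A manifest records
the config hash, seed, and per-stage record counts; identical config + seed
reproduce byte-identical count matrices.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import array_model as am
from . import demux_count as dc
from . import spot_stats as ss
from . import synthetic_data as sd
from .config import RunConfig

__all__ = ["PipelineError", "run_pipeline", "simulate_stage", "demux_stage", "stats_stage"]

log = logging.getLogger("mascseq")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _stage_seeds(seed: int) -> dict[str, int]:
    """Independent per-stage seeds derived from the run seed."""
    ss_root = np.random.SeedSequence(seed)
    names = ["barcodes", "transcriptome", "expression", "placement", "molecules",
             "leakage", "reads", "saturation"]
    children = ss_root.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def simulate_stage(config: RunConfig, out_dir: Path) -> dict[str, Any]:
    """Generate the array, transcriptome, ground truth and paired FASTQ."""
    a, s = config.array, config.sim
    seeds = _stage_seeds(config.seed)
    probe = am.ProbeSpec(
        barcode_length=a.barcode_length, umi_length=a.umi_length,
        r1_length=a.r1_length, r2_length=a.r2_length,
    )
    barcodes = am.generate_barcodes(
        a.n_barcoded, a.barcode_length, a.min_hamming, seeds["barcodes"]
    )
    layout = am.build_layout(a.n_barcoded, a.n_frame, a.pitch_um, barcodes, a.spot_diameter_um)
    am.write_layout(layout, out_dir / "layout.tsv")

    transcriptome = sd.simulate_transcriptome(
        s.n_genes, (s.transcript_length_min, s.transcript_length_max),
        s.rrna_fraction, seeds["transcriptome"], a.r2_length,
    )
    transcriptome.to_fasta(out_dir / "transcriptome.fasta")
    (out_dir / "rrna_gene_ids.txt").write_text(
        "".join(g + "\n" for g in transcriptome.rrna_gene_ids)
    )
    pd.DataFrame(
        sorted(transcriptome.gene_map.items()), columns=["transcript_id", "gene_id"]
    ).to_csv(out_dir / "gene_map.tsv", sep="\t", index=False)

    model = sd.default_expression_model(
        s.n_genes, seeds["expression"], s.dispersion,
        (s.budget_low, s.budget_high), s.expression_sigma,
    )
    sim_cfg = sd.SimConfig(
        n_single=s.n_single, n_double=s.n_double, n_cluster=s.n_cluster,
        leakage_fraction=s.leakage_fraction, pcr_duplicate_mean=s.pcr_duplicate_mean,
        substitution_error_rate=s.substitution_error_rate,
        antisense_fraction=s.antisense_fraction,
        low_quality_fraction=s.low_quality_fraction, seed=seeds["placement"],
    )
    placements = sd.place_cells(layout, sim_cfg)
    annotations = sd.placements_to_annotations(placements)
    annotations.to_csv(out_dir / "annotations.tsv", sep="\t", index=False)

    truth = sd.draw_molecules(placements, transcriptome, model, seeds["molecules"])
    truth = sd.apply_leakage(truth, s.leakage_fraction, seeds["leakage"])
    truth.write_molecules_tsv(out_dir / "truth_molecules.tsv")

    read_cfg = sd.SimConfig(
        n_single=s.n_single, n_double=s.n_double, n_cluster=s.n_cluster,
        leakage_fraction=s.leakage_fraction, pcr_duplicate_mean=s.pcr_duplicate_mean,
        substitution_error_rate=s.substitution_error_rate,
        antisense_fraction=s.antisense_fraction,
        low_quality_fraction=s.low_quality_fraction, seed=seeds["reads"],
    )
    r1, r2, provenance = sd.synthesize_reads(truth, layout, probe, read_cfg, transcriptome)
    sd.write_fastq(r1, out_dir / "R1.fastq")
    sd.write_fastq(r2, out_dir / "R2.fastq")
    provenance.to_csv(out_dir / "provenance.tsv", sep="\t", index=False)
    counts = {
        "barcoded_spots": len(layout.barcoded_spots),
        "frame_spots": len(layout.frame_spots),
        "genes": s.n_genes,
        "molecules": truth.total_molecules(),
        "read_pairs": len(r1),
    }
    log.info("simulate: %s", counts)
    return counts


def demux_stage(config: RunConfig, out_dir: Path) -> dict[str, Any]:
    """Filter, demultiplex, map, dedup and count the run directory's reads."""
    a, d = config.array, config.demux
    probe = am.ProbeSpec(
        barcode_length=a.barcode_length, umi_length=a.umi_length,
        r1_length=a.r1_length, r2_length=a.r2_length,
    )
    layout = am.read_layout(out_dir / "layout.tsv", a.pitch_um, a.spot_diameter_um)
    barcodes = layout.barcode_set(a.min_hamming)
    sequences = dc.load_transcriptome_fasta(out_dir / "transcriptome.fasta")
    gene_map_df = pd.read_csv(out_dir / "gene_map.tsv", sep="\t")
    gene_map = dc.GeneMap(dict(zip(gene_map_df["transcript_id"], gene_map_df["gene_id"])))
    rrna_path = out_dir / "rrna_gene_ids.txt"
    rrna_ids = (
        [l for l in rrna_path.read_text().splitlines() if l.strip()]
        if rrna_path.exists()
        else []
    )

    pairs = dc.read_fastq_pairs(out_dir / "R1.fastq", out_dir / "R2.fastq")
    kept, filter_report = dc.quality_filter(
        pairs, d.min_mean_q, d.homopolymer_max_run, d.min_r2_len
    )
    assignments, demux_report = dc.demultiplex(
        [p[0] for p in kept], barcodes,
        dc.BarcodeMatchPolicy(d.max_mismatch, d.require_unique_best), probe,
    )
    hits, map_report = dc.map_reads(
        [p[1] for p in kept], sequences, d.min_match, d.seed_k
    )
    reads = dc.annotate_reads(hits, assignments)
    reads.to_csv(out_dir / "reads_annotated.tsv", sep="\t", index=False)
    policy = dc.DedupPolicy(d.window_bp, d.umi_max_mismatch)
    dedup = dc.dedup_umis(reads, gene_map, policy, a.umi_length)
    gene_ids = sorted(set(gene_map.mapping.values()))
    matrix = dc.build_count_matrix(dedup, layout.barcoded_spot_ids, gene_ids, rrna_ids)
    matrix.write_tsv(out_dir / "counts_unique.tsv", out_dir / "counts_raw.tsv")
    for name, rep in (
        ("filter_report", filter_report),
        ("demux_report", demux_report),
        ("mapping_report", map_report),
    ):
        pd.DataFrame(sorted(rep.items()), columns=["key", "value"]).to_csv(
            out_dir / f"{name}.tsv", sep="\t", index=False
        )
    counts = {
        "read_pairs_in": len(pairs),
        "read_pairs_kept": filter_report["kept"],
        "reads_assigned": len(assignments),
        "reads_mapped": map_report["mapped"],
        "reads_counted": len(reads),
        "unique_molecules": int(matrix.unique.to_numpy().sum()),
    }
    log.info("demux: %s", counts)
    return counts


def stats_stage(config: RunConfig, out_dir: Path) -> dict[str, Any]:
    """Spot metrics, category comparisons, precision, saturation, top genes."""
    a, d, st = config.array, config.demux, config.stats
    seeds = _stage_seeds(config.seed)
    layout = am.read_layout(out_dir / "layout.tsv", a.pitch_um, a.spot_diameter_um)
    unique = pd.read_csv(out_dir / "counts_unique.tsv", sep="\t", index_col="spot_id")
    annotations = ss.load_annotations(out_dir / "annotations.tsv", layout)
    metrics = ss.spot_metrics(unique)
    metrics.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)

    present = set(annotations["category"])
    comp_rows = []
    for pair in st.category_pairs:
        cat_a, cat_b = pair
        if cat_a not in present or cat_b not in present:
            continue
        c = ss.compare_categories(metrics, annotations, "unique_transcripts", (cat_a, cat_b))
        comp_rows.append((c.category_a, c.category_b, c.n_a, c.n_b, c.rank_sum,
                          c.p_value, c.star, c.method))
    pd.DataFrame(
        comp_rows,
        columns=["category_a", "category_b", "n_a", "n_b", "rank_sum", "p_value",
                 "star", "method"],
    ).to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)

    stats_counts: dict[str, Any] = {"comparisons": len(comp_rows)}
    if "single" in present and "background" in present:
        prec = ss.precision(metrics, annotations)
        pd.DataFrame(
            [(prec.sc, prec.ec, prec.precision)], columns=["SC", "EC", "precision"]
        ).to_csv(out_dir / "precision.tsv", sep="\t", index=False)
        stats_counts["precision"] = prec.precision

    reads = pd.read_csv(
        out_dir / "reads_annotated.tsv", sep="\t",
        dtype={"umi": str, "spot_id": str, "transcript_id": str},
    )
    gene_map_df = pd.read_csv(out_dir / "gene_map.tsv", sep="\t")
    gene_map = dc.GeneMap(dict(zip(gene_map_df["transcript_id"], gene_map_df["gene_id"])))
    depths = sorted({int(round(f * len(reads))) for f in st.depth_fractions})
    curve = ss.saturation(
        reads, depths, seeds["saturation"], gene_map,
        dc.DedupPolicy(d.window_bp, d.umi_max_mismatch), a.umi_length,
    )
    curve.write_tsv(out_dir / "saturation.tsv")
    stats_counts["saturation_depths"] = len(depths)

    if "single" in present:
        top = ss.top_expressed_genes(unique, annotations, "single", st.top_n_genes)
        top.to_csv(out_dir / "top_genes.tsv", sep="\t", index=False)
        stats_counts["top_genes"] = len(top)
    log.info("stats: %s", stats_counts)
    return stats_counts


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run simulate -> demux -> stats and write a manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_sha256": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    for name, fn in (("simulate", simulate_stage), ("demux", demux_stage), ("stats", stats_stage)):
        try:
            manifest["stages"][name] = fn(config, out)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise PipelineError(name, exc) from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
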