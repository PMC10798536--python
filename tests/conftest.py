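"""Shared fixtures: small arrays, transcriptomes and fully simulated batches."""

from __future__ import annotations

import pytest

from mascseq.array_model import ProbeSpec, build_layout, generate_barcodes
from mascseq.synthetic_data import (
    SimConfig,
    default_expression_model,
    draw_molecules,
    place_cells,
    simulate_transcriptome,
    synthesize_reads,
)


@pytest.fixture(scope="session")
def probe_spec():
    return ProbeSpec()


@pytest.fixture(scope="session")
def small_barcodes():
    return generate_barcodes(60, 18, 3, seed=11)


@pytest.fixture(scope="session")
def small_layout(small_barcodes):
    return build_layout(60, 10, 150.0, small_barcodes)


@pytest.fixture(scope="session")
def small_transcriptome():
    return simulate_transcriptome(30, (300, 800), rrna_fraction=0.1, seed=7)


@pytest.fixture(scope="session")
def default_barcodes():
    """Production-size barcode set (1934 x 18 nt, min pairwise Hamming 3)."""
    return generate_barcodes(1934, 18, 3, seed=20)


@pytest.fixture(scope="session")
def default_layout(default_barcodes):
    return build_layout(1934, 66, 150.0, default_barcodes)


@pytest.fixture(scope="session")
def clean_batch(small_layout, small_transcriptome, probe_spec):
    """Noise-free simulated batch: no leakage, duplicates or errors."""
    cfg = SimConfig(
        n_single=20, n_double=5, n_cluster=2,
        leakage_fraction=0.0, pcr_duplicate_mean=0.0,
        substitution_error_rate=0.0, seed=3,
    )
    placements = place_cells(small_layout, cfg)
    model = default_expression_model(30, seed=2, cells_budget_range=(100, 200))
    truth = draw_molecules(placements, small_transcriptome, model, seed=4)
    r1, r2, prov = synthesize_reads(truth, small_layout, probe_spec, cfg, small_transcriptome)
    return {
        "config": cfg,
        "placements": placements,
        "truth": truth,
        "r1": r1,
        "r2": r2,
        "provenance": prov,
    }
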