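"""Ground-truthed synthetic MASC-seq experiments.

The generator emulates one array experiment end to end: a reference
transcriptome, cells placed on capture spots (singles, doubles, clusters of
3-6 cells, the rest background), per-cell mRNA budgets spread over genes by
an overdispersed draw, ambient "leakage" of molecules to random spots, and
finally paired FASTQ reads with PCR duplicates and substitution errors.
Every molecule and read carries provenance so downstream stages can be
checked against exact ground truth.

Read geometry follows the assay: R1 is 31 nt (18-nt spot barcode, 9-nt UMI,
poly-T padding), R2 is a 121-nt sense-strand window from the transcript's 3'
end. Duplicate reads of one molecule jitter their start within a 250-bp
window so that the positional UMI-collapse rule recovers molecules exactly.

Two deliberate idealizations matter for interpreting tests: UMIs within one
(spot, gene) are drawn uniformly but kept at pairwise Hamming >= 2, so
molecule identity is recoverable by a 1-mismatch collapse; and base qualities
are constant (Q37), with a separate low-quality injection knob to exercise
the quality filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import DNA_ALPHABET, random_dna, revcomp
from .array_model import ArrayLayout, ProbeSpec

__all__ = [
    "TranscriptRecord",
    "SyntheticTranscriptome",
    "ExpressionModel",
    "SimConfig",
    "GroundTruth",
    "FastqRecord",
    "simulate_transcriptome",
    "default_expression_model",
    "place_cells",
    "draw_molecules",
    "apply_leakage",
    "synthesize_reads",
    "write_fastq",
    "placements_to_annotations",
]

# dedup positional window the jitter is tied to (duplicates must span < window)
DEDUP_WINDOW_BP = 250


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    sequence: str
    is_rrna: bool = False


@dataclass
class SyntheticTranscriptome:
    """Reference transcripts, each mapping to exactly one gene."""

    records: list[TranscriptRecord]

    def __post_init__(self) -> None:
        ids = [r.transcript_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("transcript ids are not unique")
        if any(not r.sequence for r in self.records):
            raise ValueError("empty transcript sequence")

    @property
    def sequences(self) -> dict[str, str]:
        return {r.transcript_id: r.sequence for r in self.records}

    @property
    def gene_map(self) -> dict[str, str]:
        """transcript_id -> gene_id."""
        return {r.transcript_id: r.gene_id for r in self.records}

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.gene_id, None)
        return list(seen)

    @property
    def rrna_gene_ids(self) -> list[str]:
        return sorted({r.gene_id for r in self.records if r.is_rrna})

    def transcript_of_gene(self) -> dict[str, str]:
        """gene_id -> one representative transcript (first in record order)."""
        out: dict[str, str] = {}
        for r in self.records:
            out.setdefault(r.gene_id, r.transcript_id)
        return out

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.transcript_id} gene={r.gene_id} rrna={int(r.is_rrna)}\n")
                for i in range(0, len(r.sequence), 80):
                    fh.write(r.sequence[i : i + 80] + "\n")


@dataclass
class ExpressionModel:
    """Relative gene abundances plus per-cell molecule budgets.

    ``gene_means`` are relative weights (normalized internally); ``dispersion``
    is a gamma-mixing overdispersion (0 = plain multinomial); budgets are drawn
    uniformly from ``cells_budget_range`` (inclusive), which spans the
    organism-dependent estimates of ~1.25e3 to ~2.3e5 mRNA molecules per cell.
    """

    gene_means: np.ndarray
    dispersion: float = 0.3
    cells_budget_range: tuple[int, int] = (1250, 6250)

    def __post_init__(self) -> None:
        self.gene_means = np.asarray(self.gene_means, dtype=float)
        if (self.gene_means < 0).any():
            raise ValueError("gene means must be >= 0")
        if self.gene_means.sum() <= 0:
            raise ValueError("gene means must not all be zero")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.cells_budget_range
        if not (0 < lo <= hi):
            raise ValueError("cells_budget_range must satisfy 0 < low <= high")


def default_expression_model(
    n_genes: int,
    seed: int = 0,
    dispersion: float = 0.3,
    cells_budget_range: tuple[int, int] = (1250, 6250),
    sigma: float = 1.2,
) -> ExpressionModel:
    """Log-normal relative gene abundances (a standard skewed expression profile)."""
    rng = np.random.default_rng(seed)
    means = rng.lognormal(mean=0.0, sigma=sigma, size=n_genes)
    return ExpressionModel(means, dispersion, cells_budget_range)


@dataclass
class SimConfig:
    """Tunable study conditions for one simulated experiment."""

    n_single: int = 194
    n_double: int = 40
    n_cluster: int = 20
    leakage_fraction: float = 0.05
    pcr_duplicate_mean: float = 2.0
    substitution_error_rate: float = 0.001
    antisense_fraction: float = 0.0
    low_quality_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "leakage_fraction",
            "substitution_error_rate",
            "antisense_fraction",
            "low_quality_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.pcr_duplicate_mean < 0:
            raise ValueError("pcr_duplicate_mean must be >= 0")
        if min(self.n_single, self.n_double, self.n_cluster) < 0:
            raise ValueError("occupancy counts must be >= 0")


@dataclass
class GroundTruth:
    """Molecule table plus (after read synthesis) per-read provenance."""

    molecules: dict[tuple[str, str], int]
    spot_ids: list[str]  # the barcoded-spot universe
    provenance: pd.DataFrame | None = None

    def total_molecules(self) -> int:
        return sum(self.molecules.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, g, c) for (s, g), c in sorted(self.molecules.items())]
        return pd.DataFrame(rows, columns=["spot_id", "gene_id", "count"])

    def to_matrix(self, gene_ids: Sequence[str]) -> pd.DataFrame:
        """Dense spot x gene molecule matrix over the full spot universe."""
        df = self.to_frame()
        if df.empty:
            mat = pd.DataFrame(0, index=list(self.spot_ids), columns=list(gene_ids), dtype=int)
        else:
            mat = (
                df.pivot_table(
                    index="spot_id", columns="gene_id", values="count",
                    aggfunc="sum", fill_value=0,
                )
                .reindex(index=list(self.spot_ids), columns=list(gene_ids), fill_value=0)
                .astype(int)
            )
        mat.index.name = "spot_id"
        mat.columns.name = None
        return mat

    def write_molecules_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class FastqRecord:
    read_id: str
    sequence: str
    quality: str


def simulate_transcriptome(
    n_genes: int,
    length_range: tuple[int, int] = (300, 1500),
    rrna_fraction: float = 0.0,
    seed: int = 0,
    r2_length: int = 121,
) -> SyntheticTranscriptome:
    """Uniform-composition random transcripts, one per gene.

    ``round(rrna_fraction * n_genes)`` transcripts are flagged as rRNA (the
    stand-in for an rRNA-identification exclusion list).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo > hi:
        raise ValueError("length_range low must be <= high")
    if lo < r2_length:
        raise ValueError(
            f"minimum transcript length {lo} is below the R2 read length "
            f"{r2_length}; reads could not be drawn"
        )
    if not (0.0 <= rrna_fraction <= 1.0):
        raise ValueError("rrna_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_rrna = int(round(rrna_fraction * n_genes))
    rrna_idx = set(rng.choice(n_genes, size=n_rrna, replace=False).tolist())
    records = []
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        gid = f"G{i + 1:05d}"
        records.append(
            TranscriptRecord(
                transcript_id=f"{gid}.t1",
                gene_id=gid,
                sequence=random_dna(rng, length),
                is_rrna=i in rrna_idx,
            )
        )
    return SyntheticTranscriptome(records)


def place_cells(layout: ArrayLayout, config: SimConfig) -> list[tuple[str, int]]:
    """Assign cells to disjoint barcoded spots; everything else is background.

    Returns one ``(spot_id, n_cells)`` entry per barcoded spot, in layout
    order. Cluster spots draw their occupancy uniformly from 3..6 cells.
    """
    spot_ids = layout.barcoded_spot_ids
    n_occupied = config.n_single + config.n_double + config.n_cluster
    if n_occupied > len(spot_ids):
        raise ValueError(
            f"cannot occupy {n_occupied} spots on an array with "
            f"{len(spot_ids)} barcoded spots"
        )
    rng = np.random.default_rng(config.seed)
    chosen = rng.choice(len(spot_ids), size=n_occupied, replace=False)
    counts = {spot_ids[i]: 0 for i in range(len(spot_ids))}
    cursor = 0
    for _ in range(config.n_single):
        counts[spot_ids[chosen[cursor]]] = 1
        cursor += 1
    for _ in range(config.n_double):
        counts[spot_ids[chosen[cursor]]] = 2
        cursor += 1
    for _ in range(config.n_cluster):
        counts[spot_ids[chosen[cursor]]] = int(rng.integers(3, 7))
        cursor += 1
    return [(sid, counts[sid]) for sid in spot_ids]


def placements_to_annotations(placements: Iterable[tuple[str, int]]) -> pd.DataFrame:
    """Image-review category per spot implied by the simulated occupancy."""

    def cat(n: int) -> str:
        if n == 0:
            return "background"
        if n == 1:
            return "single"
        if n == 2:
            return "double"
        return "cluster"

    return pd.DataFrame(
        [(sid, cat(n)) for sid, n in placements], columns=["spot_id", "category"]
    )


def draw_molecules(
    placements: Sequence[tuple[str, int]],
    transcriptome: SyntheticTranscriptome,
    model: ExpressionModel,
    seed: int = 0,
) -> GroundTruth:
    """Draw per-cell molecule budgets and apportion them over genes.

    Each cell draws an integer budget uniformly from the model's budget range,
    then splits it over genes with a gamma-mixed multinomial (negative-binomial
    style overdispersion when ``dispersion > 0``). Multi-cell spots sum their
    cells' molecules.
    """
    gene_ids = transcriptome.gene_ids
    if len(model.gene_means) != len(gene_ids):
        raise ValueError(
            f"model has {len(model.gene_means)} gene means but the transcriptome "
            f"has {len(gene_ids)} genes"
        )
    rng = np.random.default_rng(seed)
    lo, hi = model.cells_budget_range
    molecules: dict[tuple[str, str], int] = {}
    for sid, n_cells in placements:
        for _ in range(n_cells):
            budget = int(rng.integers(lo, hi + 1))
            if model.dispersion > 0:
                shape = 1.0 / model.dispersion
                lam = rng.gamma(shape, model.gene_means * model.dispersion)
            else:
                lam = model.gene_means
            total = lam.sum()
            if total <= 0:  # pathological gamma draw; fall back to the means
                lam = model.gene_means
                total = lam.sum()
            counts = rng.multinomial(budget, lam / total)
            for gi in np.flatnonzero(counts):
                key = (sid, gene_ids[gi])
                molecules[key] = molecules.get(key, 0) + int(counts[gi])
    return GroundTruth(molecules=molecules, spot_ids=[sid for sid, _ in placements])


def apply_leakage(truth: GroundTruth, leakage_fraction: float, seed: int = 0) -> GroundTruth:
    """Reassign each molecule to a uniformly random barcoded spot with prob. λ.

    Models ambient RNA: permeabilized cells leak transcripts that diffuse and
    are captured at the wrong spot. Molecule totals are conserved exactly.
    """
    if not (0.0 <= leakage_fraction <= 1.0):
        raise ValueError("leakage_fraction must be in [0, 1]")
    if leakage_fraction == 0.0:
        return GroundTruth(dict(truth.molecules), list(truth.spot_ids), truth.provenance)
    rng = np.random.default_rng(seed)
    spot_ids = list(truth.spot_ids)
    out: dict[tuple[str, str], int] = {}
    for (sid, gid), count in sorted(truth.molecules.items()):
        n_leak = int(rng.binomial(count, leakage_fraction))
        if count - n_leak:
            out[(sid, gid)] = out.get((sid, gid), 0) + (count - n_leak)
        if n_leak:
            dests = rng.integers(0, len(spot_ids), size=n_leak)
            for d in dests:
                key = (spot_ids[int(d)], gid)
                out[key] = out.get(key, 0) + 1
    return GroundTruth(molecules=out, spot_ids=spot_ids)


def _draw_umi(
    rng: np.random.Generator, length: int, used: list[str], min_dist: int = 2
) -> str:
    """Uniform UMI kept at pairwise Hamming >= min_dist from prior UMIs here."""
    for _ in range(200):
        umi = random_dna(rng, length)
        ok = True
        for u in used:
            if sum(a != b for a, b in zip(umi, u)) < min_dist:
                ok = False
                break
        if ok:
            return umi
    raise RuntimeError(
        f"could not draw a UMI at Hamming >= {min_dist} from {len(used)} "
        "existing UMIs; too many molecules share one spot and gene"
    )


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.flatnonzero(mask):
        orig = chars[i]
        alts = [b for b in DNA_ALPHABET if b != orig]
        chars[i] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


def synthesize_reads(
    truth: GroundTruth,
    layout: ArrayLayout,
    probe_spec: ProbeSpec,
    config: SimConfig,
    transcriptome: SyntheticTranscriptome,
) -> tuple[list[FastqRecord], list[FastqRecord], pd.DataFrame]:
    """Emit paired reads for every molecule, plus full per-read provenance.

    Per molecule: one original read plus D PCR duplicates (D ~ Poisson with the
    configured mean); all copies share the molecule's UMI and draw their R2
    start uniformly from the 250-bp window ending at the transcript 3' end
    (clamped at 0), so duplicates always collapse under the positional rule.
    Substitution errors at the configured rate hit both mates independently.
    """
    barcode_of = layout.barcode_of()
    for (sid, _g) in truth.molecules:
        if sid not in barcode_of:
            raise ValueError(f"truth references spot {sid} which carries no barcode")
    seqs = transcriptome.sequences
    rep_transcript = transcriptome.transcript_of_gene()
    r2_len = probe_spec.r2_length
    pad_len = probe_spec.r1_length - probe_spec.barcode_length - probe_spec.umi_length
    rng = np.random.default_rng(config.seed)
    hi_q = chr(37 + 33)  # constant Q37
    lo_q = chr(2 + 33)

    r1_out: list[FastqRecord] = []
    r2_out: list[FastqRecord] = []
    prov_rows = []
    umis_at: dict[tuple[str, str], list[str]] = {}
    mol_no = 0
    read_no = 0
    for (sid, gid), count in sorted(truth.molecules.items()):
        tid = rep_transcript.get(gid)
        if tid is None:
            raise ValueError(f"gene {gid} has no transcript in the reference")
        tseq = seqs[tid]
        if len(tseq) < r2_len:
            raise ValueError(
                f"transcript {tid} ({len(tseq)} nt) is shorter than the R2 "
                f"read length {r2_len}"
            )
        win_hi = len(tseq) - r2_len  # inclusive
        win_lo = max(0, win_hi - (DEDUP_WINDOW_BP - 1))
        used = umis_at.setdefault((sid, gid), [])
        barcode = barcode_of[sid]
        for _ in range(count):
            mol_no += 1
            mol_id = f"m{mol_no:08d}"
            umi = _draw_umi(rng, probe_spec.umi_length, used)
            used.append(umi)
            antisense = rng.random() < config.antisense_fraction
            n_copies = 1 + int(rng.poisson(config.pcr_duplicate_mean))
            for copy in range(n_copies):
                read_no += 1
                rid = f"r{read_no:08d}"
                start = int(rng.integers(win_lo, win_hi + 1))
                frag = tseq[start : start + r2_len]
                strand = "+"
                if antisense:
                    frag = revcomp(frag)
                    strand = "-"
                r1_seq = _substitute(barcode + umi + "T" * pad_len, config.substitution_error_rate, rng)
                r2_seq = _substitute(frag, config.substitution_error_rate, rng)
                r2_qual = hi_q * len(r2_seq)
                if config.low_quality_fraction and rng.random() < config.low_quality_fraction:
                    r2_qual = lo_q * len(r2_seq)
                r1_out.append(FastqRecord(rid, r1_seq, hi_q * len(r1_seq)))
                r2_out.append(FastqRecord(rid, r2_seq, r2_qual))
                prov_rows.append(
                    (rid, sid, mol_id, tid, umi, start, strand, copy > 0)
                )
    provenance = pd.DataFrame(
        prov_rows,
        columns=[
            "read_id",
            "spot_id",
            "molecule_id",
            "transcript_id",
            "umi",
            "start",
            "strand",
            "is_duplicate",
        ],
    )
    return r1_out, r2_out, provenance


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    """Write 4-line FASTQ records (Phred+33)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
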