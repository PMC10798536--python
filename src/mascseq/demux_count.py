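"""Read filtering, spot demultiplexing, transcript mapping, UMI dedup, counting.

This is the computational core of the workflow. Reads enter as paired FASTQ
(R1 = spot barcode + UMI, R2 = transcript fragment) and leave as a
spot x gene matrix of unique molecules. The stages are:

1. quality filter (mean R2 quality, terminal homopolymer trimming);
2. demultiplex R1 against the array's barcode set, with optional
   single-mismatch correction (safe when barcodes are >= 3 apart);
3. map R2 to the reference transcriptome with a deterministic k-mer
   seed-and-extend matcher (substitutions only, no indels) — or import
   alignments from an external aligner via SAM;
4. UMI deduplication: within each (spot, gene, strand) reads are sorted by
   start position and chained into positional groups (break when the gap to
   the previous read exceeds 250 bp); within a group, UMIs are clustered by
   single-linkage at Hamming <= 1; the number of UMI clusters is the unique
   molecule count;
5. assembly of dense unique/raw count matrices with rRNA genes excluded.

Multimapping reads and ambiguous barcodes are discarded, never fractionally
assigned. Transcript coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import encode_seqs, revcomp
from .array_model import ProbeSpec, SpotBarcodeSet

__all__ = [
    "BarcodeMatchPolicy",
    "DedupPolicy",
    "MappingHit",
    "CountMatrix",
    "GeneMap",
    "DedupResult",
    "read_fastq_pairs",
    "load_transcriptome_fasta",
    "quality_filter",
    "demultiplex",
    "build_kmer_index",
    "map_reads",
    "import_sam",
    "annotate_reads",
    "dedup_umis",
    "build_count_matrix",
    "gene_map_from_gff",
]


@dataclass(frozen=True)
class BarcodeMatchPolicy:
    """How R1 prefixes are matched to spot barcodes.

    Correction to the unique barcode within ``max_mismatch`` is unambiguous
    only when barcodes are at pairwise distance > 2*max_mismatch; ambiguous
    best hits are rejected at runtime when ``require_unique_best`` is set.
    """

    max_mismatch: int = 1
    require_unique_best: bool = True


@dataclass(frozen=True)
class DedupPolicy:
    """Positional UMI-collapse rule: 250-bp chaining, 1 UMI mismatch."""

    window_bp: int = 250
    umi_max_mismatch: int = 1
    grouping: str = "single-linkage"

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.umi_max_mismatch not in (0, 1):
            raise ValueError("umi_max_mismatch must be 0 or 1")


class MappingHit(NamedTuple):
    read_id: str
    transcript_id: str
    start: int  # 0-based alignment start on the transcript
    strand: str  # '+' or '-'


@dataclass
class CountMatrix:
    """Spot x gene matrices: unique molecules (post-dedup) and raw reads."""

    unique: pd.DataFrame
    raw: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.unique.index.equals(self.raw.index) or not self.unique.columns.equals(
            self.raw.columns
        ):
            raise ValueError("unique and raw layers must share spots and genes")
        if (self.unique.to_numpy() > self.raw.to_numpy()).any():
            raise ValueError("unique counts exceed raw read counts somewhere")
        if (self.unique.to_numpy() < 0).any() or (self.raw.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def write_tsv(self, unique_path: str | Path, raw_path: str | Path) -> None:
        self.unique.to_csv(unique_path, sep="\t", index_label="spot_id")
        self.raw.to_csv(raw_path, sep="\t", index_label="spot_id")


@dataclass
class GeneMap:
    """transcript_id -> gene_id mapping; ``n_missing`` transcripts lacked the tag."""

    mapping: dict[str, str]
    n_missing: int = 0

    def get(self, transcript_id: str) -> str:
        return self.mapping.get(transcript_id, transcript_id)


Record = tuple[str, str, str]  # (read_id, sequence, quality)


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[tuple[Record, Record]]:
    """Load paired FASTQ files; record counts and ids must agree."""
    with open(r1_path) as fh:
        r1 = [(t.split()[0], s, q) for t, s, q in FastqGeneralIterator(fh)]
    with open(r2_path) as fh:
        r2 = [(t.split()[0], s, q) for t, s, q in FastqGeneralIterator(fh)]
    if len(r1) != len(r2):
        raise ValueError(f"R1 has {len(r1)} records but R2 has {len(r2)}")
    for (id1, _, _), (id2, _, _) in zip(r1, r2):
        if id1 != id2:
            raise ValueError(f"read id mismatch between mates: {id1!r} vs {id2!r}")
    return list(zip(r1, r2))


def load_transcriptome_fasta(path: str | Path) -> dict[str, str]:
    """Reference transcript sequences keyed by FASTA record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _mean_quality(qual: str) -> float:
    return float(np.frombuffer(qual.encode("ascii"), dtype=np.uint8).mean()) - 33.0


def _trim_terminal_homopolymers(seq: str, qual: str, max_run: int) -> tuple[str, str]:
    if not seq:
        return seq, qual
    i = 0
    while i < len(seq) and seq[i] == seq[0]:
        i += 1
    if i >= max_run:
        seq, qual = seq[i:], qual[i:]
    if seq:
        j = 0
        while j < len(seq) and seq[len(seq) - 1 - j] == seq[-1]:
            j += 1
        if j >= max_run:
            seq, qual = seq[: len(seq) - j], qual[: len(qual) - j]
    return seq, qual


def quality_filter(
    pairs: Sequence[tuple[Record, Record]],
    min_mean_q: float = 20.0,
    homopolymer_max_run: int = 15,
    min_r2_len: int = 30,
) -> tuple[list[tuple[Record, Record]], dict[str, int]]:
    """Drop low-quality pairs and trim terminal homopolymer runs from R2.

    A pair is discarded when the R2 mean Phred quality falls below
    ``min_mean_q``, or when R2 is shorter than ``min_r2_len`` after trimming
    terminal runs of length >= ``homopolymer_max_run``.
    """
    if min(min_mean_q, homopolymer_max_run, min_r2_len) <= 0:
        raise ValueError("filter thresholds must be positive")
    kept: list[tuple[Record, Record]] = []
    report = Counter(
        input=len(pairs), kept=0, discarded_low_quality=0, discarded_short_after_trim=0,
        trimmed=0,
    )
    for (rid1, s1, q1), (rid2, s2, q2) in pairs:
        if _mean_quality(q2) < min_mean_q:
            report["discarded_low_quality"] += 1
            continue
        ts, tq = _trim_terminal_homopolymers(s2, q2, homopolymer_max_run)
        if len(ts) != len(s2):
            report["trimmed"] += 1
        if len(ts) < min_r2_len:
            report["discarded_short_after_trim"] += 1
            continue
        kept.append(((rid1, s1, q1), (rid2, ts, tq)))
        report["kept"] += 1
    return kept, dict(report)


def demultiplex(
    r1_records: Iterable[Record],
    barcodes: SpotBarcodeSet,
    policy: BarcodeMatchPolicy = BarcodeMatchPolicy(),
    probe_spec: ProbeSpec = ProbeSpec(),
) -> tuple[dict[str, tuple[str, str]], dict[str, int]]:
    """Assign reads to spots from the R1 barcode prefix and extract the UMI.

    Exact hits are assigned directly; otherwise, if correction is enabled,
    a read is assigned to the unique nearest barcode within ``max_mismatch``.
    Ambiguous and unmatched reads are rejected with reasons tallied.
    """
    bl, ul = probe_spec.barcode_length, probe_spec.umi_length
    exact = {bc: sid for sid, bc in barcodes.entries.items()}
    mat = barcodes.as_matrix()
    sids = list(barcodes.entries)
    assignments: dict[str, tuple[str, str]] = {}
    report = Counter(exact=0, corrected=0, unmatched=0, ambiguous=0, too_short=0)
    for rid, seq, _qual in r1_records:
        if len(seq) < bl + ul:
            report["too_short"] += 1
            continue
        bc, umi = seq[:bl], seq[bl : bl + ul]
        sid = exact.get(bc)
        if sid is not None:
            report["exact"] += 1
        elif policy.max_mismatch >= 1:
            q = np.frombuffer(bc.encode("ascii"), dtype=np.uint8)
            d = (mat != q).sum(axis=1)
            dmin = int(d.min())
            if dmin > policy.max_mismatch:
                report["unmatched"] += 1
                continue
            idx = np.flatnonzero(d == dmin)
            if len(idx) > 1 and policy.require_unique_best:
                report["ambiguous"] += 1
                continue
            sid = sids[int(idx[0])]
            report["corrected"] += 1
        else:
            report["unmatched"] += 1
            continue
        assignments[rid] = (sid, umi)
    return assignments, dict(report)


def build_kmer_index(
    sequences: Mapping[str, str], k: int = 17
) -> dict[str, list[tuple[str, int]]]:
    """Exact k-mer -> [(transcript_id, position)] lookup table."""
    if not sequences:
        raise ValueError("empty transcriptome")
    index: dict[str, list[tuple[str, int]]] = {}
    for tid in sorted(sequences):
        seq = sequences[tid]
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((tid, pos))
    return index


def map_reads(
    r2_records: Iterable[Record],
    sequences: Mapping[str, str],
    min_match: int = 30,
    k: int = 17,
    index: dict[str, list[tuple[str, int]]] | None = None,
) -> tuple[list[MappingHit], dict[str, int]]:
    """Seed-and-extend mapping of R2 reads onto transcript sequences.

    Each non-overlapping k-mer of the read (both orientations) seeds candidate
    ungapped alignments; the candidate with the most matching bases wins,
    subject to ``min_match``. Reads whose best score is tied across different
    transcripts are discarded as multimappers.
    """
    if not sequences:
        raise ValueError("empty transcriptome")
    if index is None:
        index = build_kmer_index(sequences, k)
    hits: list[MappingHit] = []
    report = Counter(mapped=0, unmapped=0, multimapped=0, too_short=0)
    for rid, seq, _qual in r2_records:
        if len(seq) < k:
            report["too_short"] += 1
            continue
        best_score = -1
        best: tuple[str, int, str] | None = None
        best_tids: set[str] = set()
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            L = len(s)
            cands: set[tuple[str, int]] = set()
            offsets = list(range(0, L - k + 1, k))
            if offsets[-1] != L - k:
                offsets.append(L - k)
            for off in offsets:
                for tid, pos in index.get(s[off : off + k], ()):
                    start = pos - off
                    if start >= 0 and start + L <= len(sequences[tid]):
                        cands.add((tid, start))
            for tid, start in sorted(cands):
                ref = sequences[tid][start : start + L]
                if ref == s:
                    score = L
                else:
                    a = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
                    b = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
                    score = int((a == b).sum())
                if score < min_match:
                    continue
                if score > best_score:
                    best_score = score
                    best = (tid, start, strand)
                    best_tids = {tid}
                elif score == best_score:
                    best_tids.add(tid)
        if best is None:
            report["unmapped"] += 1
        elif len(best_tids) > 1:
            report["multimapped"] += 1
        else:
            hits.append(MappingHit(rid, best[0], best[1], best[2]))
            report["mapped"] += 1
    return hits, dict(report)


def import_sam(path: str | Path, sequences: Mapping[str, str]) -> list[MappingHit]:
    """Convert primary mapped SAM records to MappingHits.

    Secondary/supplementary/unmapped records are ignored. References unknown
    to the transcriptome abort with the full offender list.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        unknown = [r for r in fh.references if r not in sequences]
        if unknown:
            raise ValueError(
                "SAM references absent from the transcriptome: " + ", ".join(unknown)
            )
        hits: list[MappingHit] = []
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            hits.append(
                MappingHit(
                    aln.query_name,
                    aln.reference_name,
                    int(aln.reference_start),
                    "-" if aln.is_reverse else "+",
                )
            )
    return hits


def annotate_reads(
    hits: Iterable[MappingHit], assignments: Mapping[str, tuple[str, str]]
) -> pd.DataFrame:
    """Join mapping hits with spot assignments into one tidy read table."""
    rows = [
        (h.read_id, *assignments[h.read_id], h.transcript_id, h.start, h.strand)
        for h in hits
        if h.read_id in assignments
    ]
    return pd.DataFrame(
        rows, columns=["read_id", "spot_id", "umi", "transcript_id", "start", "strand"]
    )


def _positional_groups(starts: np.ndarray, window_bp: int) -> np.ndarray:
    """Chain sorted starts: a new group opens when the gap exceeds the window."""
    labels = np.zeros(len(starts), dtype=int)
    for i in range(1, len(starts)):
        labels[i] = labels[i - 1] + (starts[i] - starts[i - 1] > window_bp)
    return labels


def _cluster_umis(umis: Sequence[str], max_mismatch: int) -> list[int]:
    """Single-linkage components of UMIs at Hamming <= max_mismatch."""
    n = len(umis)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    first_of: dict[str, int] = {}
    for i, u in enumerate(umis):
        if u in first_of:
            union(first_of[u], i)
        else:
            first_of[u] = i
    if max_mismatch >= 1:
        uniq = list(first_of)
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                if sum(a != b for a, b in zip(uniq[i], uniq[j])) <= max_mismatch:
                    union(first_of[uniq[i]], first_of[uniq[j]])
    roots: dict[int, int] = {}
    labels = []
    for i in range(n):
        r = find(i)
        labels.append(roots.setdefault(r, len(roots)))
    return labels


@dataclass
class DedupResult:
    """Per-(spot, gene) unique/raw counts and per-read molecule labels."""

    unique_counts: pd.DataFrame  # spot_id, gene_id, count
    raw_counts: pd.DataFrame  # spot_id, gene_id, count
    read_groups: pd.DataFrame  # read_id -> molecule label
    n_rejected_umi: int = 0


def dedup_umis(
    reads: pd.DataFrame,
    gene_map: Mapping[str, str] | GeneMap,
    policy: DedupPolicy = DedupPolicy(),
    umi_length: int = 9,
) -> DedupResult:
    """Collapse PCR duplicates by the positional UMI-grouping rule.

    ``reads`` must carry columns read_id, spot_id, umi, transcript_id, start,
    strand (the output of :func:`annotate_reads`). Reads whose UMI is not
    ``umi_length`` nt are rejected individually.
    """
    if isinstance(gene_map, GeneMap):
        getter = gene_map.get
    else:  # plain mapping: transcripts absent from it count as their own gene
        getter = lambda t: gene_map.get(t, t)  # noqa: E731
    df = reads.copy()
    if len(df):
        bad = df["umi"].str.len() != umi_length
        n_rejected = int(bad.sum())
        df = df.loc[~bad]
    else:
        n_rejected = 0
    if len(df) == 0:
        empty = pd.DataFrame(columns=["spot_id", "gene_id", "count"])
        groups = pd.DataFrame(columns=["read_id", "spot_id", "gene_id", "molecule"])
        return DedupResult(empty, empty.copy(), groups, n_rejected)
    df = df.assign(gene_id=[getter(t) for t in df["transcript_id"]])
    unique_rows: dict[tuple[str, str], int] = {}
    raw_rows: dict[tuple[str, str], int] = {}
    group_rows = []
    for (spot, gene, strand), g in df.groupby(["spot_id", "gene_id", "strand"], sort=True):
        g = g.sort_values(["start", "umi", "read_id"], kind="mergesort")
        starts = g["start"].to_numpy()
        pg = _positional_groups(starts, policy.window_bp)
        n_unique = 0
        for pgi in np.unique(pg):
            sub = g.iloc[np.flatnonzero(pg == pgi)]
            labels = _cluster_umis(sub["umi"].tolist(), policy.umi_max_mismatch)
            n_unique += len(set(labels))
            for rid, lab in zip(sub["read_id"], labels):
                group_rows.append(
                    (rid, spot, gene, f"{spot}|{gene}|{strand}|{pgi}|{lab}")
                )
        key = (spot, gene)
        unique_rows[key] = unique_rows.get(key, 0) + n_unique
        raw_rows[key] = raw_rows.get(key, 0) + len(g)
    unique_counts = pd.DataFrame(
        [(s, g, c) for (s, g), c in sorted(unique_rows.items())],
        columns=["spot_id", "gene_id", "count"],
    )
    raw_counts = pd.DataFrame(
        [(s, g, c) for (s, g), c in sorted(raw_rows.items())],
        columns=["spot_id", "gene_id", "count"],
    )
    read_groups = pd.DataFrame(
        group_rows, columns=["read_id", "spot_id", "gene_id", "molecule"]
    )
    return DedupResult(unique_counts, raw_counts, read_groups, n_rejected)


def _pivot_counts(
    counts: pd.DataFrame, spot_ids: Sequence[str], gene_ids: Sequence[str]
) -> pd.DataFrame:
    if counts.empty:
        mat = pd.DataFrame(0, index=list(spot_ids), columns=list(gene_ids), dtype=int)
    else:
        mat = (
            counts.pivot_table(
                index="spot_id", columns="gene_id", values="count",
                aggfunc="sum", fill_value=0,
            )
            .reindex(index=list(spot_ids), columns=list(gene_ids), fill_value=0)
            .astype(int)
        )
    mat.index.name = "spot_id"
    mat.columns.name = None
    return mat


def build_count_matrix(
    dedup: DedupResult,
    spot_ids: Sequence[str],
    gene_ids: Sequence[str],
    rrna_gene_ids: Sequence[str] = (),
) -> CountMatrix:
    """Dense matrices over the full spot universe, rRNA genes excluded.

    Spots with no reads keep all-zero rows; genes on the rRNA exclusion list
    (the stand-in for an rRNA-detection step on real references) are dropped
    before counting.
    """
    if len(set(spot_ids)) != len(spot_ids):
        raise ValueError("duplicate spot ids")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids")
    rrna = set(rrna_gene_ids)
    genes = [g for g in gene_ids if g not in rrna]
    return CountMatrix(
        unique=_pivot_counts(dedup.unique_counts, spot_ids, genes),
        raw=_pivot_counts(dedup.raw_counts, spot_ids, genes),
    )


def gene_map_from_gff(path: str | Path, attribute_tag: str = "gene_id") -> GeneMap:
    """Build the transcript -> gene mapping from a GFF3 file.

    The attribute tag used for the gene key is configurable (mirroring a
    pipeline option for references whose GFFs name genes differently).
    Transcripts lacking the tag map to themselves and are tallied.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # noqa: BLE001 - surface parse failures uniformly
        raise ValueError(f"could not read GFF file {path}: {exc}") from exc
    if not any(True for _ in db.all_features()):
        raise ValueError(f"could not read GFF file {path}: no features parsed")
    mapping: dict[str, str] = {}
    n_missing = 0
    for feature_type in ("mRNA", "transcript"):
        for feat in db.features_of_type(feature_type):
            tid = feat.attributes.get("ID", [feat.id])[0]
            values = feat.attributes.get(attribute_tag)
            if values:
                mapping[tid] = values[0]
            else:
                mapping[tid] = tid
                n_missing += 1
    return GeneMap(mapping, n_missing)
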