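"""Spot-level statistics for barcoded-array single-cell experiments.

Spots are categorized from image review as background (0 cells), single,
double, or cluster (>2 cells). From the unique-count matrix this module
derives per-spot metrics (genes detected, unique transcripts), rank-sum
comparisons between categories, the background-corrected precision statistic

    precision = (SC - EC) / SC,

where SC and EC are the median unique-transcript counts of single-cell and
empty (background) spots — the fraction of a single-cell spot's signal
attributable to its own cell under the assumption that single-cell spots
collect as much ambient RNA as empty spots do. It also estimates mRNA
molecules per cell from extracted RNA mass, the ratio of estimated molecules
to detected transcripts, sequencing-saturation curves under nested
subsampling, per-gene total correlations between libraries, and top-expressed
gene rankings.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .array_model import ArrayLayout
from .demux_count import CountMatrix, DedupPolicy, DedupResult, GeneMap, dedup_umis

__all__ = [
    "CATEGORIES",
    "SpotMetrics",
    "PrecisionResult",
    "MrnaAssumptions",
    "MrnaEstimate",
    "CategoryComparison",
    "SaturationCurve",
    "load_annotations",
    "spot_metrics",
    "compare_categories",
    "precision",
    "estimate_mrna",
    "total_rna_from_mass",
    "mrna_detection_ratio",
    "saturation",
    "gene_total_correlation",
    "top_expressed_genes",
]

CATEGORIES = ("background", "single", "double", "cluster")

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class PrecisionResult:
    sc: float  # median unique transcripts, single-cell spots
    ec: float  # median unique transcripts, background spots
    precision: float


@dataclass(frozen=True)
class MrnaAssumptions:
    """Conversion assumptions for RNA-mass -> molecule estimates.

    ``mass_per_nt`` is the average molar mass of one RNA nucleotide
    (g/mol/nt); 340.5 is the standard value. ``mrna_fraction_range`` brackets
    the mRNA share of total RNA (1-5%).
    """

    extraction_efficiency: float = 0.5
    avg_mrna_len: float = 1000.0
    mrna_fraction_range: tuple[float, float] = (0.01, 0.05)
    mass_per_nt: float = 340.5

    def __post_init__(self) -> None:
        if not (0 < self.extraction_efficiency <= 1):
            raise ValueError("extraction_efficiency must be in (0, 1]")
        lo, hi = self.mrna_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("mrna_fraction_range must satisfy 0 < low <= high <= 1")
        if self.avg_mrna_len <= 0 or self.mass_per_nt <= 0:
            raise ValueError("avg_mrna_len and mass_per_nt must be positive")


@dataclass(frozen=True)
class MrnaEstimate:
    total_rna_molecules_per_cell: int
    mrna_low: int
    mrna_high: int


@dataclass(frozen=True)
class CategoryComparison:
    category_a: str
    category_b: str
    n_a: int
    n_b: int
    rank_sum: float  # rank sum of category_a in the pooled ranking
    p_value: float
    method: str  # 'exact' or 'asymptotic'

    @property
    def star(self) -> str:
        if self.p_value < 1e-4:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "NS"


@dataclass
class SaturationCurve:
    """Unique transcripts and genes detected per subsampled depth."""

    points: pd.DataFrame  # depth, unique_transcripts, genes

    def write_tsv(self, path: str | Path) -> None:
        self.points.to_csv(path, sep="\t", index=False)


def load_annotations(path: str | Path, layout: ArrayLayout | None = None) -> pd.DataFrame:
    """Read the spot-category TSV (columns spot_id, category) with validation."""
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or lines[0].split("\t") != ["spot_id", "category"]:
        raise ValueError("annotation TSV line 1: expected header 'spot_id\\tcategory'")
    known_spots = {s.spot_id for s in layout.spots} if layout is not None else None
    rows = []
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise ValueError(f"annotation TSV line {line_no}: expected 2 columns, got {len(cols)}")
        sid, cat = cols
        if cat not in CATEGORIES:
            raise ValueError(
                f"annotation TSV line {line_no}: unknown category {cat!r} "
                f"(expected one of {', '.join(CATEGORIES)})"
            )
        if known_spots is not None and sid not in known_spots:
            raise ValueError(f"annotation TSV line {line_no}: unknown spot id {sid!r}")
        rows.append((sid, cat))
    return pd.DataFrame(rows, columns=["spot_id", "category"])


def spot_metrics(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-spot genes detected and unique-transcript totals.

    Accepts a :class:`CountMatrix` (its unique layer is used) or a bare
    spot x gene DataFrame of unique counts.
    """
    unique = matrix.unique if isinstance(matrix, CountMatrix) else matrix
    genes_detected = (unique > 0).sum(axis=1)
    unique_transcripts = unique.sum(axis=1)
    return pd.DataFrame(
        {
            "spot_id": unique.index,
            "genes_detected": genes_detected.to_numpy(),
            "unique_transcripts": unique_transcripts.to_numpy(),
        }
    ).reset_index(drop=True)


def _category_values(
    metrics: pd.DataFrame, annotations: pd.DataFrame, category: str, metric: str
) -> np.ndarray:
    merged = metrics.merge(annotations, on="spot_id", how="inner")
    vals = merged.loc[merged["category"] == category, metric].to_numpy(dtype=float)
    return vals


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by full enumeration (handles ties).

    Returns (rank sum of a, p). The p-value is the probability, over all
    equally likely assignments of pooled observations to the two groups, of a
    rank sum at least as far from its mean as the observed one.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - mu)
    n_extreme = 0
    n_total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(comb)].sum()
        n_total += 1
        if abs(w - mu) >= dev - 1e-9:
            n_extreme += 1
    return w_obs, n_extreme / n_total


def compare_categories(
    metrics: pd.DataFrame,
    annotations: pd.DataFrame,
    metric: str = "unique_transcripts",
    pair: tuple[str, str] = ("single", "background"),
    exact_max_n: int = 8,
) -> CategoryComparison:
    """Two-sided Wilcoxon rank-sum test between two spot categories.

    Small groups (both sizes <= ``exact_max_n``) use exact enumeration of the
    rank-sum distribution, which is valid under ties; larger groups use the
    tie-corrected normal approximation. Stars: ``**`` for p < 1e-4, ``*`` for
    p < 0.05, else NS.
    """
    cat_a, cat_b = pair
    for c in pair:
        if c not in CATEGORIES:
            raise ValueError(f"unknown category {c!r}")
    a = _category_values(metrics, annotations, cat_a, metric)
    b = _category_values(metrics, annotations, cat_b, metric)
    if len(a) == 0 or len(b) == 0:
        empty = cat_a if len(a) == 0 else cat_b
        raise ValueError(f"category {empty!r} has no spots")
    if max(len(a), len(b)) <= exact_max_n:
        w, p = _exact_ranksum_p(a, b)
        method = "exact"
    else:
        ranks = stats.rankdata(np.concatenate([a, b]))
        w = float(ranks[: len(a)].sum())
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0  # all observations identical: no evidence of a shift
        else:
            _u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        method = "asymptotic"
    return CategoryComparison(cat_a, cat_b, len(a), len(b), w, float(p), method)


def precision(metrics: pd.DataFrame, annotations: pd.DataFrame) -> PrecisionResult:
    """Background-corrected precision (SC - EC) / SC on unique transcripts."""
    sc_vals = _category_values(metrics, annotations, "single", "unique_transcripts")
    ec_vals = _category_values(metrics, annotations, "background", "unique_transcripts")
    if len(sc_vals) == 0 or len(ec_vals) == 0:
        raise ValueError("precision needs at least one single and one background spot")
    sc = float(np.median(sc_vals))
    ec = float(np.median(ec_vals))
    if sc == 0:
        raise ValueError("precision undefined: median single-cell signal is zero")
    return PrecisionResult(sc=sc, ec=ec, precision=(sc - ec) / sc)


def estimate_mrna(
    total_rna_molecules: int, assumptions: MrnaAssumptions = MrnaAssumptions()
) -> MrnaEstimate:
    """mRNA molecules per cell bracketed by the mRNA fraction of total RNA."""
    if total_rna_molecules <= 0:
        raise ValueError("total_rna_molecules must be positive")
    lo_f, hi_f = assumptions.mrna_fraction_range
    return MrnaEstimate(
        total_rna_molecules_per_cell=int(total_rna_molecules),
        mrna_low=int(round(lo_f * total_rna_molecules)),
        mrna_high=int(round(hi_f * total_rna_molecules)),
    )


def total_rna_from_mass(
    extracted_mass_ng: float,
    n_cells: int,
    assumptions: MrnaAssumptions = MrnaAssumptions(),
) -> float:
    """Total RNA molecules per cell from extracted mass and cell count.

    mass is corrected for extraction efficiency, divided by the molar mass of
    an average transcript (avg_mrna_len * mass_per_nt), converted to molecules
    via Avogadro's number, and divided by the number of cells.
    """
    if extracted_mass_ng <= 0 or n_cells <= 0:
        raise ValueError("mass and cell count must be positive")
    grams = extracted_mass_ng * 1e-9 / assumptions.extraction_efficiency
    moles = grams / (assumptions.avg_mrna_len * assumptions.mass_per_nt)
    return moles * AVOGADRO / n_cells


def mrna_detection_ratio(mrna_low: int, transcripts_per_cell: float) -> int:
    """Floor of estimated mRNA molecules over detected transcripts per cell."""
    if transcripts_per_cell <= 0:
        raise ValueError("transcripts_per_cell must be positive")
    return math.floor(mrna_low / transcripts_per_cell)


def saturation(
    reads: pd.DataFrame,
    depths: Sequence[int],
    seed: int,
    gene_map: Mapping[str, str] | GeneMap,
    policy: DedupPolicy = DedupPolicy(),
    umi_length: int = 9,
) -> SaturationCurve:
    """Unique transcripts and genes detected at nested subsampled depths.

    ``reads`` is the annotated read table (demultiplexed + mapped). A single
    seeded permutation makes every depth's subsample a subset of all larger
    depths, so the full-depth point reproduces the standard pipeline output
    bit for bit.
    """
    depths = list(depths)
    if any(d < 0 for d in depths):
        raise ValueError("depths must be non-negative")
    if sorted(set(depths)) != depths:
        raise ValueError("depths must be strictly increasing")
    if depths and depths[-1] > len(reads):
        raise ValueError(
            f"depth {depths[-1]} exceeds the library size {len(reads)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(reads))
    rows = []
    for d in depths:
        if d == 0:
            rows.append((0, 0, 0))
            continue
        sub = reads.iloc[np.sort(perm[:d])]
        dd = dedup_umis(sub, gene_map, policy, umi_length)
        n_unique = int(dd.unique_counts["count"].sum()) if len(dd.unique_counts) else 0
        n_genes = int(dd.unique_counts["gene_id"].nunique()) if len(dd.unique_counts) else 0
        rows.append((d, n_unique, n_genes))
    return SaturationCurve(
        pd.DataFrame(rows, columns=["depth", "unique_transcripts", "genes"])
    )


def gene_total_correlation(totals_a: pd.Series, totals_b: pd.Series) -> float:
    """Pearson correlation of per-gene totals between two libraries."""
    if not totals_a.index.equals(totals_b.index):
        raise ValueError("gene universes differ between the two libraries")
    if len(totals_a) < 3:
        raise ValueError("need at least 3 genes")
    a = totals_a.to_numpy(dtype=float)
    b = totals_b.to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in per-gene totals")
    r, _p = stats.pearsonr(a, b)
    return float(r)


def top_expressed_genes(
    matrix: CountMatrix | pd.DataFrame,
    annotations: pd.DataFrame,
    category: str = "single",
    n: int = 10,
) -> pd.DataFrame:
    """Genes ranked by unique counts summed over spots of one category.

    Ties break lexicographically by gene id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unique = matrix.unique if isinstance(matrix, CountMatrix) else matrix
    spot_ids = annotations.loc[annotations["category"] == category, "spot_id"]
    spot_ids = [s for s in spot_ids if s in unique.index]
    if not spot_ids:
        raise ValueError(f"category {category!r} has no spots in the matrix")
    totals = unique.loc[spot_ids].sum(axis=0)
    order = sorted(totals.index, key=lambda g: (-totals[g], g))
    top = order[:n]
    return pd.DataFrame(
        {"gene_id": top, "total_unique": [int(totals[g]) for g in top]}
    )
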