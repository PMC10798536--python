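"""Barcoded capture-array model.

A MASC-seq capture array is a printed grid of ~100 um oligo-dT spots. Each
capture spot carries one spot-unique positional barcode that is read at the
start of R1, followed by a semi-random UMI and a poly-T capture region.
A small number of non-capturing *frame* spots on the array border exist only
for image orientation. This module defines the probe geometry, generates
barcode sets with a guaranteed minimum pairwise Hamming distance (so that
single-substitution correction is unambiguous), lays spots out on a
centered-rectangular lattice, and round-trips layouts through a TSV
interchange format compatible in spirit with ST-pipeline barcode files
(``barcode <tab> x <tab> y`` plus ``spot_id`` and ``kind`` columns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from ._seq import DNA_ALPHABET, encode_seqs

__all__ = [
    "ProbeSpec",
    "SpotBarcodeSet",
    "Spot",
    "ArrayLayout",
    "BarcodeDesignError",
    "LayoutParseError",
    "generate_barcodes",
    "build_layout",
    "write_layout",
    "read_layout",
]

SPOT_KINDS = ("barcoded", "frame")


class BarcodeDesignError(ValueError):
    """A requested barcode set cannot be constructed."""


class LayoutParseError(ValueError):
    """A layout TSV is malformed; carries the offending 1-based line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"layout TSV line {line_no}: {message}")


@dataclass(frozen=True)
class ProbeSpec:
    """Geometry of the capture probe and the paired sequencing reads.

    The probe is, 5'->3': an 18-nt spot barcode, a 9-nt UMI and a poly-T
    capture region. R1 covers barcode+UMI (31 cycles), R2 the transcript
    fragment (121 cycles).
    """

    barcode_length: int = 18
    umi_length: int = 9
    capture_region: str = "poly-T20VN"
    r1_length: int = 31
    r2_length: int = 121

    def __post_init__(self) -> None:
        for name in ("barcode_length", "umi_length", "r1_length", "r2_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.barcode_length + self.umi_length > self.r1_length:
            raise ValueError(
                "barcode_length + umi_length must fit within r1_length "
                f"({self.barcode_length} + {self.umi_length} > {self.r1_length})"
            )


@dataclass
class SpotBarcodeSet:
    """Spot-id -> barcode mapping with a declared minimum pairwise distance."""

    entries: dict[str, str]
    min_pairwise_hamming: int = 3

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries.values())))

    def __len__(self) -> int:
        return len(self.entries)

    def as_matrix(self) -> np.ndarray:
        return encode_seqs(list(self.entries.values()))

    def validate(self) -> None:
        """Check length uniformity, alphabet, distinctness and pairwise distance."""
        seqs = list(self.entries.values())
        if not seqs:
            raise BarcodeDesignError("barcode set is empty")
        length = len(seqs[0])
        for sid, bc in self.entries.items():
            if len(bc) != length:
                raise BarcodeDesignError(f"barcode for {sid} has length {len(bc)} != {length}")
            if set(bc) - set(DNA_ALPHABET):
                raise BarcodeDesignError(f"barcode for {sid} contains non-ACGT characters")
        if len(set(seqs)) != len(seqs):
            raise BarcodeDesignError("barcodes are not pairwise distinct")
        mat = self.as_matrix()
        for i in range(len(mat) - 1):
            d = (mat[i + 1 :] != mat[i]).sum(axis=1)
            if d.min() < self.min_pairwise_hamming:
                j = i + 1 + int(d.argmin())
                raise BarcodeDesignError(
                    f"barcodes {i} and {j} are at Hamming distance {int(d.min())} "
                    f"< declared minimum {self.min_pairwise_hamming}"
                )


@dataclass(frozen=True)
class Spot:
    spot_id: str
    x_um: float
    y_um: float
    kind: str
    barcode: str | None = None


@dataclass
class ArrayLayout:
    """Physical array layout: spot positions, kinds and barcodes.

    Coordinates are metadata for image work; nothing in read counting uses
    them. Frame spots carry no barcode and can never receive reads.
    """

    spots: list[Spot]
    pitch_um: float = 150.0
    spot_diameter_um: float = 100.0

    @property
    def barcoded_spots(self) -> list[Spot]:
        return [s for s in self.spots if s.kind == "barcoded"]

    @property
    def frame_spots(self) -> list[Spot]:
        return [s for s in self.spots if s.kind == "frame"]

    @property
    def barcoded_spot_ids(self) -> list[str]:
        return [s.spot_id for s in self.barcoded_spots]

    def barcode_of(self) -> dict[str, str]:
        return {s.spot_id: s.barcode for s in self.barcoded_spots}

    def barcode_set(self, min_pairwise_hamming: int = 3) -> SpotBarcodeSet:
        return SpotBarcodeSet(self.barcode_of(), min_pairwise_hamming)

    def validate(self) -> None:
        coords = [(s.x_um, s.y_um) for s in self.spots]
        if len(set(coords)) != len(coords):
            raise ValueError("layout has duplicate spot coordinates")
        ids = [s.spot_id for s in self.spots]
        if len(set(ids)) != len(ids):
            raise ValueError("layout has duplicate spot ids")
        for s in self.spots:
            if s.kind not in SPOT_KINDS:
                raise ValueError(f"unknown spot kind {s.kind!r} for {s.spot_id}")
            if s.kind == "barcoded" and not s.barcode:
                raise ValueError(f"barcoded spot {s.spot_id} lacks a barcode")
            if s.kind == "frame" and s.barcode:
                raise ValueError(f"frame spot {s.spot_id} carries a barcode")


def generate_barcodes(
    n: int, length: int = 18, min_hamming: int = 3, seed: int = 0
) -> SpotBarcodeSet:
    """Draw ``n`` distinct barcodes with pairwise Hamming distance >= ``min_hamming``.

    Rejection sampling against the already-accepted set; deterministic for a
    fixed seed. Raises :class:`BarcodeDesignError` when the constraint cannot
    be met (trivially, or after a bounded number of attempts).
    """
    if n < 1 or length < 1 or min_hamming < 1:
        raise ValueError("n, length and min_hamming must all be >= 1")
    if n > 1 and min_hamming > length:
        raise BarcodeDesignError(
            f"cannot place {n} barcodes of length {length} at pairwise Hamming "
            f">= {min_hamming}: maximum distance at this length is {length}"
        )
    if n > 4**length:
        raise BarcodeDesignError(
            f"cannot place {n} distinct barcodes of length {length}: only {4**length} exist"
        )
    rng = np.random.default_rng(seed)
    accepted = np.empty((n, length), dtype=np.uint8)
    n_acc = 0
    attempts = 0
    max_attempts = 200 * n + 1000
    while n_acc < n:
        if attempts >= max_attempts:
            raise BarcodeDesignError(
                f"could not place {n} barcodes of length {length} at pairwise "
                f"Hamming >= {min_hamming} within {max_attempts} sampling attempts"
            )
        attempts += 1
        cand = rng.integers(0, 4, size=length).astype(np.uint8)
        if n_acc and int((accepted[:n_acc] != cand).sum(axis=1).min()) < min_hamming:
            continue
        accepted[n_acc] = cand
        n_acc += 1
    seqs = ["".join(DNA_ALPHABET[b] for b in row) for row in accepted]
    entries = {f"s{i + 1:04d}": s for i, s in enumerate(seqs)}
    return SpotBarcodeSet(entries=entries, min_pairwise_hamming=min_hamming)


def build_layout(
    n_barcoded: int = 1934,
    n_frame: int = 66,
    pitch_um: float = 150.0,
    barcodes: SpotBarcodeSet | None = None,
    spot_diameter_um: float = 100.0,
) -> ArrayLayout:
    """Lay out ``n_barcoded`` + ``n_frame`` spots on a centered-rectangular lattice.

    Rows are offset by half the pitch in alternating fashion; frame spots are
    placed on the array border (they orient the image and never capture RNA).
    The default counts reproduce the production array: 1934 barcoded + 66
    frame = 2000 spots.
    """
    if n_barcoded < 0 or n_frame < 0:
        raise ValueError("spot counts must be non-negative")
    if barcodes is None and n_barcoded > 0:
        raise ValueError("a SpotBarcodeSet is required when n_barcoded > 0")
    if n_barcoded > 0 and len(barcodes) < n_barcoded:
        raise ValueError(
            f"barcode set has {len(barcodes)} entries but {n_barcoded} barcoded "
            "spots were requested"
        )
    total = n_barcoded + n_frame
    if total == 0:
        return ArrayLayout([], pitch_um, spot_diameter_um)
    n_cols = max(1, math.ceil(math.sqrt(total)))
    n_rows = math.ceil(total / n_cols)
    positions = []  # (row, col) row-major, truncated to the spot count
    for row in range(n_rows):
        for col in range(n_cols):
            if len(positions) < total:
                positions.append((row, col))
    last_row = positions[-1][0]
    border = [
        (r, c)
        for (r, c) in positions
        if r == 0 or r == last_row or c == 0 or c == n_cols - 1
    ]
    if len(border) < n_frame:  # degenerate tiny arrays: spill frames inward
        interior = [p for p in positions if p not in set(border)]
        border = border + interior[: n_frame - len(border)]
    frame_pos = border[:n_frame]
    frame_set = set(frame_pos)
    barcoded_pos = [p for p in positions if p not in frame_set][:n_barcoded]

    def coord(row: int, col: int) -> tuple[float, float]:
        x = (col + 0.5 * (row % 2)) * pitch_um
        y = row * pitch_um
        return x, y

    spots: list[Spot] = []
    barcode_items = list(barcodes.entries.items()) if barcodes is not None else []
    for (sid, bc), (row, col) in zip(barcode_items, barcoded_pos):
        x, y = coord(row, col)
        spots.append(Spot(sid, x, y, "barcoded", bc))
    for i, (row, col) in enumerate(frame_pos):
        x, y = coord(row, col)
        spots.append(Spot(f"f{i + 1:04d}", x, y, "frame", None))
    layout = ArrayLayout(spots, pitch_um, spot_diameter_um)
    layout.validate()
    return layout


_HEADER = "spot_id\tbarcode\tx_um\ty_um\tkind"


def write_layout(layout: ArrayLayout, path: str | Path) -> None:
    """Write the layout TSV (header + one row per spot; frame barcodes empty)."""
    lines = [_HEADER]
    for s in layout.spots:
        lines.append(
            f"{s.spot_id}\t{s.barcode or ''}\t{s.x_um:.2f}\t{s.y_um:.2f}\t{s.kind}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_layout(
    path: str | Path, pitch_um: float = 150.0, spot_diameter_um: float = 100.0
) -> ArrayLayout:
    """Parse a layout TSV; malformed rows fail with their 1-based line number."""
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines:
        raise LayoutParseError(1, "empty file")
    if lines[0] != _HEADER:
        raise LayoutParseError(1, f"expected header {_HEADER!r}, got {lines[0]!r}")
    spots: list[Spot] = []
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 5:
            raise LayoutParseError(line_no, f"expected 5 columns, got {len(cols)}")
        sid, bc, x_s, y_s, kind = cols
        try:
            x, y = float(x_s), float(y_s)
        except ValueError:
            raise LayoutParseError(line_no, f"non-numeric coordinate {x_s!r}/{y_s!r}") from None
        if kind not in SPOT_KINDS:
            raise LayoutParseError(line_no, f"unknown spot kind {kind!r}")
        if kind == "barcoded":
            if not bc or set(bc) - set(DNA_ALPHABET):
                raise LayoutParseError(line_no, f"invalid barcode {bc!r} for barcoded spot")
        elif bc:
            raise LayoutParseError(line_no, "frame spot must have an empty barcode field")
        spots.append(Spot(sid, x, y, kind, bc or None))
    layout = ArrayLayout(spots, pitch_um, spot_diameter_um)
    layout.validate()
    return layout
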