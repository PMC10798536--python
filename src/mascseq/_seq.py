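"""Small shared sequence helpers."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming distance undefined for lengths {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def encode_seqs(seqs: list[str]) -> np.ndarray:
    """Encode equal-length DNA strings as a (n, L) uint8 matrix of byte values."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), len(seqs[0])
    )


def random_dna(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 4, size=length)
    return "".join(DNA_ALPHABET[i] for i in idx)
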