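"""Small shared helpers: seeds, sequence utilities, weighted medians."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# IUPAC ambiguity codes, enough for PAM patterns (NGG, TTTV, NAG, ...).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True if ``seq`` matches the IUPAC ``pattern`` position by position."""
    if len(pattern) != len(seq):
        return False
    return all(base in IUPAC[p] for p, base in zip(pattern, seq))


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministically fan a master seed out to a named pipeline stage.

    Stable across runs and platforms (crc32-based), always < 2**31 so the
    result is safe for any RNG constructor.
    """
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: smallest v with cumulative weight >= half."""
    values = np.asarray(values)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0 or weights.sum() <= 0:
        raise ValueError("weighted_median of empty/zero-weight data")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    idx = np.searchsorted(cum, cum[-1] / 2.0)
    return float(values[order][idx])


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))
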