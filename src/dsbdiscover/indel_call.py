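"""Amplicon indel calling by flank anchoring and length difference.

A read is classified against an amplicon reference by locating exact,
unique matches to two 20-bp anchor sequences positioned 20 bp outside each
end of the gRNA target span. Reads missing either anchor (or matching it
more than once, or matching in both orientations) are excluded; reads whose
mean base quality is not strictly above the threshold are excluded; for the
rest the indel size is simply the length difference between the observed
flank-to-flank segment and the reference one. Substitutions between the
flanks therefore never change a call — this is a length-only definition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from ._util import revcomp

FLANK_LEN = 20
FLANK_STANDOFF = 20
DEFAULT_MIN_MEAN_Q = 20.0

EXCLUDED_NO_FLANK = "no_flank"
EXCLUDED_QUALITY = "quality"


@dataclass(frozen=True)
class AmpliconSpec:
    """Amplicon reference with its two flank anchors located."""

    ref_seq: str
    target_start: int
    target_end: int
    left_flank: str
    right_flank: str
    inner_ref_len: int

    def __post_init__(self) -> None:
        for name, flank in (("left", self.left_flank), ("right", self.right_flank)):
            n = _count_occurrences(self.ref_seq, flank)
            if n != 1:
                raise ValueError(f"{name} flank occurs {n} times in reference; must be unique")


def locate_flanks(ref_seq: str, target_start: int, target_end: int) -> AmpliconSpec:
    """Derive the two 20-bp anchors sitting 20 bp outside the target span."""
    if not 0 <= target_start < target_end <= len(ref_seq):
        raise ValueError("target span out of reference bounds")
    lo = target_start - FLANK_STANDOFF - FLANK_LEN
    hi = target_end + FLANK_STANDOFF + FLANK_LEN
    if lo < 0 or hi > len(ref_seq):
        raise ValueError(
            f"reference too short to host {FLANK_LEN}-bp flanks at "
            f"{FLANK_STANDOFF}-bp standoff (need [{lo}, {hi}))"
        )
    left = ref_seq[lo:lo + FLANK_LEN]
    right = ref_seq[target_end + FLANK_STANDOFF:
                    target_end + FLANK_STANDOFF + FLANK_LEN]
    inner_ref_len = (target_end + FLANK_STANDOFF) - (target_start - FLANK_STANDOFF)
    return AmpliconSpec(
        ref_seq=ref_seq, target_start=target_start, target_end=target_end,
        left_flank=left, right_flank=right, inner_ref_len=inner_ref_len,
    )


def _count_occurrences(hay: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1  # overlapping occurrences count


def _inner_length(seq: str, spec: AmpliconSpec) -> Optional[int]:
    """Flank-to-flank inner length if both flanks occur exactly once, in order."""
    if _count_occurrences(seq, spec.left_flank) != 1:
        return None
    if _count_occurrences(seq, spec.right_flank) != 1:
        return None
    li = seq.find(spec.left_flank)
    ri = seq.find(spec.right_flank)
    inner = ri - (li + FLANK_LEN)
    if inner < 0:
        return None
    return inner


@dataclass(frozen=True)
class ReadCall:
    indel_size: Optional[int] = None
    excluded_reason: Optional[str] = None

    @property
    def excluded(self) -> bool:
        return self.excluded_reason is not None


def call_read(read_seq: str, read_quals: Sequence[float], spec: AmpliconSpec,
              min_mean_q: float = DEFAULT_MIN_MEAN_Q) -> ReadCall:
    """Classify one read: signed indel size, or an exclusion with reason.

    The read is tried forward, then reverse-complemented; a read whose
    flanks resolve in both orientations is ambiguous and excluded. The
    quality filter is strict: mean quality exactly at ``min_mean_q`` is
    excluded.
    """
    if len(read_seq) != len(read_quals):
        raise ValueError("read sequence and quality lengths differ")
    fwd = _inner_length(read_seq, spec)
    rev = _inner_length(revcomp(read_seq), spec)
    if (fwd is None) == (rev is None):  # neither, or ambiguous both
        return ReadCall(excluded_reason=EXCLUDED_NO_FLANK)
    if float(np.mean(read_quals)) <= min_mean_q:
        return ReadCall(excluded_reason=EXCLUDED_QUALITY)
    inner = fwd if fwd is not None else rev
    return ReadCall(indel_size=inner - spec.inner_ref_len)


@dataclass
class IndelSummary:
    """Per-amplicon indel-size histogram with exact exclusion bookkeeping."""

    n_input: int
    n_excluded_no_flank: int
    n_excluded_quality: int
    histogram: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        analyzed = sum(self.histogram.values())
        if self.n_input != self.n_excluded_no_flank + self.n_excluded_quality + analyzed:
            raise ValueError("indel summary does not conserve read counts")

    @property
    def n_analyzed(self) -> int:
        return sum(self.histogram.values())

    @property
    def indel_fraction(self) -> float:
        n = self.n_analyzed
        if n == 0:
            return 0.0
        return sum(c for size, c in self.histogram.items() if size != 0) / n


ReadLike = Union[tuple, "object"]  # (name, seq, quals) tuples or Bio SeqRecords


def _as_seq_quals(read: ReadLike) -> tuple[str, Sequence[float]]:
    if isinstance(read, tuple):
        _, seq, quals = read
        return seq, quals
    return str(read.seq), read.letter_annotations["phred_quality"]


def summarize_indels(reads: Iterable[ReadLike], spec: AmpliconSpec,
                     min_mean_q: float = DEFAULT_MIN_MEAN_Q) -> IndelSummary:
    """Aggregate :func:`call_read` over a read set (order never matters)."""
    hist: Counter = Counter()
    n_input = n_no_flank = n_quality = 0
    for read in reads:
        seq, quals = _as_seq_quals(read)
        n_input += 1
        call = call_read(seq, quals, spec, min_mean_q=min_mean_q)
        if call.excluded_reason == EXCLUDED_NO_FLANK:
            n_no_flank += 1
        elif call.excluded_reason == EXCLUDED_QUALITY:
            n_quality += 1
        else:
            hist[call.indel_size] += 1
    return IndelSummary(
        n_input=n_input, n_excluded_no_flank=n_no_flank,
        n_excluded_quality=n_quality, histogram=dict(sorted(hist.items())),
    )
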