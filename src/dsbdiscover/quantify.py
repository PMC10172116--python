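"""Window enrichment (reads per million), background offsets, coverage tracks.

The enrichment statistic is the one usual for break-site pileups: the number
of reads whose alignment start falls in a fixed window centred at the cut
(1.5 kb by default, half-open ``[pos - w/2, pos + w/2)``), scaled per one
million total library reads (RPM). Both mates of a pair count separately;
windows are clipped silently at chromosome edges. Background enrichment is
the same statistic evaluated 10 kb downstream of the cut (upstream fallback
with a flag when the downstream position leaves the chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align_io import AlignmentSet

DEFAULT_WINDOW = 1500
DEFAULT_BG_OFFSET = 10000


def rpm_window(aln: AlignmentSet, chrom: str, pos: int,
               window: int = DEFAULT_WINDOW) -> float:
    """Reads with alignment start in ``[pos - w//2, pos + w//2)`` per million."""
    total = aln.total_reads
    if total == 0:
        raise ValueError("cannot compute RPM on an empty alignment set")
    starts = aln.chrom_read_starts(chrom)
    lo, hi = pos - window // 2, pos + window // 2
    count = int(np.searchsorted(starts, hi) - np.searchsorted(starts, lo))
    return count * 1e6 / total


@dataclass(frozen=True)
class BackgroundRPM:
    """Background RPM result; ``value`` is None when no offset fits."""

    value: Optional[float]
    position: Optional[int]
    fallback_used: bool = False
    reason: Optional[str] = None


def background_rpm(aln: AlignmentSet, chrom: str, cut_pos: int,
                   offset: int = DEFAULT_BG_OFFSET,
                   window: int = DEFAULT_WINDOW) -> BackgroundRPM:
    """RPM at ``cut_pos + offset`` (reference orientation), upstream fallback."""
    if aln.genome is None:
        raise ValueError("alignment set carries no genome reference")
    chrlen = aln.genome.lengths[chrom]
    down, up = cut_pos + offset, cut_pos - offset
    if 0 <= down < chrlen:
        return BackgroundRPM(rpm_window(aln, chrom, down, window), down)
    if 0 <= up < chrlen:
        return BackgroundRPM(rpm_window(aln, chrom, up, window), up,
                             fallback_used=True,
                             reason="downstream offset beyond chromosome end")
    return BackgroundRPM(None, None, reason="both offsets out of range")


def coverage_track(aln: AlignmentSet, chrom: str, start: int, end: int
                   ) -> list[tuple[str, int, int, int]]:
    """Per-base read coverage as bedGraph intervals (zero runs omitted)."""
    if start >= end:
        raise ValueError("inverted or empty range")
    if aln.genome is not None and end > aln.genome.lengths[chrom]:
        raise ValueError("range beyond chromosome end")
    delta = np.zeros(end - start + 1, dtype=np.int64)
    for r in aln.records:
        if r.chrom != chrom:
            continue
        mates = [(r.start1, r.end1)]
        if not r.is_singleton:
            mates.append((r.start2, r.end2))
        for s, e in mates:
            s, e = max(s, start), min(e, end)
            if s < e:
                delta[s - start] += 1
                delta[e - start] -= 1
    cov = np.cumsum(delta[:-1])
    out: list[tuple[str, int, int, int]] = []
    run_start = 0
    for i in range(1, len(cov) + 1):
        if i == len(cov) or cov[i] != cov[run_start]:
            v = int(cov[run_start])
            if v != 0:
                out.append((chrom, start + run_start, start + i, v))
            run_start = i
    return out


def write_bedgraph(track: Sequence[tuple[str, int, int, int]], path: str,
                   trackline: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if trackline:
            fh.write(trackline.rstrip("\n") + "\n")
        for chrom, s, e, v in track:
            fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


@dataclass(frozen=True)
class EnrichmentRecord:
    """Paired enrichment at one site: treated vs no-drug, plus backgrounds."""

    chrom: str
    cut_pos: int
    rpm_inhibited: float
    rpm_no_drug: float
    rpm_bg_inhibited: Optional[float]
    rpm_bg_no_drug: Optional[float]


def enrichment_table(sites, aln_inhibited: AlignmentSet, aln_no_drug: AlignmentSet,
                     window: int = DEFAULT_WINDOW,
                     offset: int = DEFAULT_BG_OFFSET) -> list[EnrichmentRecord]:
    """Quantify each site in both arms; arms should be depth-matched first."""
    out = []
    for s in sites:
        bg_i = background_rpm(aln_inhibited, s.chrom, s.cut_pos, offset, window)
        bg_n = background_rpm(aln_no_drug, s.chrom, s.cut_pos, offset, window)
        out.append(EnrichmentRecord(
            chrom=s.chrom, cut_pos=s.cut_pos,
            rpm_inhibited=rpm_window(aln_inhibited, s.chrom, s.cut_pos, window),
            rpm_no_drug=rpm_window(aln_no_drug, s.chrom, s.cut_pos, window),
            rpm_bg_inhibited=bg_i.value, rpm_bg_no_drug=bg_n.value,
        ))
    return out
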