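"""Cleavage-site discovery from fragment pileups.

The scan is deliberately simple and fully specified so that every step has
a brute-force oracle: fragment midpoints are binned (50 bp), a sliding
window (500 bp, stride one bin) qualifies wherever it holds at least
``cutoff_c`` midpoints, overlapping qualifying windows merge into candidate
regions summarised by the weighted median midpoint, and each candidate is
resolved to a protospacer placement by scanning both strands around the
summit for PAM-adjacent matches with minimal Hamming distance to the guide.
Sites present in a matched no-Cas9 control are subtracted as presumed false
positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._util import hamming, revcomp, weighted_median
from .align_io import AlignmentSet
from .genome import (
    DEFAULT_PAM,
    GenomeRef,
    pam_matches,
    placement_coords,
    validate_nuclease,
)
from .quantify import DEFAULT_WINDOW, rpm_window

DEFAULT_BIN_SIZE = 50
DEFAULT_SCAN_WINDOW = 500
DEFAULT_CUTOFF = 2
DEFAULT_SEARCH_RADIUS = 75
DEFAULT_END_TOLERANCE = 75
DEFAULT_CONTROL_TOLERANCE = 100


@dataclass(frozen=True)
class GuideSpec:
    """A gRNA with its nuclease, PAM rule and mismatch budget."""

    name: str
    protospacer: str
    nuclease: str = "cas9"
    pam_rule: Optional[str] = None
    max_mismatch: int = 6

    def __post_init__(self) -> None:
        validate_nuclease(self.nuclease, self.protospacer)
        if self.pam_rule is None:
            object.__setattr__(self, "pam_rule", DEFAULT_PAM[self.nuclease])
        if not 0 <= self.max_mismatch < len(self.protospacer):
            raise ValueError("max_mismatch must be in [0, protospacer length)")


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    summit: int
    support: int
    region_start: int = 0
    region_end: int = 0


@dataclass(frozen=True)
class SiteCall:
    """A discovered cleavage site resolved to a protospacer placement."""

    chrom: str
    cut_pos: int
    strand: str
    matched_seq: str  # genomic protospacer, guide orientation
    pam_seq: str
    n_mismatch: int
    support: int
    rpm: float = float("nan")
    is_on_target: bool = field(default=False)


def bin_fragment_midpoints(aln: AlignmentSet, bin_size: int = DEFAULT_BIN_SIZE
                           ) -> dict[str, np.ndarray]:
    """Count proper-pair fragment midpoints per fixed-width bin, per chromosome."""
    if aln.genome is None:
        raise ValueError("alignment set carries no genome reference")
    counts = {
        name: np.zeros(-(-length // bin_size), dtype=np.int64)
        for name, length in aln.genome.lengths.items()
    }
    for r in aln.records:
        mid = r.midpoint
        if mid is None:
            continue
        counts[r.chrom][mid // bin_size] += 1
    return counts


def find_candidates(binned: dict[str, np.ndarray],
                    cutoff_c: int = DEFAULT_CUTOFF,
                    window: int = DEFAULT_SCAN_WINDOW,
                    bin_size: int = DEFAULT_BIN_SIZE) -> list[CandidateRegion]:
    """Sliding-window scan over binned midpoints, merged and summarised.

    A window of ``window`` bases (``window // bin_size`` bins, stride one
    bin) qualifies when it holds >= ``cutoff_c`` midpoints; overlapping
    qualifying windows merge, support is the midpoint count of the merged
    region, and the summit is the weighted median bin centre. Output is
    sorted by support descending, ties by coordinate.
    """
    if cutoff_c < 1:
        raise ValueError("cutoff_c must be >= 1")
    w = max(1, window // bin_size)
    out: list[CandidateRegion] = []
    for chrom, counts in binned.items():
        if len(counts) == 0 or counts.sum() == 0:
            continue
        n_windows = max(1, len(counts) - w + 1)
        sums = np.convolve(counts, np.ones(w, dtype=np.int64), mode="full")[w - 1:w - 1 + n_windows]
        qual = np.flatnonzero(sums >= cutoff_c)
        if qual.size == 0:
            continue
        # merge qualifying windows [i, i+w) that overlap
        breaks = np.flatnonzero(np.diff(qual) >= w)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [qual.size - 1]))
        for s_i, e_i in zip(starts, ends):
            b0, b1 = int(qual[s_i]), int(qual[e_i]) + w  # bin span of merged region
            b1 = min(b1, len(counts))
            region = counts[b0:b1]
            support = int(region.sum())
            centers = np.arange(b0, b1) * bin_size + bin_size // 2
            summit = int(weighted_median(centers, region))
            out.append(CandidateRegion(chrom=chrom, summit=summit, support=support,
                                       region_start=b0 * bin_size, region_end=b1 * bin_size))
    out.sort(key=lambda c: (-c.support, c.chrom, c.summit))
    return out


def refine_cut_candidates(aln: AlignmentSet, candidates: Sequence[CandidateRegion],
                          cutoff_c: int = DEFAULT_CUTOFF,
                          end_tolerance: int = DEFAULT_END_TOLERANCE,
                          pad: int = 300) -> list[CandidateRegion]:
    """Sharpen candidates to the break signature: fragment ends abutting a cut.

    Chromatin protection at a double-strand break means sonicated fragments
    *end* at the cut rather than spanning it, so a genuine cleavage site is a
    position where at least ``cutoff_c`` fragment ends (either end of a
    fragment) stack within ``end_tolerance`` bp. For each candidate region
    the maximum such stab count is found by an interval sweep; candidates
    below the cutoff are dropped, the rest get their summit moved to the
    centre of the first maximal stab run and their support replaced by the
    abutting-fragment count. Random background midpoint clusters rarely have
    coincident fragment ends, so this stage is what separates cut pileups
    from accidental coverage.
    """
    # fragment end positions per chromosome, sorted, with fragment bounds
    frags: dict[str, np.ndarray] = {}
    for chrom in {c.chrom for c in candidates}:
        spans = [r.fragment_span for r in aln.records
                 if r.chrom == chrom and not r.is_singleton]
        arr = np.asarray(spans, dtype=np.int64).reshape(-1, 2)
        frags[chrom] = arr
    out: list[CandidateRegion] = []
    for cand in candidates:
        arr = frags[cand.chrom]
        if arr.size == 0:
            continue
        lo, hi = cand.region_start - pad, cand.region_end + pad
        mids = (arr[:, 0] + arr[:, 1]) // 2
        sel = arr[(mids >= lo) & (mids < hi)]
        if sel.shape[0] == 0:
            continue
        ends = np.concatenate([sel[:, 0], sel[:, 1]])
        support, run_lo, run_hi = _max_stab(ends, end_tolerance)
        if support < cutoff_c:
            continue
        out.append(CandidateRegion(
            chrom=cand.chrom, summit=int((run_lo + run_hi) // 2),
            support=int(support),
            region_start=cand.region_start, region_end=cand.region_end,
        ))
    out.sort(key=lambda c: (-c.support, c.chrom, c.summit))
    return out


def _max_stab(points: np.ndarray, tol: int) -> tuple[int, int, int]:
    """Max number of points within any ``[c-tol, c+tol]`` stab, via sweep.

    Returns ``(count, run_lo, run_hi)`` where ``[run_lo, run_hi]`` is the
    first (leftmost) maximal run of stab centres ``c``.
    """
    starts = np.sort(points) - tol  # stab interval [p-tol, p+tol]
    ends = np.sort(points) + tol
    events = np.concatenate([
        np.stack([starts, np.ones_like(starts)], axis=1),
        np.stack([ends + 1, -np.ones_like(ends)], axis=1),
    ])
    order = np.lexsort((events[:, 1], events[:, 0]))  # position, then -1 before +1
    events = events[order]
    best = cur = 0
    best_lo = best_hi = int(starts[0])
    i = 0
    n = len(events)
    while i < n:
        pos = events[i, 0]
        while i < n and events[i, 0] == pos:
            cur += int(events[i, 1])
            i += 1
        nxt = events[i, 0] if i < n else pos + 1
        if cur > best:
            best = cur
            best_lo, best_hi = int(pos), int(nxt - 1)
    return best, best_lo, best_hi


def count_mismatches(a: str, b: str) -> int:
    """Hamming distance between two equal-length DNA strings (no gaps)."""
    return hamming(a.upper(), b.upper())


def match_protospacer(genome: GenomeRef, region: CandidateRegion, guide: GuideSpec,
                      search_radius: int = DEFAULT_SEARCH_RADIUS
                      ) -> Optional[SiteCall]:
    """Best PAM-adjacent protospacer placement near a candidate summit.

    Considers every placement on either strand whose modelled cut position
    lies within ``summit +/- search_radius`` and whose PAM satisfies the
    guide's rule; returns the placement minimising the mismatch count (ties:
    smallest |cut - summit|, then + strand, then leftmost), or None if the
    best exceeds ``max_mismatch`` or no PAM-adjacent placement exists.
    """
    L = len(guide.protospacer)
    pam_len = len(guide.pam_rule)
    chrom_seq = genome.seq(region.chrom)
    lo = max(0, region.summit - search_radius - L - pam_len)
    hi = min(len(chrom_seq) - L, region.summit + search_radius + L + pam_len)
    best = None  # (n_mm, dist, strand_rank, p, call fields)
    for strand in "+-":
        for p in range(lo, hi + 1):
            pam_start, pam_end, cut, span = placement_coords(
                p, L, strand, guide.nuclease, pam_len)
            if abs(cut - region.summit) > search_radius:
                continue
            if span[0] < 0 or span[1] > len(chrom_seq):
                continue
            if not pam_matches(genome, region.chrom, pam_start, pam_end,
                               strand, guide.pam_rule):
                continue
            proto_ref = chrom_seq[p:p + L]
            proto = proto_ref if strand == "+" else revcomp(proto_ref)
            n_mm = count_mismatches(proto, guide.protospacer)
            key = (n_mm, abs(cut - region.summit), 0 if strand == "+" else 1, p)
            if best is None or key < best[0]:
                pam_ref = chrom_seq[pam_start:pam_end]
                pam = pam_ref if strand == "+" else revcomp(pam_ref)
                best = (key, SiteCall(
                    chrom=region.chrom, cut_pos=cut, strand=strand,
                    matched_seq=proto, pam_seq=pam, n_mismatch=n_mm,
                    support=region.support, is_on_target=(n_mm == 0),
                ))
    if best is None or best[1].n_mismatch > guide.max_mismatch:
        return None
    return best[1]


def subtract_control(treated_sites: Sequence[SiteCall],
                     control_sites: Sequence[SiteCall],
                     tolerance: int = DEFAULT_CONTROL_TOLERANCE
                     ) -> tuple[list[SiteCall], list[SiteCall]]:
    """Remove treated sites within ``tolerance`` bp of a control site.

    Returns ``(kept, removed)``; the removed sites are the presumed false
    positives also present without the nuclease.
    """
    kept, removed = [], []
    by_chrom: dict[str, list[int]] = {}
    for c in control_sites:
        by_chrom.setdefault(c.chrom, []).append(c.cut_pos)
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    for s in treated_sites:
        cuts = by_chrom.get(s.chrom)
        hit = False
        if cuts:
            i = int(np.searchsorted(cuts, s.cut_pos))
            for j in (i - 1, i):
                if 0 <= j < len(cuts) and abs(cuts[j] - s.cut_pos) <= tolerance:
                    hit = True
                    break
        (removed if hit else kept).append(s)
    return kept, removed


def discover_sites(
    aln: AlignmentSet,
    control: Optional[AlignmentSet],
    genome: GenomeRef,
    guide: GuideSpec,
    cutoff_c: int = DEFAULT_CUTOFF,
    *,
    bin_size: int = DEFAULT_BIN_SIZE,
    window: int = DEFAULT_SCAN_WINDOW,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    end_tolerance: int = DEFAULT_END_TOLERANCE,
    control_tolerance: int = DEFAULT_CONTROL_TOLERANCE,
    rpm_window_size: int = DEFAULT_WINDOW,
    annotate_rpm: bool = True,
    return_removed: bool = False,
):
    """Full discovery pipeline for one treated sample (optionally vs control).

    bin -> candidate scan -> cut refinement -> protospacer matching ->
    per-cut deduplication (max support wins) -> RPM annotation -> control
    subtraction. Output is sorted by RPM descending, on-target sites first.
    """
    validate_nuclease(guide.nuclease, guide.protospacer)
    sites = _discover_one(aln, genome, guide, cutoff_c, bin_size, window,
                          search_radius, end_tolerance, rpm_window_size,
                          annotate_rpm)
    removed: list[SiteCall] = []
    if control is not None:
        ctrl_sites = _discover_one(control, genome, guide, cutoff_c, bin_size,
                                   window, search_radius, end_tolerance,
                                   rpm_window_size, False)
        sites, removed = subtract_control(sites, ctrl_sites, control_tolerance)
    sites.sort(key=lambda s: (not s.is_on_target, -s.rpm if s.rpm == s.rpm else 0.0,
                              s.chrom, s.cut_pos))
    if return_removed:
        return sites, removed
    return sites


def _discover_one(aln, genome, guide, cutoff_c, bin_size, window,
                  search_radius, end_tolerance, rpm_window_size,
                  annotate_rpm) -> list[SiteCall]:
    binned = bin_fragment_midpoints(aln, bin_size)
    candidates = find_candidates(binned, cutoff_c, window, bin_size)
    candidates = refine_cut_candidates(aln, candidates, cutoff_c, end_tolerance)
    by_cut: dict[tuple[str, int], SiteCall] = {}
    for cand in candidates:
        call = match_protospacer(genome, cand, guide, search_radius)
        if call is None:
            continue
        key = (call.chrom, call.cut_pos)
        if key not in by_cut or call.support > by_cut[key].support:
            by_cut[key] = call
    sites = list(by_cut.values())
    if annotate_rpm:
        sites = [replace(s, rpm=rpm_window(aln, s.chrom, s.cut_pos, rpm_window_size))
                 for s in sites]
    return sites
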