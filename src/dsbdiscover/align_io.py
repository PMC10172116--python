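"""Paired-end alignment containers, SAM I/O, filtering and depth matching.

The preprocessing contract mirrors standard ChIP-seq practice for break
mapping: keep properly paired reads with mapping quality >= 25, drop
singletons and positional PCR duplicates, then subset every compared sample
to the same number of read pairs so reads-per-million values are directly
comparable across libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pysam

from .genome import GenomeRef

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 25


@dataclass(frozen=True)
class ReadPairRecord:
    """One aligned pair (or orphaned single read) in 0-based coordinates.

    ``start1 <= start2`` always holds for proper pairs; ``mapq`` is the
    minimum of the two mates' mapping qualities (conservative). Orphans keep
    only mate-1 fields and carry ``is_singleton=True``.
    """

    qname: str
    chrom: str
    start1: int
    end1: int
    strand1: str
    start2: Optional[int] = None
    end2: Optional[int] = None
    strand2: Optional[str] = None
    mapq: int = 60
    is_duplicate: bool = False
    is_singleton: bool = False
    provenance: Optional[str] = None  # "site:<idx>" or "bg" when simulated

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if not self.is_singleton and (self.start2 is None or self.start1 > self.start2):
            raise ValueError(f"{self.qname}: proper pair requires start1 <= start2")

    @property
    def fragment_span(self) -> Optional[tuple[int, int]]:
        """(min start, max end) of the sequenced fragment; None for orphans."""
        if self.is_singleton:
            return None
        return (self.start1, max(self.end1, self.end2))

    @property
    def midpoint(self) -> Optional[int]:
        span = self.fragment_span
        if span is None:
            return None
        return (span[0] + span[1]) // 2

    def signature(self) -> tuple:
        """Positional duplicate signature: both mate starts plus strands."""
        return (self.chrom, self.start1, self.strand1, self.start2, self.strand2)


@dataclass
class AlignmentSet:
    """A collection of read pairs plus the bookkeeping RPM depends on."""

    records: list[ReadPairRecord]
    genome: Optional[GenomeRef] = None
    label: str = ""
    ledger: Optional[dict] = None        # simulator ground-truth provenance
    filter_report: Optional[dict] = None

    @property
    def total_reads(self) -> int:
        """Reads represented: two per pair, one per orphan (RPM denominator)."""
        return sum(1 if r.is_singleton else 2 for r in self.records)

    @property
    def n_pairs(self) -> int:
        return sum(1 for r in self.records if not r.is_singleton)

    def chrom_read_starts(self, chrom: str) -> np.ndarray:
        """Sorted alignment-start coordinates of every mate on ``chrom``."""
        starts: list[int] = []
        for r in self.records:
            if r.chrom != chrom:
                continue
            starts.append(r.start1)
            if not r.is_singleton:
                starts.append(r.start2)
        return np.sort(np.asarray(starts, dtype=np.int64))


def _sort_key(r: ReadPairRecord) -> tuple:
    return (r.chrom, r.start1, r.qname)


def sort_records(records: Sequence[ReadPairRecord],
                 genome: Optional[GenomeRef] = None) -> list[ReadPairRecord]:
    if genome is not None:
        order = {name: i for i, name in enumerate(genome.names)}
        return sorted(records, key=lambda r: (order[r.chrom], r.start1, r.qname))
    return sorted(records, key=_sort_key)


# --- SAM I/O -----------------------------------------------------------------

def write_sam(aln: AlignmentSet, path: str) -> None:
    """Emit coordinate-sorted SAM (1-based POS on disk, 0-based in memory)."""
    if aln.genome is None:
        raise ValueError("AlignmentSet needs a genome reference to write SAM")
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length}
               for name, length in aln.genome.lengths.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        tid = {name: i for i, name in enumerate(aln.genome.names)}
        segs = []
        for r in sort_records(aln.records, aln.genome):
            segs.extend(_pair_to_segments(r, tid, aln.genome, out.header))
        segs.sort(key=lambda s: (s.reference_id, s.reference_start, s.query_name))
        for seg in segs:
            out.write(seg)


def _pair_to_segments(r: ReadPairRecord, tid: dict, genome: GenomeRef, header):
    def seg(start, end, strand, flag, mate_start, tlen):
        a = pysam.AlignedSegment(header)
        a.query_name = r.qname
        a.reference_id = tid[r.chrom]
        a.reference_start = start
        a.mapping_quality = r.mapq
        a.cigarstring = f"{end - start}M"
        seq = genome.fetch(r.chrom, start, end)
        a.query_sequence = seq
        a.flag = flag
        a.next_reference_id = tid[r.chrom] if mate_start is not None else -1
        a.next_reference_start = mate_start if mate_start is not None else -1
        a.template_length = tlen
        return a

    PAIRED, PROPER, MUNMAP, REV, MREV, R1, R2 = 0x1, 0x2, 0x8, 0x10, 0x20, 0x40, 0x80
    if r.is_singleton:
        flag = PAIRED | MUNMAP | R1 | (REV if r.strand1 == "-" else 0)
        return [seg(r.start1, r.end1, r.strand1, flag, None, 0)]
    span = max(r.end1, r.end2) - r.start1
    f1 = PAIRED | PROPER | R1 | (REV if r.strand1 == "-" else 0) | (MREV if r.strand2 == "-" else 0)
    f2 = PAIRED | PROPER | R2 | (REV if r.strand2 == "-" else 0) | (MREV if r.strand1 == "-" else 0)
    return [
        seg(r.start1, r.end1, r.strand1, f1, r.start2, span),
        seg(r.start2, r.end2, r.strand2, f2, r.start1, -span),
    ]


def read_alignments(path: str, genome: GenomeRef) -> AlignmentSet:
    """Read SAM/BAM, pair mates by name, flag unmatched mates as singletons.

    Unknown chromosomes are a hard error naming the offending record;
    anomalous qname groups (more than two primary records) are skipped with
    a logged warning and counted in the returned set's ``filter_report``.
    """
    known = set(genome.names)
    groups: dict[str, list] = {}
    n_skipped = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                n_skipped += 1
                continue
            if seg.reference_name not in known:
                raise ValueError(
                    f"record {seg.query_name!r} maps to unknown chromosome "
                    f"{seg.reference_name!r}"
                )
            groups.setdefault(seg.query_name, []).append(seg)
    records: list[ReadPairRecord] = []
    n_malformed = 0
    for qname, segs in groups.items():
        if len(segs) > 2:
            n_malformed += 1
            logger.warning("qname %s has %d primary records; skipped", qname, len(segs))
            continue
        if len(segs) == 1 or segs[0].reference_name != segs[1].reference_name:
            for s in segs:  # mate-less, or mates on different chromosomes
                records.append(ReadPairRecord(
                    qname=qname, chrom=s.reference_name,
                    start1=s.reference_start, end1=s.reference_end,
                    strand1="-" if s.is_reverse else "+",
                    mapq=s.mapping_quality, is_singleton=True,
                ))
            continue
        a, b = sorted(segs, key=lambda s: (s.reference_start, s.is_read2))
        records.append(ReadPairRecord(
            qname=qname, chrom=a.reference_name,
            start1=a.reference_start, end1=a.reference_end,
            strand1="-" if a.is_reverse else "+",
            start2=b.reference_start, end2=b.reference_end,
            strand2="-" if b.is_reverse else "+",
            mapq=min(a.mapping_quality, b.mapping_quality),
        ))
    return AlignmentSet(
        records=sort_records(records, genome), genome=genome, label=path,
        filter_report={"n_unmapped_or_secondary": n_skipped,
                       "n_malformed_groups": n_malformed},
    )


# --- filtering and depth matching -------------------------------------------

def filter_alignments(aln: AlignmentSet, min_mapq: int = DEFAULT_MIN_MAPQ) -> AlignmentSet:
    """Apply the standard retention rules, in a fixed order.

    1. drop records with mapq < ``min_mapq``;
    2. drop singletons;
    3. drop positional PCR duplicates (identical chrom/start/strand signature
       for both mates; the first record in coordinate order is kept).

    The removal counts per reason are attached as ``filter_report``.
    Filtering is idempotent.
    """
    report = {"n_input_records": len(aln.records),
              "removed_mapq": 0, "removed_singleton": 0, "removed_duplicate": 0}
    kept: list[ReadPairRecord] = []
    seen: set[tuple] = set()
    for r in aln.records:  # records are kept in coordinate-sorted order
        if r.mapq < min_mapq:
            report["removed_mapq"] += 1
        elif r.is_singleton:
            report["removed_singleton"] += 1
        elif r.signature() in seen:
            report["removed_duplicate"] += 1
        else:
            seen.add(r.signature())
            kept.append(r)
    report["n_retained_pairs"] = len(kept)
    return AlignmentSet(records=kept, genome=aln.genome, label=aln.label,
                        ledger=aln.ledger, filter_report=report)


def subsample_equal_depth(samples: Sequence[AlignmentSet], seed: int) -> list[AlignmentSet]:
    """Subset every sample to the minimum pair count, uniformly at random.

    The per-sample RNG is derived from ``(seed, n_pairs)``; two samples with
    identical content therefore receive the identical subset, and a sample
    already at the minimum depth is returned unchanged.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples to depth-match")
    sizes = [s.n_pairs for s in samples]
    if any(n == 0 for n in sizes):
        raise ValueError("cannot depth-match an empty sample")
    if any(r.is_singleton for s in samples for r in s.records):
        raise ValueError("depth matching expects filtered (pair-only) samples")
    target = min(sizes)
    out = []
    for s, n in zip(samples, sizes):
        if n == target:
            out.append(s)
            continue
        rng = np.random.default_rng([int(seed), n])
        idx = np.sort(rng.choice(n, size=target, replace=False))
        recs = [s.records[i] for i in idx]
        out.append(replace_records(s, recs))
    return out


def replace_records(aln: AlignmentSet, records: list[ReadPairRecord]) -> AlignmentSet:
    return AlignmentSet(records=records, genome=aln.genome, label=aln.label,
                        ledger=aln.ledger, filter_report=aln.filter_report)
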