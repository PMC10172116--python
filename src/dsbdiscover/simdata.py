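"""Ground-truth simulator for MRE11 ChIP-seq-like data and amplicon reads.

The chromatin-immunoprecipitation model: a double-strand break protects DNA
so that sonicated fragments *end* at the cut. Each planted site draws a
Poisson number of bound fragment pairs with mean
``lambda0 * efficiency * residence_multiplier`` (the multiplier represents
prolonged MRE11 residence under DNA-PKcs inhibition and applies only in the
inhibited condition). Each fragment sits entirely on one side of the cut,
its cut-proximal end half-normally jittered off the cut, and extends away
from it; uniform background fragments model unspecific pulldown. Because
paired-end sequencing reads only the two fragment ends, pooled coverage
around a cut shows the characteristic two flanking peaks with a dip at the
cut itself.

Background fragments and their noise draws use RNG substreams independent
of the site fragments, so the background reads of the treated and control
conditions are identical under the same seed — the simulated analogue of an
inhibitor that causes no DNA damage of its own.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from ._util import hamming, revcomp
from .align_io import AlignmentSet, ReadPairRecord, sort_records
from .genome import (
    DEFAULT_PAM,
    GenomeRef,
    make_genome,
    placement_coords,
    realize_pam,
    validate_nuclease,
    write_fasta,
)
from .indel_call import FLANK_LEN, AmpliconSpec

__all__ = [
    "GenomeRef", "make_genome", "write_fasta", "AmpliconSpec",
    "PlantedSite", "SimConfig", "plant_sites", "simulate_chip_reads",
    "simulate_amplicon_reads", "write_truth_bed", "write_ledger_json",
    "write_fastq", "CONDITIONS",
]

CONDITIONS = ("treated_inhibited", "treated_no_drug", "no_cas9")

_MAPQ_GOOD = 60
_MAPQ_LOW = 10
_RESAMPLE_CAP = 1000


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted on- or off-target protospacer."""

    chrom: str
    cut_pos: int
    strand: str
    protospacer: str  # as planted, 5'->3' on ``strand``
    pam: str
    n_mismatch: int
    efficiency: float

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")
        if self.n_mismatch < 0:
            raise ValueError("n_mismatch must be >= 0")


@dataclass
class SimConfig:
    """Knobs of the fragment-accumulation model.

    lambda0
        Expected site-bound fragment pairs at efficiency 1 without inhibitor.
    residence_multiplier
        Fold increase of that mean under DNA-PKcs inhibition (>= 1);
        a value of 1 reproduces the no-drug arm exactly under the same seed.
    frag_len_min / frag_len_max
        Sonication fragment length bounds (bp); must fit two reads.
    end_sigma
        Half-normal scale (bp) of the cut-proximal fragment end's offset.
    read_len
        Bases sequenced from each fragment end (2 x 36 bp chemistry default).
    bg_pairs
        Uniform background fragment pairs genome-wide.
    dup_rate / lowmapq_rate / orphan_rate
        Per-pair probabilities of being PCR-duplicated, assigned a low
        mapping quality, or emitted as a mate-less singleton. The three
        categories are mutually exclusive (one categorical draw per pair) so
        the provenance ledger accounts for every removal exactly.
    """

    lambda0: float = 50.0
    residence_multiplier: float = 5.0
    frag_len_min: int = 150
    frag_len_max: int = 400
    end_sigma: float = 25.0
    read_len: int = 36
    bg_pairs: int = 3000
    dup_rate: float = 0.05
    lowmapq_rate: float = 0.05
    orphan_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residence_multiplier < 1:
            raise ValueError("residence_multiplier must be >= 1")
        if self.frag_len_min < 2 * self.read_len:
            raise ValueError("frag_len_min must be >= 2 * read_len")
        if self.frag_len_min > self.frag_len_max:
            raise ValueError("frag_len_min must be <= frag_len_max")
        for name in ("dup_rate", "lowmapq_rate", "orphan_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dup_rate + self.lowmapq_rate + self.orphan_rate > 1:
            raise ValueError("noise rates sum above 1")


# --- planting ----------------------------------------------------------------

def plant_sites(
    genome: GenomeRef,
    grna: str,
    pam_rule: Optional[str],
    site_requests: Sequence[tuple],
    seed: int,
    nuclease: str = "cas9",
) -> tuple[GenomeRef, list[PlantedSite]]:
    """Overwrite the genome with mismatched protospacer+PAM copies.

    Each request is ``(chrom, position, strand, n_mismatch, efficiency)``
    where ``position`` is the leftmost reference coordinate of the
    protospacer. Mutated positions are chosen at random; a substituted base
    is never the original one, so the recomputed Hamming distance always
    equals the request.
    """
    validate_nuclease(nuclease, grna)
    if pam_rule is None:
        pam_rule = DEFAULT_PAM[nuclease]
    L = len(grna)
    rng = np.random.default_rng(seed)
    buffers = {name: bytearray(seq, "ascii") for name, seq in genome}
    lengths = genome.lengths
    spans: dict[str, list[tuple[int, int]]] = {}
    sites: list[PlantedSite] = []

    for chrom, pos, strand, n_mm, eff in site_requests:
        if chrom not in buffers:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 0 <= n_mm <= L:
            raise ValueError(f"n_mismatch {n_mm} outside [0, {L}]")
        pam_start, pam_end, cut, span = placement_coords(
            pos, L, strand, nuclease, len(pam_rule))
        if span[0] < 0 or span[1] > lengths[chrom]:
            raise ValueError(f"site at {chrom}:{pos} ({strand}) out of bounds")
        for s0, s1 in spans.setdefault(chrom, []):
            if span[0] < s1 and s0 < span[1]:
                raise ValueError(f"site at {chrom}:{pos} overlaps a previous request")
        spans[chrom].append(span)

        proto = list(grna)
        if n_mm:
            for i in rng.choice(L, size=n_mm, replace=False):
                others = [b for b in "ACGT" if b != grna[i]]
                proto[i] = others[rng.integers(0, 3)]
        proto_s = "".join(proto)
        assert hamming(proto_s, grna) == n_mm
        pam_s = realize_pam(pam_rule, rng)

        proto_ref = proto_s if strand == "+" else revcomp(proto_s)
        pam_ref = pam_s if strand == "+" else revcomp(pam_s)
        buffers[chrom][pos:pos + L] = proto_ref.encode()
        buffers[chrom][pam_start:pam_end] = pam_ref.encode()
        sites.append(PlantedSite(
            chrom=chrom, cut_pos=cut, strand=strand, protospacer=proto_s,
            pam=pam_s, n_mismatch=n_mm, efficiency=float(eff),
        ))

    new_genome = GenomeRef(tuple(
        (name, buffers[name].decode("ascii")) for name, _ in genome
    ))
    return new_genome, sites


# --- ChIP read simulation ----------------------------------------------------

def simulate_chip_reads(
    genome: GenomeRef,
    sites: Sequence[PlantedSite],
    cfg: SimConfig,
    condition: str,
) -> AlignmentSet:
    """Simulate one library: site-bound + background fragment pairs.

    Deterministic per ``cfg.seed``; site fragments, background fragments and
    the two noise channels each use an independent substream.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    lengths = genome.lengths
    mult = cfg.residence_multiplier if condition == "treated_inhibited" else 1.0

    rng_sites = np.random.default_rng([cfg.seed, 11])
    rng_site_noise = np.random.default_rng([cfg.seed, 13])
    rng_bg = np.random.default_rng([cfg.seed, 17])
    rng_bg_noise = np.random.default_rng([cfg.seed, 19])

    records: list[ReadPairRecord] = []
    ledger = {
        "condition": condition,
        "n_site_pairs": [0] * len(sites),
        "n_bg_pairs": 0,
        "n_dup": 0, "n_lowmapq": 0, "n_orphan": 0,
        "n_pairs_emitted": 0,
    }

    if condition != "no_cas9":
        for idx, site in enumerate(sites):
            n = int(rng_sites.poisson(cfg.lambda0 * site.efficiency * mult))
            ledger["n_site_pairs"][idx] = n
            chrlen = lengths[site.chrom]
            for i in range(n):
                frag = _draw_site_fragment(site, cfg, chrlen, rng_sites)
                records.append(_fragment_to_pair(
                    f"site{idx}:{i}", site.chrom, frag, cfg, f"site:{idx}"))

    for i in range(cfg.bg_pairs):
        frag, chrom = _draw_background_fragment(genome, cfg, rng_bg)
        records.append(_fragment_to_pair(f"bg:{i}", chrom, frag, cfg, "bg"))
    ledger["n_bg_pairs"] = cfg.bg_pairs

    site_recs = [r for r in records if r.provenance != "bg"]
    bg_recs = [r for r in records if r.provenance == "bg"]
    out: list[ReadPairRecord] = []
    for recs, rng_noise in ((site_recs, rng_site_noise), (bg_recs, rng_bg_noise)):
        out.extend(_apply_noise(recs, cfg, rng_noise, ledger))

    ledger["n_pairs_emitted"] = len(out)
    return AlignmentSet(records=sort_records(out, genome), genome=genome,
                        label=condition, ledger=ledger)


def _draw_site_fragment(site: PlantedSite, cfg: SimConfig, chrlen: int,
                        rng: np.random.Generator) -> tuple[int, int]:
    """One fragment abutting the cut; resampled if it leaves the chromosome."""
    for _ in range(_RESAMPLE_CAP):
        left_side = rng.random() < 0.5
        offset = abs(rng.normal(0.0, cfg.end_sigma))
        length = int(rng.integers(cfg.frag_len_min, cfg.frag_len_max + 1))
        if left_side:
            end = site.cut_pos - int(round(offset))
            start = end - length
        else:
            start = site.cut_pos + int(round(offset))
            end = start + length
        if 0 <= start and end <= chrlen:
            return start, end
    raise RuntimeError(
        f"could not place fragment at {site.chrom}:{site.cut_pos} "
        f"within {_RESAMPLE_CAP} attempts"
    )


def _draw_background_fragment(genome: GenomeRef, cfg: SimConfig,
                              rng: np.random.Generator) -> tuple[tuple[int, int], str]:
    names = genome.names
    lens = np.array([genome.lengths[n] for n in names], dtype=float)
    p = lens / lens.sum()
    for _ in range(_RESAMPLE_CAP):
        ci = int(rng.choice(len(names), p=p))
        length = int(rng.integers(cfg.frag_len_min, cfg.frag_len_max + 1))
        start = int(rng.integers(0, int(lens[ci])))
        if start + length <= lens[ci]:
            return (start, start + length), names[ci]
    raise RuntimeError("could not place background fragment")


def _fragment_to_pair(qname: str, chrom: str, frag: tuple[int, int],
                      cfg: SimConfig, provenance: str) -> ReadPairRecord:
    start, end = frag
    return ReadPairRecord(
        qname=qname, chrom=chrom,
        start1=start, end1=start + cfg.read_len, strand1="+",
        start2=end - cfg.read_len, end2=end, strand2="-",
        mapq=_MAPQ_GOOD, provenance=provenance,
    )


def _apply_noise(records: list[ReadPairRecord], cfg: SimConfig,
                 rng: np.random.Generator, ledger: dict) -> list[ReadPairRecord]:
    from dataclasses import replace

    out: list[ReadPairRecord] = []
    for r in records:
        u = rng.random()
        if u < cfg.dup_rate:
            ledger["n_dup"] += 1
            out.append(r)
            out.append(replace(r, qname=r.qname + ":d", is_duplicate=True))
        elif u < cfg.dup_rate + cfg.lowmapq_rate:
            ledger["n_lowmapq"] += 1
            out.append(replace(r, mapq=_MAPQ_LOW))
        elif u < cfg.dup_rate + cfg.lowmapq_rate + cfg.orphan_rate:
            ledger["n_orphan"] += 1
            out.append(replace(r, start2=None, end2=None, strand2=None,
                               is_singleton=True))
        else:
            out.append(r)
    return out


# --- amplicon read simulation ------------------------------------------------

def simulate_amplicon_reads(
    spec: AmpliconSpec,
    indel_fraction: float,
    size_dist: dict[int, float],
    n_reads: int,
    read_len: int = 151,
    mean_q: float = 30.0,
    flank_corrupt_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str, list[int]]], list[dict]]:
    """Amplicon reads carrying a planted indel spectrum, with ground truth.

    Returns ``(reads, truth)`` where each read is a ``(name, seq, quals)``
    tuple and each truth entry records the planted size and whether a flank
    anchor was corrupted. Indels are placed at the nominal cut position
    (3 bp inside the 3' end of the target span, Cas9 geometry); insertions
    add random bases, deletions remove bases centred on the cut.
    """
    if not 0 <= indel_fraction <= 1:
        raise ValueError("indel_fraction must be in [0, 1]")
    sizes = list(size_dist)
    probs = np.array([size_dist[s] for s in sizes], dtype=float)
    if sizes and (any(s == 0 or not isinstance(s, (int, np.integer)) for s in sizes)
                  or not np.isclose(probs.sum(), 1.0)):
        raise ValueError("size_dist keys must be nonzero integers with probabilities summing to 1")
    cut = spec.target_end - 3
    left_inner = spec.ref_seq.find(spec.left_flank) + FLANK_LEN
    right_inner = spec.ref_seq.find(spec.right_flank)
    for s in sizes:
        if s < 0:
            half = -s // 2
            if cut - half < left_inner or cut - half - s > right_inner:
                raise ValueError(f"deletion of {-s} bp exceeds the inner segment")

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str, list[int]]] = []
    truth: list[dict] = []
    for i in range(n_reads):
        if sizes and rng.random() < indel_fraction:
            size = int(sizes[rng.choice(len(sizes), p=probs)])
        else:
            size = 0
        seq = _mutate_amplicon(spec.ref_seq, cut, size, rng)
        corrupted = rng.random() < flank_corrupt_rate
        if corrupted:
            seq = _corrupt_flank(seq, spec, rng)
        seq = seq[:read_len]
        quals = np.clip(np.rint(rng.normal(mean_q, 3.0, size=len(seq))), 2, 40)
        reads.append((f"amp:{i}", seq, [int(q) for q in quals]))
        truth.append({"name": f"amp:{i}", "size": size, "corrupted": corrupted})
    return reads, truth


def _mutate_amplicon(ref: str, cut: int, size: int, rng: np.random.Generator) -> str:
    if size == 0:
        return ref
    if size > 0:
        ins = "".join("ACGT"[rng.integers(0, 4)] for _ in range(size))
        return ref[:cut] + ins + ref[cut:]
    start = cut - (-size // 2)
    return ref[:start] + ref[start - size:]


def _corrupt_flank(seq: str, spec: AmpliconSpec, rng: np.random.Generator) -> str:
    flank = spec.left_flank if rng.random() < 0.5 else spec.right_flank
    i = seq.find(flank)
    if i < 0:  # flank already absent (e.g. shifted out); corrupt left anchor span
        i = max(0, min(len(seq) - 1, spec.ref_seq.find(spec.left_flank)))
        j = i
    else:
        j = i + int(rng.integers(0, FLANK_LEN))
    others = [b for b in "ACGT" if b != seq[j]]
    return seq[:j] + others[rng.integers(0, 3)] + seq[j + 1:]


# --- writers -----------------------------------------------------------------

def write_truth_bed(sites: Sequence[PlantedSite], path: str) -> None:
    """Ground-truth BED (0-based half-open): cut point plus site metadata."""
    with open(path, "w") as fh:
        for s in sites:
            name = f"{s.protospacer}|{s.pam}|mm{s.n_mismatch}|eff{s.efficiency:g}"
            fh.write(f"{s.chrom}\t{s.cut_pos}\t{s.cut_pos + 1}\t{name}\t"
                     f"{s.n_mismatch}\t{s.strand}\n")


def write_ledger_json(aln: AlignmentSet, path: str) -> None:
    if aln.ledger is None:
        raise ValueError("alignment set carries no provenance ledger")
    with open(path, "w") as fh:
        json.dump(aln.ledger, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_fastq(reads: Sequence[tuple[str, str, Sequence[int]]], path: str) -> None:
    """Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for name, seq, quals in reads:
            q = "".join(chr(33 + int(x)) for x in quals)
            fh.write(f"@{name}\n{seq}\n+\n{q}\n")


def sim_config_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
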