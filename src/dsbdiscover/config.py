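"""End-to-end run configuration and orchestration.

One YAML-serialisable :class:`RunConfig` plus one master seed drive the full
workflow: simulate the three conditions (inhibited, no-drug, no-Cas9),
filter and depth-match them, discover sites in both treated arms against
the no-Cas9 control, quantify paired enrichment, run the signed-rank
comparisons and write the report bundle. Every stochastic stage derives its
own seed deterministically from the master seed and the stage name, so a
full run is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from ._util import derive_seed
from .align_io import filter_alignments, subsample_equal_depth
from .genome import GenomeRef, make_genome
from .quantify import enrichment_table
from .report import compare_paired, overlap_sites, write_reports
from .simdata import PlantedSite, SimConfig, plant_sites, simulate_chip_reads
from .site_discovery import (
    DEFAULT_BIN_SIZE,
    DEFAULT_CONTROL_TOLERANCE,
    DEFAULT_CUTOFF,
    DEFAULT_END_TOLERANCE,
    DEFAULT_SCAN_WINDOW,
    DEFAULT_SEARCH_RADIUS,
    GuideSpec,
    SiteCall,
    discover_sites,
)

#: the TRAC-targeting guide used as the default toy gRNA
DEFAULT_GRNA = "AGAGTCTCTCAGCTGGTACA"


@dataclass
class GenomeParams:
    n_chroms: int = 1
    lengths: list[int] = field(default_factory=lambda: [30_000_000])


@dataclass
class SiteRequest:
    chrom: str
    position: int
    strand: str
    n_mismatch: int
    efficiency: float

    def as_tuple(self) -> tuple:
        return (self.chrom, self.position, self.strand, self.n_mismatch,
                self.efficiency)


@dataclass
class DiscoveryParams:
    cutoff_c: int = DEFAULT_CUTOFF
    min_mapq: int = 25
    bin_size: int = DEFAULT_BIN_SIZE
    window: int = DEFAULT_SCAN_WINDOW
    search_radius: int = DEFAULT_SEARCH_RADIUS
    end_tolerance: int = DEFAULT_END_TOLERANCE
    control_tolerance: int = DEFAULT_CONTROL_TOLERANCE
    rpm_window: int = 1500
    bg_offset: int = 10000


@dataclass
class GuideParams:
    name: str = "guide"
    protospacer: str = DEFAULT_GRNA
    nuclease: str = "cas9"
    pam_rule: Optional[str] = None
    max_mismatch: int = 6

    def to_spec(self) -> GuideSpec:
        return GuideSpec(name=self.name, protospacer=self.protospacer,
                         nuclease=self.nuclease, pam_rule=self.pam_rule,
                         max_mismatch=self.max_mismatch)


@dataclass
class RunConfig:
    master_seed: int = 0
    genome: GenomeParams = field(default_factory=GenomeParams)
    guide: GuideParams = field(default_factory=GuideParams)
    sites: list[SiteRequest] = field(default_factory=list)
    sim: SimConfig = field(default_factory=SimConfig)
    discovery: DiscoveryParams = field(default_factory=DiscoveryParams)
    out_dir: Optional[str] = None

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            master_seed=d.get("master_seed", 0),
            genome=GenomeParams(**d.get("genome", {})),
            guide=GuideParams(**d.get("guide", {})),
            sites=[SiteRequest(**s) for s in d.get("sites", [])],
            sim=SimConfig(**d.get("sim", {})),
            discovery=DiscoveryParams(**d.get("discovery", {})),
            out_dir=d.get("out_dir"),
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.master_seed, stage)


def default_site_requests(genome_length: int = 30_000_000,
                          mismatches: Optional[list[int]] = None,
                          efficiencies: Optional[list[float]] = None,
                          chrom: str = "chr1") -> list[SiteRequest]:
    """Desk-scale ground truth: one on-target plus ten off-targets.

    Off-target mismatch counts span 0-6 and efficiencies 0.05-0.5; sites are
    spread evenly across the chromosome with a wide margin so 10-kb
    background offsets stay on-chromosome.
    """
    if mismatches is None:
        mismatches = [0, 1, 2, 2, 3, 3, 4, 4, 5, 6]
    if efficiencies is None:
        step = 0.45 / (len(mismatches) - 1) if len(mismatches) > 1 else 0.0
        efficiencies = [round(0.5 - step * i, 3) for i in range(len(mismatches))]
    if len(mismatches) != len(efficiencies):
        raise ValueError("mismatches and efficiencies must align")
    n = len(mismatches) + 1
    margin = 20_000
    positions = [margin + i * (genome_length - 2 * margin) // n for i in range(n)]
    reqs = [SiteRequest(chrom, positions[0], "+", 0, 1.0)]  # on-target
    for i, (mm, eff) in enumerate(zip(mismatches, efficiencies)):
        strand = "+" if i % 2 == 0 else "-"
        reqs.append(SiteRequest(chrom, positions[i + 1], strand, mm, eff))
    return reqs


def default_run_config(master_seed: int = 0, out_dir: Optional[str] = None,
                       residence_multiplier: float = 5.0) -> RunConfig:
    gp = GenomeParams()
    return RunConfig(
        master_seed=master_seed,
        genome=gp,
        guide=GuideParams(),
        sites=default_site_requests(gp.lengths[0]),
        sim=SimConfig(residence_multiplier=residence_multiplier),
        discovery=DiscoveryParams(),
        out_dir=out_dir,
    )


# --- orchestration -----------------------------------------------------------

def run_end_to_end(cfg: RunConfig) -> dict:
    """Simulate, filter, depth-match, discover, quantify, compare, report.

    Returns a machine-readable summary; writes the report bundle when
    ``cfg.out_dir`` is set.
    """
    guide = cfg.guide.to_spec()
    genome = make_genome(cfg.genome.n_chroms, cfg.genome.lengths,
                         seed=cfg.stage_seed("genome"))
    genome, planted = plant_sites(
        genome, guide.protospacer, guide.pam_rule,
        [s.as_tuple() for s in cfg.sites],
        seed=cfg.stage_seed("plant"), nuclease=guide.nuclease,
    )

    sim = dataclasses.replace(cfg.sim, seed=cfg.stage_seed("sim"))
    raw = {cond: simulate_chip_reads(genome, planted, sim, cond)
           for cond in ("treated_inhibited", "treated_no_drug", "no_cas9")}
    filtered = {k: filter_alignments(v, cfg.discovery.min_mapq)
                for k, v in raw.items()}
    inh, nd, ctrl = subsample_equal_depth(
        [filtered["treated_inhibited"], filtered["treated_no_drug"],
         filtered["no_cas9"]],
        seed=cfg.stage_seed("subsample"),
    )

    disc = dict(cutoff_c=cfg.discovery.cutoff_c, bin_size=cfg.discovery.bin_size,
                window=cfg.discovery.window,
                search_radius=cfg.discovery.search_radius,
                end_tolerance=cfg.discovery.end_tolerance,
                control_tolerance=cfg.discovery.control_tolerance,
                rpm_window_size=cfg.discovery.rpm_window)
    sites_inh, removed_inh = discover_sites(inh, ctrl, genome, guide,
                                            return_removed=True, **disc)
    sites_nd, removed_nd = discover_sites(nd, ctrl, genome, guide,
                                          return_removed=True, **disc)

    enrich = enrichment_table(sites_inh, inh, nd,
                              window=cfg.discovery.rpm_window,
                              offset=cfg.discovery.bg_offset)
    comparisons = {}
    if len(enrich) >= 2:
        comparisons["site_rpm_inhibited_vs_no_drug"] = compare_paired(
            [e.rpm_inhibited for e in enrich],
            [e.rpm_no_drug for e in enrich], test="signed_rank")
        bg_pairs = [(e.rpm_bg_inhibited, e.rpm_bg_no_drug) for e in enrich
                    if e.rpm_bg_inhibited is not None and e.rpm_bg_no_drug is not None]
        if len(bg_pairs) >= 2:
            comparisons["background_rpm_inhibited_vs_no_drug"] = compare_paired(
                [b[0] for b in bg_pairs], [b[1] for b in bg_pairs],
                test="signed_rank")

    recovery = _recovery(sites_inh, planted, cfg.discovery.control_tolerance)
    overlap = overlap_sites(sites_inh, sites_nd)

    summary = {
        "n_sites_inhibited": len(sites_inh),
        "n_sites_no_drug": len(sites_nd),
        "n_removed_by_control": {"inhibited": len(removed_inh),
                                 "no_drug": len(removed_nd)},
        "planted_sites": len(planted),
        "recovered_planted": recovery["recovered"],
        "recovery_fraction": recovery["fraction"],
        "background_calls_inhibited": recovery["background_calls"],
        "overlap_inhibited_vs_no_drug": {
            "only_inhibited": overlap.only_a, "only_no_drug": overlap.only_b,
            "both": overlap.both},
        "p_values": {k: v.p_value for k, v in comparisons.items()},
        "depth_pairs": inh.n_pairs,
        "seeds": {s: cfg.stage_seed(s)
                  for s in ("genome", "plant", "sim", "subsample")},
    }

    if cfg.out_dir:
        write_reports(sites_inh, enrich, comparisons, cfg.out_dir,
                      removed_sites=removed_inh, config_echo=cfg.to_dict(),
                      seeds=summary["seeds"])
        with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary


def _recovery(calls: list[SiteCall], planted: list[PlantedSite],
              tolerance: int) -> dict:
    recovered = 0
    matched_calls = set()
    for p in planted:
        hit = None
        for i, c in enumerate(calls):
            if c.chrom == p.chrom and abs(c.cut_pos - p.cut_pos) <= tolerance:
                hit = i
                break
        if hit is not None:
            recovered += 1
            matched_calls.add(hit)
    background = sum(
        1 for i, c in enumerate(calls)
        if i not in matched_calls and not any(
            c.chrom == p.chrom and abs(c.cut_pos - p.cut_pos) <= tolerance
            for p in planted)
    )
    return {"recovered": recovered,
            "fraction": recovered / len(planted) if planted else float("nan"),
            "background_calls": background}
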