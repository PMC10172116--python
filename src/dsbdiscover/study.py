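"""Canned study-condition runs used by the test suite and acceptance script.

These functions fix the package's reference simulation conditions — the
desk-scale discovery run, the residence-multiplier sensitivity sweep, the
amplicon indel benchmark and the cut-site coverage profile — so that the
same computations back both the automated tests and reproducibility
reporting. All randomness derives from a single master seed.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from ._util import derive_seed
from .align_io import filter_alignments, subsample_equal_depth
from .config import default_run_config, default_site_requests, run_end_to_end
from .genome import make_genome
from .indel_call import locate_flanks, summarize_indels
from .quantify import coverage_track, enrichment_table
from .report import compare_paired
from .simdata import SimConfig, plant_sites, simulate_amplicon_reads, simulate_chip_reads
from .site_discovery import GuideSpec, discover_sites

_TRAC_GUIDE = "AGAGTCTCTCAGCTGGTACA"


def desk_scale_run(master_seed: int = 0) -> dict:
    """The default desk-scale end-to-end run (see :func:`default_run_config`)."""
    return run_end_to_end(default_run_config(master_seed=master_seed))


def multiplier_sweep(
    master_seed: int = 0,
    n_seeds: int = 10,
    mismatches: Optional[list[int]] = None,
    efficiencies: Optional[list[float]] = None,
    genome_length: int = 30_000_000,
    sim: Optional[SimConfig] = None,
) -> dict:
    """Repeat the inhibited vs no-drug comparison across simulation seeds.

    The genome and planted sites (weak off-targets by default, so the
    no-drug arm misses some) are fixed once; each seed re-simulates all
    three conditions, depth-matches, discovers sites in both treated arms
    against the no-Cas9 control and quantifies paired enrichment at the
    inhibited-arm sites. Returns per-seed site counts, pooled paired site
    RPMs, and the per-seed signed-rank p-value for the 10-kb background
    offsets (the inhibitor-neutrality check).
    """
    if mismatches is None:
        mismatches = [1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6]
    if efficiencies is None:
        efficiencies = [round(x, 4) for x in np.linspace(0.03, 0.25, len(mismatches))]
    guide = GuideSpec(name="sweep", protospacer=_TRAC_GUIDE)
    genome = make_genome(1, [genome_length], seed=derive_seed(master_seed, "sweep-genome"))
    reqs = default_site_requests(genome_length, mismatches=mismatches,
                                 efficiencies=efficiencies)
    genome, planted = plant_sites(
        genome, guide.protospacer, guide.pam_rule,
        [r.as_tuple() for r in reqs],
        seed=derive_seed(master_seed, "sweep-plant"),
    )
    base_sim = sim if sim is not None else SimConfig()

    counts_inh, counts_nd = [], []
    pooled_pairs: list[tuple[float, float]] = []
    bg_p_values: list[float] = []
    recovered_inh, background_calls = [], []
    for i in range(n_seeds):
        sim_i = dataclasses.replace(base_sim, seed=derive_seed(master_seed, f"sweep-sim-{i}"))
        raw = {c: simulate_chip_reads(genome, planted, sim_i, c)
               for c in ("treated_inhibited", "treated_no_drug", "no_cas9")}
        filt = {k: filter_alignments(v) for k, v in raw.items()}
        inh, nd, ctrl = subsample_equal_depth(
            [filt["treated_inhibited"], filt["treated_no_drug"], filt["no_cas9"]],
            seed=derive_seed(master_seed, f"sweep-sub-{i}"))
        sites_inh = discover_sites(inh, ctrl, genome, guide)
        sites_nd = discover_sites(nd, ctrl, genome, guide)
        counts_inh.append(len(sites_inh))
        counts_nd.append(len(sites_nd))
        recovered_inh.append(_n_recovered(sites_inh, planted))
        background_calls.append(len(sites_inh) - _n_recovered(sites_inh, planted))

        enrich = enrichment_table(sites_inh, inh, nd)
        pooled_pairs.extend((e.rpm_inhibited, e.rpm_no_drug) for e in enrich)
        bg = [(e.rpm_bg_inhibited, e.rpm_bg_no_drug) for e in enrich
              if e.rpm_bg_inhibited is not None and e.rpm_bg_no_drug is not None]
        if len(bg) >= 2:
            res = compare_paired([b[0] for b in bg], [b[1] for b in bg],
                                 test="signed_rank")
            bg_p_values.append(res.p_value)
        else:
            bg_p_values.append(1.0)

    pooled = compare_paired([p[0] for p in pooled_pairs],
                            [p[1] for p in pooled_pairs], test="signed_rank")
    return {
        "n_planted": len(planted),
        "counts_inhibited": counts_inh,
        "counts_no_drug": counts_nd,
        "recovered_inhibited": recovered_inh,
        "background_calls_inhibited": background_calls,
        "site_rpm_pairs": pooled_pairs,
        "site_rpm_signed_rank_p": pooled.p_value,
        "bg_p_values": bg_p_values,
    }


def _n_recovered(calls, planted, tolerance: int = 100) -> int:
    n = 0
    for p in planted:
        if any(c.chrom == p.chrom and abs(c.cut_pos - p.cut_pos) <= tolerance
               for c in calls):
            n += 1
    return n


def indel_benchmark(master_seed: int = 0, n_reads: int = 20_000,
                    indel_fraction: float = 0.3,
                    size_dist: Optional[dict[int, float]] = None,
                    flank_corrupt_rate: float = 0.0) -> dict:
    """Amplicon spectrum recovery: simulate, call, compare to ground truth."""
    if size_dist is None:
        size_dist = {1: 0.8, -3: 0.2}
    ref = make_genome(1, [200], seed=derive_seed(master_seed, "amplicon-ref")).seq("chr1")
    spec = locate_flanks(ref, 90, 110)
    reads, truth = simulate_amplicon_reads(
        spec, indel_fraction=indel_fraction, size_dist=size_dist,
        n_reads=n_reads, flank_corrupt_rate=flank_corrupt_rate,
        seed=derive_seed(master_seed, "amplicon-reads"))
    summary = summarize_indels(reads, spec)
    return {
        "spec": spec,
        "summary": summary,
        "truth": truth,
        "n_corrupted_truth": sum(t["corrupted"] for t in truth),
        "true_fraction_planted": sum(
            1 for t in truth if t["size"] != 0 and not t["corrupted"]
        ) / max(1, sum(1 for t in truth if not t["corrupted"])),
    }


def two_peak_profile(master_seed: int = 0, n_pairs_mean: int = 2000,
                     flank: int = 600) -> dict:
    """Coverage shape around one strong cut: dip at the cut, flanking peaks."""
    genome = make_genome(1, [200_000], seed=derive_seed(master_seed, "peak-genome"))
    genome, planted = plant_sites(
        genome, _TRAC_GUIDE, None, [("chr1", 100_000, "+", 0, 1.0)],
        seed=derive_seed(master_seed, "peak-plant"))
    sim = SimConfig(lambda0=float(n_pairs_mean), residence_multiplier=1.0,
                    bg_pairs=0, dup_rate=0.0, lowmapq_rate=0.0, orphan_rate=0.0,
                    seed=derive_seed(master_seed, "peak-sim"))
    aln = simulate_chip_reads(genome, planted, sim, "treated_no_drug")
    cut = planted[0].cut_pos
    track = coverage_track(aln, "chr1", cut - flank, cut + flank)
    cov = np.zeros(2 * flank, dtype=int)
    for _, s, e, v in track:
        cov[s - (cut - flank):e - (cut - flank)] = v
    left, right = cov[:flank], cov[flank:]
    return {
        "cut_pos": cut,
        "n_pairs": aln.n_pairs,
        "cov_at_cut": int(cov[flank]),
        "left_max": int(left.max()),
        "right_max": int(right.max()),
        "coverage": cov,
    }
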