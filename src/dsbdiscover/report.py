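"""Comparison statistics, site-set overlap bookkeeping and table export.

Paired samples are compared with the Wilcoxon signed-rank test (or paired
t-test), independent samples with the Wilcoxon rank-sum / Mann-Whitney test
(or Welch t-test); all tests are two-sided. The signed-rank test drops zero
differences (their count is reported) and uses the exact null distribution
for up to 25 non-zero pairs — computed in-package over doubled midranks so
ties are handled exactly — switching to the normal approximation with
continuity correction above that. The rank-sum test is exact for
min(n, m) <= 10 without ties, otherwise normally approximated with tie
correction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .site_discovery import SiteCall

EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_MIN_N = 10
DEFAULT_OVERLAP_TOLERANCE = 100

PAIRED_TESTS = ("signed_rank", "t_paired")
UNPAIRED_TESTS = ("rank_sum", "t_unpaired")


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    n: tuple[int, ...]
    statistic: float
    p_value: float
    sidedness: str = "two_sided"
    exact: bool = False
    degenerate: bool = False
    n_zero_dropped: int = 0


def _signed_rank_exact(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p over all 2^n sign assignments.

    Midrank ties are handled by doubling the ranks to integers and
    convolving the distribution of W+ (sum of positive-difference ranks).
    Returns ``(W+, p)`` with p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).
    """
    ranks = stats.rankdata(np.abs(d))
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = dist + shifted
    dist /= 2.0 ** len(r2)
    w_plus = float(ranks[d > 0].sum())
    w2 = int(np.rint(2 * w_plus))
    p_low = dist[:w2 + 1].sum()
    p_high = dist[w2:].sum()
    return w_plus, float(min(1.0, 2.0 * min(p_low, p_high)))


def compare_paired(x: Sequence[float], y: Sequence[float],
                   test: str = "signed_rank") -> ComparisonResult:
    if test not in PAIRED_TESTS:
        raise ValueError(f"test must be one of {PAIRED_TESTS}")
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    d = x - y
    if test == "t_paired":
        if np.allclose(d, d[0]) and np.isclose(d[0], 0):
            return ComparisonResult(test, (len(x),), 0.0, 1.0, degenerate=True)
        t, p = stats.ttest_rel(x, y)
        return ComparisonResult(test, (len(x),), float(t), float(p))
    nz = d[d != 0]
    n_zero = int(len(d) - len(nz))
    if len(nz) == 0:
        return ComparisonResult(test, (len(x),), 0.0, 1.0, degenerate=True,
                                n_zero_dropped=n_zero)
    if len(nz) <= EXACT_SIGNED_RANK_MAX_N:
        w_plus, p = _signed_rank_exact(nz)
        return ComparisonResult(test, (len(x),), w_plus, p, exact=True,
                                n_zero_dropped=n_zero)
    res = stats.wilcoxon(nz, zero_method="wilcox", correction=True,
                         method="approx")
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    return ComparisonResult(test, (len(x),), w_plus, float(res.pvalue),
                            n_zero_dropped=n_zero)


def compare_unpaired(x: Sequence[float], y: Sequence[float],
                     test: str = "rank_sum") -> ComparisonResult:
    if test not in UNPAIRED_TESTS:
        raise ValueError(f"test must be one of {UNPAIRED_TESTS}")
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    n = (len(x), len(y))
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return ComparisonResult(test, n, 0.0, 1.0, degenerate=True)
    if test == "t_unpaired":
        t, p = stats.ttest_ind(x, y, equal_var=False)  # Welch df
        return ComparisonResult(test, n, float(t), float(p))
    has_ties = len(np.unique(combined)) < len(combined)
    exact = min(n) <= EXACT_RANK_SUM_MAX_MIN_N and not has_ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return ComparisonResult(test, n, float(res.statistic), float(res.pvalue),
                            exact=exact)


# --- site-set overlap --------------------------------------------------------

@dataclass(frozen=True)
class OverlapResult:
    only_a: int
    only_b: int
    both: int
    matched_pairs: tuple[tuple[int, int], ...]  # (index in a, index in b)


def overlap_sites(a: Sequence[SiteCall], b: Sequence[SiteCall],
                  tolerance: int = DEFAULT_OVERLAP_TOLERANCE) -> OverlapResult:
    """Greedy distance-sorted matching of two site lists, each site once.

    Candidate pairs on the same chromosome within ``tolerance`` bp are
    accepted in order of increasing distance (ties by indices), which makes
    the 'both' count symmetric in A and B.
    """
    cands = []
    for i, sa in enumerate(a):
        for j, sb in enumerate(b):
            if sa.chrom == sb.chrom and abs(sa.cut_pos - sb.cut_pos) <= tolerance:
                cands.append((abs(sa.cut_pos - sb.cut_pos), i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return OverlapResult(only_a=len(a) - len(pairs), only_b=len(b) - len(pairs),
                         both=len(pairs), matched_pairs=tuple(sorted(pairs)))


# --- table export ------------------------------------------------------------

SITE_COLUMNS = ["chrom", "cut_1based", "strand", "sequence", "pam",
                "mismatches", "support", "rpm", "on_target"]


def sites_to_frame(sites: Sequence[SiteCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": s.chrom, "cut_1based": s.cut_pos + 1, "strand": s.strand,
          "sequence": s.matched_seq, "pam": s.pam_seq,
          "mismatches": s.n_mismatch, "support": s.support,
          "rpm": s.rpm, "on_target": s.is_on_target} for s in sites],
        columns=SITE_COLUMNS,
    )


def write_site_table(sites: Sequence[SiteCall], path: str) -> None:
    df = sites_to_frame(sites)
    df["rpm"] = [repr(float(v)) for v in df["rpm"]]  # full-precision round trip
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path: str) -> list[SiteCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        SiteCall(chrom=row.chrom, cut_pos=int(row.cut_1based) - 1,
                 strand=row.strand, matched_seq=row.sequence, pam_seq=row.pam,
                 n_mismatch=int(row.mismatches), support=int(row.support),
                 rpm=float(row.rpm), is_on_target=bool(row.on_target))
        for row in df.itertuples()
    ]


def write_site_bed(sites: Sequence[SiteCall], path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.cut_pos}\t{s.cut_pos + 1}\t"
                     f"{s.matched_seq}|{s.pam_seq}|mm{s.n_mismatch}\t"
                     f"{s.support}\t{s.strand}\n")


def write_reports(sites: Sequence[SiteCall], enrichment, comparisons: dict,
                  out_dir: str, removed_sites: Sequence[SiteCall] = (),
                  config_echo: Optional[dict] = None,
                  seeds: Optional[dict] = None) -> dict[str, str]:
    """Write the standard output bundle; returns written paths by name.

    Outputs carry no timestamps, so two runs with identical configuration
    and seed produce byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    paths["sites_tsv"] = p = os.path.join(out_dir, "sites.tsv")
    write_site_table(sites, p)
    paths["sites_bed"] = p = os.path.join(out_dir, "sites.bed")
    write_site_bed(sites, p)
    if removed_sites:
        paths["removed_tsv"] = p = os.path.join(out_dir, "sites_removed_by_control.tsv")
        write_site_table(removed_sites, p)

    paths["enrichment_tsv"] = p = os.path.join(out_dir, "enrichment.tsv")
    pd.DataFrame(
        [{"chrom": e.chrom, "cut_1based": e.cut_pos + 1,
          "rpm_no_drug": e.rpm_no_drug, "rpm_inhibited": e.rpm_inhibited,
          "rpm_bg_no_drug": e.rpm_bg_no_drug,
          "rpm_bg_inhibited": e.rpm_bg_inhibited} for e in enrichment]
    ).to_csv(p, sep="\t", index=False)

    paths["comparisons_json"] = p = os.path.join(out_dir, "comparisons.json")
    with open(p, "w") as fh:
        json.dump({k: _comparison_dict(v) for k, v in comparisons.items()},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")

    paths["run_log"] = p = os.path.join(out_dir, "run_log.txt")
    with open(p, "w") as fh:
        fh.write("dsbdiscover run log\n")
        if config_echo is not None:
            fh.write("config:\n")
            fh.write(json.dumps(config_echo, indent=2, sort_keys=True, default=str) + "\n")
        if seeds is not None:
            fh.write("stage seeds:\n")
            fh.write(json.dumps(seeds, indent=2, sort_keys=True) + "\n")
    return paths


def _comparison_dict(c: ComparisonResult) -> dict:
    return {"test": c.test, "n": list(c.n), "statistic": c.statistic,
            "p_value": c.p_value, "sidedness": c.sidedness, "exact": c.exact,
            "degenerate": c.degenerate, "n_zero_dropped": c.n_zero_dropped}
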