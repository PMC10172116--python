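import numpy as np
import pytest

from dsbdiscover.genome import make_genome
from dsbdiscover.simdata import PlantedSite, SimConfig, plant_sites, simulate_chip_reads
from dsbdiscover.site_discovery import GuideSpec

TRAC_GUIDE = "AGAGTCTCTCAGCTGGTACA"


@pytest.fixture(scope="session")
def guide():
    return GuideSpec(name="trac", protospacer=TRAC_GUIDE)


@pytest.fixture(scope="session")
def small_genome():
    return make_genome(1, [200_000], seed=11)


@pytest.fixture(scope="session")
def planted_env(small_genome, guide):
    """Small genome with one strong site and two weak off-targets planted."""
    genome, sites = plant_sites(
        small_genome, guide.protospacer, guide.pam_rule,
        [("chr1", 50_000, "+", 0, 1.0),
         ("chr1", 120_000, "-", 2, 0.4),
         ("chr1", 170_000, "+", 4, 0.2)],
        seed=5,
    )
    return genome, sites


@pytest.fixture(scope="session")
def sim_env(planted_env):
    """Filtered treated/control alignment sets over the small genome."""
    from dsbdiscover.align_io import filter_alignments

    genome, sites = planted_env
    cfg = SimConfig(bg_pairs=400, seed=23)
    treated = filter_alignments(
        simulate_chip_reads(genome, sites, cfg, "treated_inhibited"))
    control = filter_alignments(
        simulate_chip_reads(genome, sites, cfg, "no_cas9"))
    return genome, sites, treated, control


def random_pairs(rng: np.random.Generator, n: int, chrom: str = "chr1",
                 chrom_len: int = 200_000, read_len: int = 36):
    """Random proper-pair records for oracle comparisons."""
    from dsbdiscover.align_io import ReadPairRecord

    recs = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - 500))
        frag = int(rng.integers(2 * read_len, 450))
        recs.append(ReadPairRecord(
            qname=f"r{i}", chrom=chrom,
            start1=start, end1=start + read_len, strand1="+",
            start2=start + frag - read_len, end2=start + frag, strand2="-",
        ))
    return recs
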