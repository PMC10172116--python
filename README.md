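# dsbdiscover

Genome-wide discovery of CRISPR–Cas off-target cleavage from paired-end
ChIP–seq-style alignments of a DNA-repair factor (MRE11), for researchers who
need to map nuclease activity in systems where purified-DNA or reporter-based
assays do not apply. MRE11 is recruited to double-strand breaks; inhibiting
DNA-PKcs (blocking NHEJ) prolongs its residence, boosting the ChIP signal at
every cut site. This package implements the computational half of that
workflow: read filtering and depth matching, pileup-based cleavage-site
detection with protospacer/PAM matching, no-nuclease control subtraction,
reads-per-million (RPM) enrichment, amplicon indel validation, and the
rank-based comparison statistics — plus a fully ground-truthed simulator so
that every stage is testable without any external sequencing data.

## The method in brief

For a guide g (a 20-nt protospacer) and a filtered alignment set, a cleavage
site is called where

1. at least *c* fragment midpoints fall in a sliding 500-bp window
   (default cutoff *c* = 2), and
2. at least *c* fragment **ends** stack within ±75 bp of a common position —
   the physical break signature, since fragments protected by repair factors
   end at the cut instead of spanning it, and
3. a protospacer placement with a valid PAM (NGG for Cas9, TTTV for Cas12a)
   and Hamming distance ≤ 6 to g lies within ±75 bp of that position.

Sites found in a matched no-nuclease control are subtracted as presumed false
positives. Enrichment at each site is

    RPM = (reads starting within the 1.5-kb window centred on the cut) × 10⁶ / total reads,

computed after every compared library is subsampled to equal read pairs.
Background is the same statistic 10 kb downstream. Paired conditions are
compared with the two-sided Wilcoxon signed-rank test (exact null up to
n = 25, midrank ties handled exactly), independent ones with the rank-sum
test. Amplicon indels are called by locating exact, unique matches to two
20-bp flanks positioned 20 bp outside the target span; after a mean-quality
filter (> 20), the indel size is the length difference between the observed
and reference flank-to-flank segment.

## Worked example

```python
from dsbdiscover import default_run_config, run_end_to_end

summary = run_end_to_end(default_run_config(master_seed=1))
print(summary["n_sites_inhibited"], summary["n_sites_no_drug"])
print(summary["recovery_fraction"], summary["background_calls_inhibited"])
print(summary["p_values"])
```

prints

```
11 10
1.0 0
{'site_rpm_inhibited_vs_no_drug': 0.0009765625,
 'background_rpm_inhibited_vs_no_drug': 1.0}
```

The default configuration simulates a 30-Mb toy genome carrying one on-target
and ten off-target protospacers (0–6 mismatches, efficiencies 0.05–0.5) and
three MRE11 ChIP libraries: DNA-PKcs-inhibited (5× residence), no-drug, and
no-Cas9. After filtering and depth matching, discovery against the no-Cas9
control recovers all 11 planted sites in the inhibited arm (`recovery_fraction
= 1.0`) with zero background calls, while the no-drug arm misses the weakest
off-target. Site RPM is significantly higher with inhibition (signed-rank
p ≈ 1e-3 over 11 sites), whereas RPM at the +10-kb background positions shows
no difference (p = 1.0) — the inhibitor adds signal at cuts, not damage
elsewhere.

The same workflow is available from a shell:

```sh
dsbdiscover run --seed 1 --out results/demo
dsbdiscover simulate --config cfg.yaml --condition treated_inhibited --out sim
dsbdiscover discover --sam sim.sam --genome sim.fasta \
    --guide AGAGTCTCTCAGCTGGTACA -c 2 --out sites.tsv
```

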