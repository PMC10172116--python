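# Methods

## The signal model

A CRISPR nuclease cut recruits the repair factor MRE11, which protects the
DNA around the break during chromatin immunoprecipitation. Sonicated,
immunoprecipitated fragments therefore *abut* the cut rather than span it:
each site-derived fragment lies entirely on one side, its cut-proximal end
close to the break, extending away from it. Because paired-end sequencing
reads only the two fragment ends, pooled base-pair coverage around a cut
shows two flanking peaks with a dip at the cut itself — the signature the
detector exploits.

The simulator realises this directly. For each planted site the number of
bound fragment pairs is Poisson with mean

    lambda0 × efficiency × residence_multiplier,

where `efficiency ∈ (0,1]` is the site's relative recruitment propensity and
`residence_multiplier ≥ 1` models prolonged MRE11 residence under DNA-PKcs
inhibition (applied only in the inhibited condition; a value of 1 reproduces
the no-drug arm bit for bit under the same seed). A fragment picks a side of
the cut (equiprobable), its cut-proximal end is offset from the cut by a
half-normal with scale `end_sigma`, and its length is uniform on
`[frag_len_min, frag_len_max]`, extending away from the cut. Background
fragments are uniform genome-wide. Library artefacts are modelled per pair by
one categorical draw — PCR duplicate, low mapping quality, or orphaned mate —
so the three categories are mutually exclusive and the provenance ledger
accounts for every downstream removal exactly.

Background fragments, site fragments and their artefact draws use separate
RNG substreams keyed on the seed. Consequently the background reads of the
inhibited, no-drug and no-Cas9 conditions are identical under one seed: the
simulated inhibitor adds residence at cuts and nothing anywhere else, which
is the property the 10-kb-offset background comparison is designed to verify.

## Parameter defaults and why

| parameter | default | units | rationale |
|---|---|---|---|
| `lambda0` | 50 | fragment pairs | strong on-target pileup at desk scale without drowning the library in signal |
| `residence_multiplier` | 5 | fold | the enrichment regime where the no-drug arm starts missing weak sites |
| `frag_len_min/max` | 150/400 | bp | typical sonication range; must fit two 36-bp reads |
| `end_sigma` | 25 | bp | places the two coverage peaks tightly around the cut; reproduces the dip-at-cut shape at 2×36-bp reads |
| `read_len` | 36 | bp | short-read ChIP chemistry (2×36 bp) |
| `bg_pairs` | 3,000 | pairs | see "Desk scale" below |
| `dup_rate/lowmapq_rate/orphan_rate` | 0.05/0.05/0.02 | — | realistic minor artefact fractions; exercised by the filter report |
| genome | 1 × 30 Mb | bp | see "Desk scale" below |
| `min_mapq` | 25 | — | retention threshold; boundary is ≥ 25 |
| scan window / bin | 500 / 50 | bp | midpoint pre-scan granularity |
| cutoff `c` | 2 | fragments | minimum fragment support for a candidate and for the refined cut |
| `end_tolerance` | 75 | bp | ≈ 3 × `end_sigma`: a stacked-fragment-end stab width |
| `search_radius` | 75 | bp | protospacer search around the refined cut; covers summit jitter |
| RPM window | 1,500 | bp | enrichment window centred on the cut |
| background offset | 10,000 | bp | downstream background position (upstream fallback, flagged) |
| control tolerance | 100 | bp | cut-to-cut distance for control subtraction and site overlap |

### Desk scale

The default study conditions (30-Mb genome, 3,000 background pairs, 11
planted sites) were calibrated once, analytically, before freezing: with a
window-based pre-scan at cutoff 2, the expected number of spurious background
candidate clusters grows as bg_pairs²/genome_length, and each cluster near a
planted protospacer sequence would let the no-Cas9 control "discover" the
planted site and wrongly subtract it. The chosen scale keeps (i) the expected
number of such collisions per run ≈ 0.01, (ii) the weakest off-target
(efficiency 0.05, multiplier 5) at ≈ 9 expected pairs after depth matching,
comfortably above cutoff 2, and (iii) the full pipeline under ~10 s on one
CPU. Background read density (~10⁻⁴ pairs/bp) corresponds to a low-depth
genome-scale ChIP library.

## The detector

Discovery proceeds in stages, each with a brute-force oracle in the test
suite:

1. **Midpoint pre-scan.** Fragment midpoints are binned (50 bp); a 500-bp
   sliding window (stride one bin) qualifies where it holds ≥ c midpoints;
   overlapping qualifying windows merge, summarised by the weighted-median
   midpoint (lower median on bin centres) and total midpoint count.
2. **Cut refinement.** Within each merged region (±300 bp), the maximum
   number of fragment ends within ±`end_tolerance` of a common position is
   found by an interval sweep. Candidates below c are dropped; the summit
   moves to the centre of the first maximal stab run. This stage embodies the
   fragments-end-at-the-cut physics: random background midpoint clusters
   rarely have coincident fragment ends, and the refined summit sits within a
   few bases of a true cut regardless of how midpoints are distributed
   (midpoint medians can sit half a fragment length away when fragment sides
   are imbalanced, which is why matching around the raw midpoint summit is
   unreliable at low support).
3. **Protospacer matching.** Both strands are scanned for placements whose
   modelled cut lies within ±`search_radius` of the summit and whose PAM
   satisfies the guide's rule; the placement minimising the Hamming mismatch
   count wins (ties: distance to summit, then + strand, then leftmost).
   Placements above `max_mismatch` (default 6) yield no call. Matching is
   Hamming-only — no DNA/RNA bulges — matching how off-target sites are
   conventionally annotated by mismatch count.
4. **Dedup, RPM, subtraction.** Calls sharing a cut coordinate keep the
   maximal support; RPM is annotated from the treated library; treated calls
   within 100 bp of a no-Cas9 control call are removed as presumed false
   positives, and reported separately.

Cut geometry: Cas9 cuts are modelled as a single blunt coordinate 3 bp 5' of
the PAM (between protospacer positions 17 and 18); Cas12a as a single
coordinate 18 bp from the PAM-proximal protospacer end (the staggered
overhang is not modelled). The simulator, the planted ground truth and the
matcher share one implementation of this geometry.

## Quantification conventions

"Reads within a window" means mate alignment-start containment in the
half-open interval `[pos − w/2, pos + w/2)`, each mate counted separately;
windows clip silently at chromosome edges. The RPM denominator is the total
retained reads of the library (two per pair). "Downstream" for the background
offset means increasing reference coordinate, with an upstream fallback
(flagged) when the downstream position leaves the chromosome. Depth matching
subsets whole pairs, uniformly without replacement, to the minimum pair count
across compared samples; the per-sample RNG is keyed on (seed, pair count) so
samples with identical content receive identical subsets, making the
multiplier-1 determinism property exact. Duplicate removal uses the
library-standard positional signature (both mate starts plus strands,
first-seen kept), applied before depth matching.

## Indel calling

The amplicon caller is deliberately alignment-free: a read is accepted only
if both 20-bp flank anchors (located 20 bp outside the target span) occur
exactly once, in order; reads failing that — or matching in both the forward
and reverse-complement orientation, which is ambiguous — are excluded as
`no_flank`. The mean-quality filter is strict (mean ≤ 20 excluded, averaged
over the whole read). The indel size is the observed minus reference
flank-to-flank length, so substitutions between the flanks never change a
call and the histogram conserves reads exactly
(`n_input = excluded + Σ histogram`).

## Statistics

Paired comparisons use the two-sided Wilcoxon signed-rank test with the
drop-zeros convention (count reported). The exact null is used for up to 25
non-zero pairs, computed by convolving doubled midranks so ties are exact;
above that, the normal approximation with continuity and tie correction
(scipy). Rank-sum comparisons are exact for min(n, m) ≤ 10 without ties,
otherwise normally approximated with tie correction; t-tests use Welch
degrees of freedom when unpaired. Degenerate inputs (all differences zero, or
a constant combined sample) return a flagged result with p = 1 rather than an
error. Two calibration facts the tests rely on, computed from the exact null
distributions: the attainable size of the exact signed-rank test at n = 15
and nominal 0.05 is 0.047913, and of the continuity-corrected rank-sum
approximation at n = m = 30 is 0.047890 — empirical type-I rates are checked
against these, not against the unattainable nominal level. Exact rank-test
p-values are discrete and therefore super-uniform under the null; uniformity
(KS) is asserted for the continuous t-test p-values, and super-uniformity
(P(p ≤ α) ≤ α within binomial slack) for the rank tests.

Site-set overlap uses distance-sorted greedy matching (each site matched at
most once, ties by index), which makes the "both" count symmetric; at the
default 100-bp tolerance and realistic inter-site distances it coincides with
optimal matching.

## What the simulator does and does not emulate

Emulated: flanking-peak/dip coverage at cuts, Poisson site occupancy with a
residence multiplier, uniform background pulldown, PCR duplicates, low-MAPQ
and orphaned reads, equal-depth comparison, shared background between
conditions, and amplicon reads with +1/−3-dominated indel spectra and
quality strings. Not emulated: sequencing errors beyond quality values,
chromatin accessibility or GC bias, chimeric/translocated fragments,
alignment itself (records are emitted pre-aligned; mapping is upstream), and
mutagenesis at ChIP sites (DNA damage detection is deliberately separated
from indel formation). Passing tests therefore demonstrate the pipeline's
correctness against its own generative model and its statistical
calibration — not performance on real chromatin, where non-uniform
background, mappability and bias structure would make control subtraction
and the cutoff choice harder than they are here.

## Problem sizes used by the tests and acceptance script

Unit tests run on 5 kb–200 kb genomes with hundreds of pairs. The end-to-end
reference studies use the 30-Mb desk scale: one discovery run ≈ 10 s; the
sensitivity sweep repeats it over 10 simulation seeds with 12 weak
off-targets (efficiencies 0.03–0.25, where the no-drug arm starts missing
sites); the indel benchmark classifies 20,000 reads; statistical calibration
uses 10⁴ null simulations. The full suite runs in about a minute on one CPU.

## Known limitations

* The candidate pre-scan merges qualifying windows, so two cuts closer than
  ~500 bp can merge into one candidate; the refinement stage then reports the
  stronger cut only.
* Hamming-only matching cannot represent bulged off-targets.
* With sparse backgrounds the 10-kb background RPM is frequently zero, so the
  background-neutrality signed-rank test is often degenerate (p = 1); this is
  the expected behaviour of a null comparison at low depth, not evidence
  about power.
* Control subtraction removes any treated site within tolerance of a control
  site, including (rarely, by construction ≈1% of desk-scale runs) a genuine
  planted site that a background cluster in the control happens to shadow.
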