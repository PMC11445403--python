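# Methods

This note documents the models, estimators, parameter choices and
numerical conventions behind each stage, what the synthetic generator
does and does not emulate, and the known limitations.

## Coordinates and containers

All positions are 1-based (VCF convention); intervals are half-open
`[start, end)` except GFF3 gene intervals, which stay 1-based inclusive
as in the format. Output TSVs carry a header comment stating this.
Genotypes live in a `(sites × samples × 2)` int8 array with −1 for a
missing allele; sample *i* owns haplotype columns 2*i* and 2*i*+1.
Multiallelic records are rejected at parse time — the pipeline's scope is
biallelic SNPs, and splitting is an upstream (bcftools) concern.

## Bioassay

Replicates are pooled on raw counts: observed mortality = 100·Σdead/Σexposed.
Abbott's correction 100·(T−C)/(100−C) is applied when control mortality
C ∈ [5%, 20%]; above 20% the test is invalid; below 5% the observed
mortality is used directly. The correction is evaluated on mortalities
rounded to 2 decimals — the precision at which tube-test percentages are
recorded on WHO report forms — so recomputed corrected values agree
exactly with values derived from reported percentages. `abbott_correct`
itself is exact and clamps at 0 when T < C (sampling noise can produce
this in small controls). Classification: discriminating dose < 90%
confirmed resistance, [90%, 98%) suspected, ≥ 98% susceptible (the
97–98% gap is treated as suspected); 5× intensity dose ≥ 98% low
intensity, otherwise moderate-to-high. Knock-down counts are treated as
dead at 24 h; alive + knocked down = exposed.

## Variant QC

Site rules use strict inequalities (QD > 5.0 etc.), so a value exactly at
a threshold fails; an absent INFO annotation passes its rule by default,
matching the GATK convention that rank-sum annotations are undefined
without both alleles in reads (`strict_missing_info=True` flips this).
Genotypes are masked to missing unless DP > 5 and GQ > 20; sites with
> 20% missing genotypes are dropped. Site filtering and genotype masking
commute (asserted by test); missingness must run after masking —
`apply_filters` enforces the order. Sample coverage fractions (share of
genome at > 10×) are consumed from a table, not computed from BAMs:
alignment metrics belong upstream. The retention rule is inclusive
(≥ 40%).

## Candidate screen

Frequencies are alternate-allele counts over non-missing called alleles
per phenotype group; denominators therefore vary by SNP when genotypes
are masked. The > 5% "common" flag uses the pooled sample population and
a strict comparison. Odds ratios use allele counts (each diploid
contributes two), resistant vs susceptible only — controls are unexposed
animals with unknown phenotype and are excluded. With any zero cell the
Haldane–Anscombe +0.5 is added to all four cells and flagged; the CI is
Woolf's exp(ln OR ± 1.96·√Σ1/cell). Allele-count ORs ignore within-host
dependence of the two alleles; with n ≤ 33 mosquitoes the CIs are wide
regardless, and the package reports the 2×2 table so carrier-based
re-analysis is trivial.

## Rogers–Huff LD

r is the product-moment correlation of diploid dosages with population
(biased) variance denominators — the standard composite-LD estimator,
needing no phasing. Missing dosages are removed pairwise-complete (the
denominator n is reported per pair). Zero variance ⇒ r undefined, kept as
NaN and never coerced to 0; with panels this small, monomorphic-in-subset
sites are common and a silent 0 would read as evidence of no LD.

## Windowed Hudson FST

Per site, with alt frequencies p₁, p₂ and called-allele counts n₁, n₂:

    N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
    D = p₁(1−p₂) + p₂(1−p₁)

and the window statistic is ΣN/ΣD over the window's usable sites
(ratio-of-sums; equal to the per-site estimator for single-site windows).
Sites with < 2 called alleles in either group are excluded. Negative
window values are retained — the estimator is unbiased near zero and
truncation would bias the permutation null. Window size is 1000 bp,
tiling each chromosome from position 1; empty windows are omitted.

Permutation test: phenotype labels are permuted over the resistant +
susceptible samples once per iteration, genome-wide, preserving group
sizes (200 iterations). Criterion (a): observed > the window's own 99th
permuted centile. Criterion (b): observed > 3 × a noise floor, by default
the 99th centile of all permuted window values pooled genome-wide —
permuting genome-wide (not per window) is what makes a single pooled
floor coherent. "Three times the minimum distribution" in the field
literature is ambiguous; both the pooled floor and a per-window variant
(`per_window_floor=True`) are implemented, the pooled reading being the
default because it acts as one genome-wide noise scale. Under the null,
criterion (a) alone passes ≈ 1% of windows (the acceptance script
measures 0.8–1.8% over seeds at 500 windows, inside the 3-binomial-SE
band); criterion (b) suppresses windows whose permuted distribution is
itself inflated by local haplotype structure.

## Garud H12 scan

Within a window the haplotype classes are the distinct 0/1 strings; with
sorted class frequencies p₁ ≥ p₂ ≥ …, H1 = Σpᵢ², H12 = (p₁+p₂)² +
Σ_{i≥3}pᵢ², H123 analogously, H2/H1 = (H1−p₁²)/H1. Windows are 1000
consecutive SNPs per chromosome; a terminal window short of 1000 SNPs is
dropped rather than padded (a shorter window has systematically fewer
distinguishable classes, which would bias its H12 upward). Haplotypes
with any missing allele in a window are dropped before evaluation.

Groups of unequal size are not directly comparable on H12 (more
haplotypes ⇒ more classes ⇒ lower homozygosity), so the scan reports, per
window and group, the mean of 200 H12 evaluations on subsamples of 20
haplotypes drawn without replacement — 20 being the susceptible group's
haplotype count in the default 23/10 panel, so the smaller group is
effectively evaluated directly and the larger one averaged over
subsamples. Sweep windows are those with mean H12 > 0.2; maximal runs of
flagged windows form sweep regions reported against their bp spans.
Calibration intuition: 20 unique haplotypes give H12 = (2/20)² +
18/20² = 0.055, while a core haplotype at frequency f contributes ≥ f²
(≈ 0.64 at f = 0.8), so 0.2 cleanly separates the two regimes.

## Haplotype clustering

Single-linkage agglomeration on normalized Hamming distance
(`scipy.cluster.hierarchy`), dendrogram cut at `max_distance` (default
0.001 — haplotypes differing at ≤ 0.1% of sites are "highly similar";
inside a 1 kb window with few SNPs this reduces to exact identity).
Clusters of ≥ 20 members are reported with per-phenotype counts.
Association uses Fisher's exact test on membership × phenotype
(resistant/susceptible haplotypes only), two-sided, with
Benjamini–Hochberg adjustment across the clusters tested; degenerate
margins are reported undefined rather than p = 1.

## CNV soft-clip screen

Per breakpoint: denominator = mapped reads with MAPQ ≥ 10 whose aligned
span covers the breakpoint (within `tolerance_bp`, default 0); numerator
= those whose soft-clip boundary on the expected side equals the
breakpoint (left clip ⇒ first aligned base, right clip ⇒ last aligned
base, both 1-based). Only CIGAR 'S' counts; hard clips do not retain the
clipped bases and are excluded. A CNV allele is called present when the
proportion reaches the threshold (inclusive ≥) at the start, end, or
both breakpoints; zero qualifying reads on both sides gives
`no_coverage`. The default threshold 0.195 can be re-derived with
`calibrate_threshold`: midpoint between the maximum non-carrier and
minimum carrier proportion when the classes separate, otherwise the
Youden-J-optimal value, always reported with achieved
sensitivity/specificity. Whole-genome amplification distorts coverage,
which is why this is a presence screen and no depth-based copy-number
estimation is attempted. Duplicate-read removal is the caller's
responsibility; calls are invariant to read order.

## Synthetic generator

The generator emulates exactly what the downstream statistics consume:
a 23/10/9 resistant/susceptible/control diploid panel (all samples
treated as female and diploid on autosomes and X alike); background
sites drawn independently per haplotype from per-site base frequencies
(default uniform on [0.05, 0.95], chosen so null sites are informative
for FST/LD rather than mostly rare); candidate SNPs at per-group
frequencies (Bernoulli by default, or exact counts = round(freq × 2N)
for fixtures that must reproduce a frequency table identically);
differentiated windows; sweeps as one stored core haplotype overwriting
a Bernoulli(f)-selected haplotype subset across an interval; missing
genotypes at a configurable rate (default 0); VCF 4.2 output with the
GATK-style INFO/FORMAT fields the QC consumes (written via pysam, read
back via cyvcf2, round-tripping losslessly); SAM reads whose soft-clip
boundaries fall exactly on planted CNV breakpoints; and binomial
tube-test counts.

It deliberately does **not** emulate: recombination or coalescent
structure (background sites are unlinked — linkage exists only where a
sweep is planted), demographic history, sequencing error, or read-level
realism beyond CIGAR/MAPQ. Consequently, passing tests demonstrate that
the estimators recover planted truth under their own model assumptions
and that the permutation/subsampling machinery is calibrated — not that
the pipeline is robust to population structure, batch effects or
alignment artefacts in real data. Determinism: a fixed config seed gives
byte-identical outputs; the pipeline fans one seed into per-stage
streams salted by stage name (CRC32), so toggling a stage never shifts
another stage's randomness, and all derived seeds stay below 2³¹.

## Problem sizes

The shipped tests and the acceptance script use panels sized to the
study design they emulate (23/10/9 samples, 200 permutations, 200
subsample iterations) with 500 1-kb FST windows (~8 variants each) for
the permutation calibration and eight 1000-SNP windows for the H12
scan — large enough for the binomial tolerance bands quoted above while
keeping a full run to seconds. The demo bundle scales chromosome lengths
to ≤ 3 Mbp; *vgsc* candidate positions keep their real AgamP4
coordinates, the *gste2* site is rescaled to fit its demo chromosome.

## Known limitations

- Biallelic SNPs only; multiallelic sites must be split or dropped
  upstream.
- FST permutation p-values are not multiplicity-adjusted across windows;
  the noise-floor criterion is a heuristic guard, not an FWER control.
- H12 subsample averaging assumes phased input; phase errors inflate
  haplotype-class counts and depress H12.
- The CNV screen cannot distinguish tandem-duplication alleles sharing a
  breakpoint, and reports presence, never copy number.
- Odds ratios treat alleles as independent draws; a carrier-level
  (dominance-coded) analysis may be preferable for strong within-host
  correlation.
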