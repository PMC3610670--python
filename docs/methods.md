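# Methods

## Scope and data model

`ehhscan` operates on fully phased, biallelic SNP panels: an H×S matrix
of {0,1} alleles (H chromosome copies, two per diploid sample) with
per-SNP physical (bp) and genetic (cM) coordinates. Phasing and
imputation are deliberately out of scope — the readers refuse missing or
unphased genotypes instead of guessing, because EHH is a statement about
exact haplotype identity and any silent fill-in would bias it upward.
Coordinates are 0-based half-open internally; VCF/BED conventions are
honoured at the file boundary. Sex chromosomes are excluded by default
via a configurable label list. When no genetic map is supplied, a
constant 1 cM/Mb is assumed (the usual cattle-scale convention);
an explicit (chrom, pos_bp, pos_cm) map overrides it.

## Core regions from |D′| confidence intervals

Because phase is known, the two-locus gamete counts are observed
directly and |D′| needs no EM step. The multinomial likelihood is
profiled over |D′| ∈ [0,1] on a grid of step 0.01, with marginal allele
frequencies fixed at their MLEs and the sign of D fixed at the observed
sign; the 90% CI is read off the normalized likelihood mass (5% in each
tail). Classification uses the standard strong-LD bounds (CI low ≥ 0.70
and high ≥ 0.98; recombination when high < 0.90; otherwise
uninformative); all five thresholds are configurable.

A candidate run of ≥ 3 SNPs qualifies as a core region when at least 95%
of its informative pairs are strong-LD; runs with no informative pair
never qualify, i.e. uninformative pairs are excluded from the
denominator. Overlapping candidates are resolved greedily, longest
first, leftmost on ties — deterministic by construction. Two numerical
caps keep the stage O(S·span): pairs are classified only up to
`max_pair_span` = 30 SNPs apart, which also caps candidate run length;
published dense-chip cattle scans report at most ~12 SNPs per core, so
the cap is far from binding. The minimum of 3 SNPs per core follows the
same reports; no maximum is imposed.

## EHH, the matched distance, and REHH

EHH of a core haplotype at distance x is computed by the group-count
formula Σ C(eᵢ,2)/C(c,2) over the carrier groups still identical from
the core edge to x; a brute-force pairwise-identity enumeration is kept
as the test oracle. Distance is genetic and measured from the region's
outermost core SNP in the tested direction. Profiles extend to the
chromosome end or until EHH reaches 0 (for REHH the walk stops at the
first marker at/beyond the matched distance — the statistic is
unchanged).

EHH at the matched distance (default 0.5 cM) is linearly interpolated
between the bracketing markers; a step-function alternative would differ
only in the last inter-marker interval and linear is the minimal
assumption. A profile that has decayed to 0 stays 0 beyond its last
marker; a profile that hits the chromosome end above 0 before the
matched distance yields an undefined test, which is dropped and counted.

The pooled-"others" EHH starts from groups defined by the non-tested
copies' own core haplotypes (groups never merge across core haplotypes)
and extends identically. REHH is the ratio of the two interpolated
values. Undefined cases — singleton tested haplotype, fewer than two
non-tested copies (e.g. a frequency-1 haplotype), zero pooled EHH — are
flagged and dropped, never coerced to 0 or ∞. Each (core haplotype ×
direction) is one test, giving roughly two tests per haplotype as in
published genome scans.

## Significance

Core haplotypes with frequency < 0.20 are discarded (strictly "less
than": the 0.20 boundary is kept). The null distribution of REHH shifts
with haplotype frequency, so tests are binned by frequency (width 0.05
over [0.20, 1]); bins with fewer than 10 tests are merged with their
nearest neighbour. Within a bin the default `gaussian_log` method fits
mean and sd (ddof = 1) of ln REHH and assigns the upper-tail normal
probability; a zero-variance bin falls back to the assumption-free
`empirical_rank` method (p = fraction of bin values ≥ the value), which
is also available globally. Significance calls are strict (p < α) at
α = 0.05 and 0.01; a region is significant when any of its tests is. No
multiple-testing correction is applied across tests by default,
mirroring how genome-wide EHH scans report raw significance counts; a
Bonferroni option exists. On neutral synthetic panels the pooled
p < 0.05 fraction sits near the nominal level (checked at ≥ 2000 tests).

## Annotation and enrichment

Significant regions (at α = 0.01 by default — the stricter of the two
scan levels, and the set a practitioner annotates) are extended ±1 Mb,
clamped to chromosome bounds, and merged when overlapping so each gene is
counted once. A gene enters the study set on ≥ 1 bp overlap with any
extended region (half-open intervals) — the most permissive defensible
mapping rule. Enrichment per term is the hypergeometric upper tail
P(X ≥ study_count) with X ~ Hypergeom(pop_total, pop_count, study_total);
the background universe is always an explicit input (the supplied
annotation's full gene list), never a baked-in constant. The Bonferroni
multiplier is the number of terms actually tested (≥ 1 study hit),
configurable to all terms in the map. Restricting to a term subset (e.g.
second-level ontology terms) is supported via a plain term-id file; the
ontology graph itself is not traversed. A generic case-normalized
gene-list intersection utility serves reference-list comparisons.

## Synthetic data

The generator emulates a dense bovine-chip cohort: ~50 kb mean marker
spacing (exponential gaps), several hundred chromosome copies, a 0.03
MAF floor applied by the downstream QC, and one chromosome of ~100 Mb at
1 cM/Mb. Copies are mosaics of a small founder pool (default 8):
each copy switches founders at Poisson breakpoints. Founders are
genealogy-consistent — each SNP's derived allele is carried by one clade
of a random founder genealogy — so founder haplotypes are mutually
compatible (infinite-sites, no recombination within the pool) and local
|D′| is high, decaying with distance through the mosaic switches. This
is what gives the panels realistic block LD rather than diffuse
intermediate LD. The switch rate default of 4×10⁻⁶ /bp (mean segment
250 kb) was calibrated so a default scan's core-region statistics
(fraction of SNPs inside cores, SNPs per core) fall in the envelope
reported for dense-chip cattle scans.

A sweep is planted as a hard identical-by-descent tract: ⌊fH⌋ randomly
chosen copies have their alleles over ± a stated genetic half-length
replaced by one template copy's alleles. This creates exactly the
high-frequency long-homozygosity signature the EHH test targets, with
recorded truth (carriers and tract), at a fraction of the cost of a
forward simulation. Because the template is an existing copy, background
copies may share its core haplotype without sharing the long tract — the
realistic dilution that REHH must overcome. Fabricated annotations place
non-overlapping genes in uniform slots and assign gene–term memberships
as independent Bernoulli draws, with one designated term's rate
multiplied inside target intervals.

What the generator does *not* model: demography, mutation-rate and
allele-age realism, soft sweeps, genotyping error, and map-rate
heterogeneity (the map is linear in bp). Passing the end-to-end tests
therefore shows the statistics and their wiring are correct and that the
method has power against its canonical signal — not that power or false
positive rates transfer quantitatively to any real cohort.

## Problem sizes and determinism

Default synthetic study conditions are H = 400 copies, S = 2000 SNPs,
one planted sweep at carrier fraction 0.4 with ±1 cM tract. Benchmarks
use 20 replicate seeds per condition; the acceptance script uses 20
replicates per rate with all randomness derived from its single `--seed`.
The pipeline itself is deterministic given inputs and config (ties in
haplotype ordering and region assembly are broken lexicographically /
leftmost), so repeated runs are byte-identical.

## Known limitations

- The |D′| CI is a profile-likelihood (fixed-marginal) approximation;
  very small gamete counts make the grid CI conservative.
- Gaussian-fit p-values are only as good as approximate log-normality of
  within-bin REHH; the empirical-rank method is the honest fallback and
  both are reported per test, never silently mixed (fallbacks are
  logged).
- EHH tests near chromosome ends are dropped rather than truncated,
  which loses power in telomeric regions.
- The enrichment stage treats genes as exchangeable units; gene length
  and clustering biases are not modelled (the planted-truth tests share
  this simplification).
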