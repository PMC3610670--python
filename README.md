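# ehhscan

Selective-sweep detection in phased SNP panels via extended haplotype
homozygosity (EHH/REHH), for population geneticists scanning dense-chip
livestock (or other long-LD) data for signatures of recent positive
selection, with downstream gene annotation and term enrichment.

## The method

Recent positive selection drives a haplotype to high frequency faster
than recombination can break it up, leaving a common haplotype with
unusually long-range homozygosity. The pipeline detects this in four
stages:

1. **Core regions.** After a MAF ≥ 0.03 quality floor, contiguous SNP
   runs in strong mutual LD are found from the confidence interval of
   |D′| on phased two-locus haplotype counts: a pair is *strong LD* when
   CI = [low, high] has low ≥ 0.70 and high ≥ 0.98, *recombination* when
   high < 0.90; a run qualifies when ≥ 95% of its informative pairs are
   strong. Each region's distinct allele strings are its *core
   haplotypes*, partitioning the 2N chromosome copies.

2. **EHH.** For core haplotype *t* with c carriers, at genetic distance
   x from the core edge,

   EHH_t(x) = Σᵢ C(eᵢ, 2) / C(c, 2),

   where the eᵢ are the sizes of the groups of carriers still identical
   over the whole interval out to x — the probability that two randomly
   drawn carriers are homozygous over the interval. EHH starts at 1 and
   only decreases.

3. **REHH.** To correct for local recombination-rate variation, EHH of
   the tested haplotype at a *matched distance* (0.5 cM, suited to
   long-LD cattle genomes) is divided by the pooled EHH of all other
   core haplotypes of the same region at the same distance:
   REHH = EHH_t(0.5 cM) / EHH_others(0.5 cM). Each (core haplotype ×
   direction) is one test; undefined cases (singletons, chromosome edge,
   zero pooled EHH) are dropped and counted.

4. **Significance and enrichment.** Haplotypes with frequency < 20% are
   discarded; within frequency bins of width 0.05, ln REHH is fitted
   with a Gaussian and p is its upper-tail probability (an empirical
   rank alternative is available). Regions significant at p < 0.01 are
   extended ±1 Mb, genes mapped into them (≥ 1 bp overlap, counted
   once), and each term is scored with the hypergeometric upper tail
   against the full annotation as background, Bonferroni-corrected over
   the terms tested; the reported ratio is
   (study_count/study_total)/(pop_count/pop_total).

A synthetic-data module generates phased panels with realistic block LD
(mosaics of genealogy-consistent founders), plants sweeps as
identical-by-descent tracts of controlled frequency and genetic length,
and fabricates gene/term annotations with a known enriched term, so
every stage is testable end to end with ground truth.

## Worked example

```
python analysis/01_simulate_cohort.py --seed 1      # panel + sweep + annotation
python analysis/02_scan_selection_signatures.py     # QC, cores, EHH/REHH, p-values
python analysis/03_annotate_and_enrich.py           # ±1 Mb extension, genes, terms
python analysis/04_benchmark_recovery.py --seed 1 --n-replicates 5
```

prints (seed 1):

```
panel: 400 copies x 2000 SNPs, chromosome 99.0 Mb
planted sweep: tract (49488657, 51427001) (160 carrier copies, 40%)
...
core regions: 232; EHH tests: 3530 (644 dropped as undefined)
tests with frequency >= 20%: 1081; significant: 40 at 0.05, 6 at 0.01
top-REHH significant region: 1:50129358-50219301 (REHH=16.25, p=0.0017) — overlaps the planted tract
...
25 terms tested; top term T007 (ratio=1.85, Bonferroni p=0.4)
planted term T007 ranks first
...
sweep recovery: 5/5 replicates
neutral fixed-window overlap: 0/5 replicates
```

The planted sweep — 160 of 400 chromosome copies made identical over
±1 cM — is recovered as the top-REHH significant region, and the term
seeded preferentially into the swept interval tops the enrichment table.
On neutral panels the scan's top region lands in a fixed 2 Mb window only
at chance rates.

The same pipeline runs from the shell (`ehhscan simulate-panel / scan /
enrich / report`) on a phased VCF or a plain haplotype table + SNP map,
with all thresholds in a YAML config.

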