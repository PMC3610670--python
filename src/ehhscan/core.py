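"""Core-region detection: LD blocks from |D'| confidence intervals.

A core region is a contiguous run of SNPs in strong mutual LD — the unit
at which core haplotypes are enumerated for the EHH test.  Pairwise LD is
classified from the confidence interval of |D'| estimated on phased
two-locus haplotype counts (phase is known, so no EM step): a pair is
"strong LD" when the CI lower bound is >= 0.70 and the upper bound
>= 0.98, "recombination" when the upper bound is < 0.90, otherwise
uninformative.  A run qualifies when, among its informative pairs, the
strong-LD fraction reaches ``min_strong_fraction``; overlapping candidate
runs are resolved greedily, longest first, leftmost on ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import HaplotypePanel

logger = logging.getLogger(__name__)

STRONG, RECOMB, UNINFORMATIVE = 1, 2, 0

_GRID_POINTS = 101  # |D'| likelihood grid resolution (step 0.01)


@dataclass
class PairLdClass:
    """|D'| point estimate, CI bounds and Gabriel-style classification."""

    dprime: float
    ci_low: float
    ci_high: float
    classification: str


@dataclass
class CoreHaplotype:
    """One distinct allele string over a core region's SNPs."""

    alleles: str
    carriers: np.ndarray  # chromosome-copy indices
    frequency: float

    @property
    def count(self) -> int:
        return len(self.carriers)


@dataclass
class CoreRegion:
    region_id: str
    chrom: str
    snp_start_idx: int  # inclusive, global panel column index
    snp_end_idx: int    # inclusive
    start_bp: int       # 0-based half-open physical bounds
    end_bp: int
    n_snps: int
    core_haplotypes: list = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _dprime_ci_arrays(n11, n10, n01, n00, confidence=0.90):
    """Vectorized |D'| estimate and profile-likelihood CI.

    The multinomial likelihood of the four phased gamete counts is profiled
    over |D'| in [0, 1] (marginal allele frequencies held at their MLEs,
    sign of D fixed at the observed sign); the CI is read off the
    normalized likelihood mass at the two tails.

    Returns (dprime, ci_low, ci_high) arrays.
    """
    n11 = np.asarray(n11, dtype=float)
    n10 = np.asarray(n10, dtype=float)
    n01 = np.asarray(n01, dtype=float)
    n00 = np.asarray(n00, dtype=float)
    n = n11 + n10 + n01 + n00
    if np.any(n < 4):
        raise ValueError("need at least 4 chromosome copies per pair")
    pA = (n11 + n10) / n
    pB = (n11 + n01) / n
    if np.any((pA <= 0) | (pA >= 1) | (pB <= 0) | (pB >= 1)):
        raise ValueError("monomorphic column in D' estimation (pre-filter MAF=0 sites)")
    p11 = n11 / n
    D = p11 - pA * pB
    dmax = np.where(
        D >= 0,
        np.minimum(pA * (1 - pB), (1 - pA) * pB),
        np.minimum(pA * pB, (1 - pA) * (1 - pB)),
    )
    sign = np.where(D >= 0, 1.0, -1.0)
    dprime = np.abs(D) / dmax

    grid = np.linspace(0.0, 1.0, _GRID_POINTS)
    eps = 1e-12
    p11g = pA * pB + sign * grid[:, None] * dmax
    p10g = np.clip(pA - p11g, eps, 1.0)
    p01g = np.clip(pB - p11g, eps, 1.0)
    p00g = np.clip(1 - pA - pB + p11g, eps, 1.0)
    p11g = np.clip(p11g, eps, 1.0)
    ll = (n11 * np.log(p11g) + n10 * np.log(p10g)
          + n01 * np.log(p01g) + n00 * np.log(p00g))
    ll -= ll.max(axis=0)
    w = np.exp(ll)
    cum = np.cumsum(w, axis=0)
    cum /= cum[-1]
    tail = (1.0 - confidence) / 2.0
    lo = grid[np.argmax(cum >= tail, axis=0)]
    hi = grid[np.argmax(cum >= 1.0 - tail, axis=0)]
    return dprime, lo, hi


def classify_bounds(ci_low, ci_high, strong_low=0.70, strong_high=0.98,
                    recomb_high=0.90):
    """Classification codes from CI bounds (vectorized)."""
    ci_low = np.asarray(ci_low)
    ci_high = np.asarray(ci_high)
    out = np.full(ci_low.shape, UNINFORMATIVE, dtype=np.int8)
    out[(ci_low >= strong_low) & (ci_high >= strong_high)] = STRONG
    out[ci_high < recomb_high] = RECOMB
    return out


def estimate_dprime_ci(panel: HaplotypePanel, i: int, j: int,
                       confidence: float = 0.90, strong_low=0.70,
                       strong_high=0.98, recomb_high=0.90) -> PairLdClass:
    """LD classification of one SNP pair from phased haplotype counts."""
    if not i < j:
        raise ValueError("require i < j")
    a = panel.alleles[:, i].astype(bool)
    b = panel.alleles[:, j].astype(bool)
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = len(a) - n11 - n10 - n01
    d, lo, hi = _dprime_ci_arrays([n11], [n10], [n01], [n00], confidence)
    code = classify_bounds(lo, hi, strong_low, strong_high, recomb_high)[0]
    name = {STRONG: "strong_ld", RECOMB: "recombination",
            UNINFORMATIVE: "uninformative"}[int(code)]
    return PairLdClass(float(d[0]), float(lo[0]), float(hi[0]), name)


def _pair_classifications(alleles, confidence, strong_low, strong_high,
                          recomb_high, max_span):
    """Classification code for every pair (k, k+d), d = 1..max_span-1.

    Returns dict d -> int8 array of length (n_cols - d).
    """
    h, s = alleles.shape
    a = alleles.astype(bool)
    col1 = a.sum(axis=0)
    out = {}
    idx_d, idx_k = [], []
    counts = [[], [], [], []]
    for d in range(1, min(max_span, s)):
        n11 = (a[:, :-d] & a[:, d:]).sum(axis=0)
        n10 = col1[:-d] - n11
        n01 = col1[d:] - n11
        n00 = h - n11 - n10 - n01
        counts[0].append(n11)
        counts[1].append(n10)
        counts[2].append(n01)
        counts[3].append(n00)
        idx_d.append(np.full(s - d, d))
        idx_k.append(np.arange(s - d))
    if not idx_d:
        return out
    flat = [np.concatenate(c) for c in counts]
    _, lo, hi = _dprime_ci_arrays(*flat, confidence=confidence)
    codes = classify_bounds(lo, hi, strong_low, strong_high, recomb_high)
    dd = np.concatenate(idx_d)
    kk = np.concatenate(idx_k)
    for d in range(1, min(max_span, s)):
        sel = dd == d
        arr = np.empty(s - d, dtype=np.int8)
        arr[kk[sel]] = codes[sel]
        out[d] = arr
    return out


def enumerate_core_haplotypes(panel: HaplotypePanel, region: CoreRegion):
    """Distinct allele strings over a region, sorted by descending frequency.

    Ties broken lexicographically on the allele string so the ordering is
    deterministic.  Carrier lists partition the panel's chromosome copies.
    """
    block = panel.alleles[:, region.snp_start_idx: region.snp_end_idx + 1]
    h = block.shape[0]
    uniq, inverse, cnt = np.unique(block, axis=0, return_inverse=True,
                                   return_counts=True)
    strings = ["".join(map(str, row)) for row in uniq]
    order = sorted(range(len(uniq)), key=lambda t: (-cnt[t], strings[t]))
    haps = []
    for t in order:
        carriers = np.flatnonzero(inverse == t)
        haps.append(CoreHaplotype(alleles=strings[t], carriers=carriers,
                                  frequency=cnt[t] / h))
    return haps


def detect_core_regions(panel: HaplotypePanel, confidence: float = 0.90,
                        strong_low: float = 0.70, strong_high: float = 0.98,
                        recomb_high: float = 0.90,
                        min_strong_fraction: float = 0.95,
                        min_core_snps: int = 3, max_core_snps: int | None = None,
                        max_pair_span: int = 30):
    """Find maximal non-overlapping strong-LD runs and their core haplotypes.

    Candidate runs of ``min_core_snps``..``max_pair_span`` SNPs qualify when
    the strong-LD fraction among their informative pairs is at least
    ``min_strong_fraction`` (runs with no informative pair never qualify);
    qualifying runs are accepted greedily, longest first, leftmost on ties.
    ``max_pair_span`` bounds both the candidate run length and the pair
    distances that are classified, keeping the pair stage O(S x span).
    """
    regions = []
    for chrom in panel.chromosomes:
        cols = panel.chrom_indices(chrom)
        c0 = int(cols[0])
        block = panel.alleles[:, cols]
        nc = block.shape[1]
        if nc < min_core_snps:
            continue
        max_len = min(max_pair_span, nc)
        if max_core_snps is not None:
            max_len = min(max_len, max_core_snps)
        cls = _pair_classifications(block, confidence, strong_low, strong_high,
                                    recomb_high, max_pair_span)
        # prefix sums per pair distance for O(1) window pair counts
        pref_s, pref_i = {}, {}
        for d, arr in cls.items():
            pref_s[d] = np.concatenate([[0], np.cumsum(arr == STRONG)])
            pref_i[d] = np.concatenate([[0], np.cumsum(arr != UNINFORMATIVE)])
        chosen = []
        occupied = np.zeros(nc, dtype=bool)
        for length in range(max_len, min_core_snps - 1, -1):
            n_windows = nc - length + 1
            strong = np.zeros(n_windows)
            inform = np.zeros(n_windows)
            for d in range(1, length):
                ps, pi = pref_s[d], pref_i[d]
                strong += ps[length - d: length - d + n_windows] - ps[:n_windows]
                inform += pi[length - d: length - d + n_windows] - pi[:n_windows]
            ok = (inform > 0) & (strong >= min_strong_fraction * inform)
            for a in np.flatnonzero(ok):
                if occupied[a: a + length].any():
                    continue
                occupied[a: a + length] = True
                chosen.append((a, a + length - 1))
        chosen.sort()
        pos = panel.snps["pos_bp"].to_numpy()
        for a, b in chosen:
            gi, gj = c0 + a, c0 + b
            region = CoreRegion(
                region_id=f"{chrom}:{int(pos[gi])}-{int(pos[gj]) + 1}",
                chrom=str(chrom), snp_start_idx=gi, snp_end_idx=gj,
                start_bp=int(pos[gi]), end_bp=int(pos[gj]) + 1,
                n_snps=b - a + 1,
            )
            region.core_haplotypes = enumerate_core_haplotypes(panel, region)
            regions.append(region)
    logger.info("detect_core_regions: %d regions", len(regions))
    return regions


def regions_to_bed(regions) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [(r.chrom, r.start_bp, r.end_bp, r.region_id, r.n_snps) for r in regions],
        columns=["chrom", "start_bp", "end_bp", "region_id", "n_snps"],
    )
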