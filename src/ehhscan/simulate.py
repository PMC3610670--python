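"""Synthetic phased panels, planted sweeps and fabricated annotations.

The generator makes every pipeline stage testable without external data.
Chromosome copies are mosaics of a small founder pool: each copy walks
along the chromosome copying one founder and switches founders at Poisson
breakpoints, which produces the distance-decaying, block-structured LD of
a real livestock population (a 50-kb SNP chip over a long-LD genome).  A
selective sweep is planted as a hard identical-by-descent tract: a chosen
carrier fraction of copies has its alleles over +/- a stated genetic
half-length replaced by one template haplotype — exactly the
long-homozygous, high-frequency signature the EHH test targets, with a
recorded ground truth.

Defaults emulate the scale of a dense bovine SNP-chip scan: ~50 kb marker
spacing, several hundred chromosome copies, a 0.03 MAF floor applied
downstream, sweep carrier fractions of 20–60%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import HaplotypePanel

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Knobs of the mosaic haplotype simulator.

    switch_rate_per_bp sets the LD decay scale: mean founder-segment
    length is 1/rate bp.  The 250-kb default was calibrated so that a
    default scan's core-region statistics (fraction of SNPs in cores,
    SNPs per core) sit in the envelope reported for dense-chip cattle
    scans.  Founder allele frequencies follow the configured spectrum
    (uniform on [freq_low, freq_high], quantized to founder clades).
    """

    n_copies: int = 400
    n_snps: int = 2000
    spacing_mean_bp: float = 50_000.0
    n_founders: int = 8
    switch_rate_per_bp: float = 4e-6
    freq_low: float = 0.05
    freq_high: float = 0.95
    map_rate_cm_per_mb: float = 1.0
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1 or self.n_copies < 4 or self.n_copies % 2:
            raise ValueError("need n_snps >= 1 and even n_copies >= 4")


@dataclass
class SyntheticTruth:
    """Ground truth of planted structure, for test harnesses."""

    sweep_tract_bp: tuple | None = None      # (start_bp, end_bp) half-open
    sweep_position_bp: int | None = None
    sweep_carriers: np.ndarray | None = None
    enriched_term: str | None = None
    enriched_target_bp: list = field(default_factory=list)
    term_gene_flags: dict = field(default_factory=dict)
    seed: int | None = None


def _founder_clades(n_founders: int, rng) -> np.ndarray:
    """Clades of a random founder genealogy, as boolean masks.

    A random binary coalescent topology over the founders; every edge's
    descendant set (size 1..K-1) is a clade.  Assigning each SNP's derived
    allele to one clade makes all founder haplotypes mutually compatible
    (infinite-sites, no recombination inside the founder pool), so |D'|
    between nearby sites is 1 among founders — the source of the block LD
    that mosaic switching then erodes with distance.
    """
    groups = [[i] for i in range(n_founders)]
    clades = [list(g) for g in groups]
    while len(groups) > 2:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        merged = groups[i] + groups[j]
        groups = [g for t, g in enumerate(groups) if t not in (i, j)] + [merged]
        clades.append(merged)
    masks = np.zeros((len(clades), n_founders), dtype=bool)
    for t, members in enumerate(clades):
        masks[t, members] = True
    return masks


def simulate_neutral_panel(config: SimulationConfig) -> HaplotypePanel:
    """Mosaic-of-founders phased panel with block-structured LD.

    Marker positions are cumulative exponential gaps (mean
    ``spacing_mean_bp``).  Founder haplotypes are genealogy-consistent:
    each SNP's derived allele is carried by the clade whose founder
    frequency best matches a target drawn from the configured spectrum.
    Each copy walks along the chromosome copying one founder, switching
    founders at Poisson breakpoints with the configured per-bp rate, which
    yields distance-decaying block LD.  Deterministic under the config
    seed.
    """
    rng = np.random.default_rng(config.seed)
    gaps = rng.exponential(config.spacing_mean_bp, size=config.n_snps)
    pos = np.cumsum(np.maximum(1, np.round(gaps)).astype(np.int64))
    clades = _founder_clades(config.n_founders, rng)
    clade_freq = clades.mean(axis=1)
    target = rng.uniform(config.freq_low, config.freq_high, size=config.n_snps)
    # nearest clade frequency to each target, random tie-break
    dist = np.abs(clade_freq[:, None] - target[None, :])
    dist += rng.uniform(0, 1e-6, size=dist.shape)
    founders = clades[np.argmin(dist, axis=0)].T.astype(np.uint8)
    # per-copy founder path: switch probability per inter-marker gap
    gap_bp = np.diff(pos, prepend=pos[0])
    gap_bp[0] = 0
    p_switch = 1.0 - np.exp(-config.switch_rate_per_bp * gap_bp)
    state = rng.integers(0, config.n_founders, size=config.n_copies)
    alleles = np.empty((config.n_copies, config.n_snps), dtype=np.uint8)
    for s in range(config.n_snps):
        if s > 0:
            flip = rng.random(config.n_copies) < p_switch[s]
            n_flip = int(flip.sum())
            if n_flip:
                state[flip] = rng.integers(0, config.n_founders, size=n_flip)
        alleles[:, s] = founders[state, s]
    snps = pd.DataFrame({
        "id": [f"snp{i}" for i in range(config.n_snps)],
        "chrom": config.chrom,
        "pos_bp": pos,
        "pos_cm": pos * config.map_rate_cm_per_mb / 1e6,
        "ref": "A",
        "alt": "G",
    })
    return HaplotypePanel(alleles=alleles, snps=snps)


def plant_sweep(panel: HaplotypePanel, position_bp: int,
                carrier_fraction: float, tract_half_length_cm: float,
                seed: int, map_rate_cm_per_mb: float = 1.0):
    """Plant a hard identical-by-descent tract (the sweep signature).

    ``floor(carrier_fraction * H)`` randomly chosen copies have their
    alleles over position +/- the genetic half-length replaced by one
    template haplotype (an existing copy's alleles, so allele frequencies
    stay plausible); all other entries are untouched.  A tract extending
    past the chromosome is clamped with a warning.  Returns (new panel,
    truth).
    """
    if not 0.0 < carrier_fraction < 1.0:
        raise ValueError("carrier_fraction must be in (0,1)")
    h = panel.n_copies
    n_carriers = int(np.floor(carrier_fraction * h))
    if n_carriers < 2:
        raise ValueError("carrier_fraction too small: fewer than 2 carriers")
    rng = np.random.default_rng(seed)
    half_bp = tract_half_length_cm / map_rate_cm_per_mb * 1e6
    lo, hi = position_bp - half_bp, position_bp + half_bp
    pos = panel.snps["pos_bp"].to_numpy()
    if lo < pos[0] or hi > pos[-1]:
        logger.warning("plant_sweep: tract [%d, %d] clamped to chromosome", lo, hi)
        lo, hi = max(lo, pos[0]), min(hi, pos[-1])
    cols = np.flatnonzero((pos >= lo) & (pos <= hi))
    if cols.size == 0:
        raise ValueError("sweep tract contains no SNPs")
    carriers = rng.choice(h, size=n_carriers, replace=False)
    carriers.sort()
    template_row = int(rng.choice(carriers))
    alleles = panel.alleles.copy()
    alleles[np.ix_(carriers, cols)] = alleles[template_row, cols]
    truth = SyntheticTruth(
        sweep_tract_bp=(int(pos[cols[0]]), int(pos[cols[-1]]) + 1),
        sweep_position_bp=int(position_bp),
        sweep_carriers=carriers,
        seed=seed,
    )
    out = HaplotypePanel(alleles=alleles, snps=panel.snps.copy(),
                         sample_ids=list(panel.sample_ids))
    return out, truth


def simulate_annotation(chrom_length: int, n_genes: int = 400, n_terms: int = 25,
                        mean_genes_per_term: float = 40.0,
                        enriched_term_spec: dict | None = None,
                        seed: int = 0, chrom: str = "1"):
    """Fabricated gene intervals and term map, with an optional planted term.

    Genes are non-overlapping: the chromosome is cut into ``n_genes`` equal
    slots and one gene placed uniformly inside each slot.  Each (gene,
    term) association is an independent Bernoulli draw at rate
    ``mean_genes_per_term / n_genes``; for the planted term
    (``enriched_term_spec = {"term_id", "target_intervals_bp",
    "multiplier"}``) the rate is multiplied for genes inside the target
    intervals, creating a known enrichment.  Returns (genes DataFrame,
    terms dict, descriptions dict, truth).
    """
    if n_genes < 1:
        raise ValueError("n_genes >= 1 required")
    slot = chrom_length // n_genes
    gene_len = max(1000, slot // 4)
    if gene_len >= slot:
        raise ValueError("infeasible packing: chromosome too short for n_genes")
    rng = np.random.default_rng(seed)
    starts = (np.arange(n_genes) * slot
              + rng.integers(0, slot - gene_len, size=n_genes))
    genes = pd.DataFrame({
        "gene_id": [f"gene{i:04d}" for i in range(n_genes)],
        "chrom": chrom,
        "start_bp": starts,
        "end_bp": starts + gene_len,
    })
    base_rate = min(1.0, mean_genes_per_term / n_genes)
    spec = enriched_term_spec or {}
    planted = spec.get("term_id")
    targets = spec.get("target_intervals_bp", [])
    mult = float(spec.get("multiplier", 1.0))
    in_target = np.zeros(n_genes, dtype=bool)
    for t_lo, t_hi in targets:
        in_target |= (starts < t_hi) & (starts + gene_len > t_lo)
    terms: dict = {}
    descriptions: dict = {}
    flags: dict = {}
    for t in range(n_terms):
        term_id = f"T{t:03d}"
        rate = np.full(n_genes, base_rate)
        if term_id == planted:
            rate[in_target] = np.minimum(1.0, base_rate * mult)
        member = rng.random(n_genes) < rate
        terms[term_id] = set(genes.loc[member, "gene_id"])
        descriptions[term_id] = f"synthetic term {t}"
        if term_id == planted:
            flags = dict(zip(genes["gene_id"], member & in_target))
    truth = SyntheticTruth(enriched_term=planted,
                           enriched_target_bp=list(targets),
                           term_gene_flags=flags, seed=seed)
    return genes, terms, descriptions, truth
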