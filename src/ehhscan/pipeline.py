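"""End-to-end orchestration: QC -> core regions -> EHH/REHH -> significance
-> annotation/enrichment, as a pure function of (inputs, config, seed).

Every output table is written with a provenance header (# version, config
hash, stage counts) and is byte-reproducible for identical inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import core, ehh, enrichment, io, significance

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline thresholds, with defaults for a dense-chip cattle scan."""

    # inputs (either a phased VCF, or haplotype table + map)
    vcf: str | None = None
    geno: str | None = None
    snp_map: str | None = None
    genetic_map: str | None = None          # TSV chrom/pos_bp/pos_cm; else rate
    map_rate_cm_per_mb: float = 1.0
    # QC
    min_maf: float = 0.03
    excluded_chromosomes: tuple = ("X",)
    # core regions
    ld_confidence: float = 0.90
    strong_low: float = 0.70
    strong_high: float = 0.98
    recomb_high: float = 0.90
    min_strong_fraction: float = 0.95
    min_core_snps: int = 3
    max_core_snps: int | None = None
    max_pair_span: int = 30
    # EHH / significance
    target_cm: float = 0.5
    min_freq: float = 0.20
    bin_width: float = 0.05
    p_method: str = "gaussian_log"
    min_bin_n: int = 10
    alphas: tuple = (0.05, 0.01)
    # enrichment
    extension_pad_bp: int = 1_000_000
    genes_bed: str | None = None
    term_assoc: str | None = None
    term_desc: str | None = None
    term_subset: str | None = None          # optional term-id subset file
    chrom_lengths: dict = field(default_factory=dict)
    # misc
    out_dir: str = "results"
    seed: int = 0

    def validate(self):
        if not (0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must be in [0, 0.5)")
        if not (0 < self.min_freq <= 1):
            raise ValueError("min_freq must be in (0, 1]")
        for a in self.alphas:
            if not (0 < a < 1):
                raise ValueError("alphas must be in (0, 1)")
        if self.target_cm < 0 or self.extension_pad_bp < 0:
            raise ValueError("target_cm and extension pad must be >= 0")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ScanResult:
    panel: "io.HaplotypePanel"
    regions: list
    tests_all: pd.DataFrame       # every (haplotype x direction) test
    tests: pd.DataFrame           # frequency-filtered, p-values assigned
    summary: pd.DataFrame
    counts: dict


def load_panel(config: PipelineConfig) -> "io.HaplotypePanel":
    if config.vcf:
        panel = io.read_phased_vcf(config.vcf)
    elif config.geno and config.snp_map:
        panel = io.read_haplotype_table(config.geno, config.snp_map)
    else:
        raise ValueError("config must supply either vcf or geno+snp_map")
    if config.genetic_map:
        gmap = pd.read_csv(config.genetic_map, sep="\t", dtype={"chrom": str})
        panel = io.attach_genetic_map(panel, gmap)
    elif panel.snps["pos_cm"].isna().any():
        panel = io.attach_genetic_map(panel, config.map_rate_cm_per_mb)
    return panel


def scan_panel(panel, config: PipelineConfig) -> ScanResult:
    """QC, core-region detection, REHH tests and significance on a panel."""
    config.validate()
    counts = {"n_snps_input": panel.n_snps}
    panel = panel.drop_chromosomes(config.excluded_chromosomes)
    counts["n_snps_after_chrom_exclusion"] = panel.n_snps
    panel = io.apply_maf_filter(panel, config.min_maf)
    counts["n_snps_after_maf"] = panel.n_snps
    if panel.n_snps == 0:
        raise ValueError("QC failure: no SNPs survive the MAF filter "
                         f"(min_maf={config.min_maf})")
    regions = core.detect_core_regions(
        panel, confidence=config.ld_confidence, strong_low=config.strong_low,
        strong_high=config.strong_high, recomb_high=config.recomb_high,
        min_strong_fraction=config.min_strong_fraction,
        min_core_snps=config.min_core_snps, max_core_snps=config.max_core_snps,
        max_pair_span=config.max_pair_span)
    counts["n_regions"] = len(regions)
    tests_all = ehh.all_rehh_tests(panel, regions, target_cm=config.target_cm)
    counts["n_tests_total"] = len(tests_all)
    counts["n_tests_dropped"] = int((~tests_all["defined"]).sum()) if len(tests_all) else 0
    filtered = significance.filter_by_frequency(tests_all, config.min_freq)
    counts["n_tests_after_freq_filter"] = len(filtered)
    if len(filtered):
        tests = significance.assign_p_values(
            filtered, min_freq=config.min_freq, bin_width=config.bin_width,
            method=config.p_method, min_bin_n=config.min_bin_n)
    else:
        tests = filtered.assign(p_value=pd.Series(dtype=float))
    for alpha in config.alphas:
        counts[f"n_sig_{alpha:g}"] = int((tests["p_value"] < alpha).sum()) if len(tests) else 0
    summary = significance.summarize_scan(panel, regions, tests, config.alphas)
    return ScanResult(panel=panel, regions=regions, tests_all=tests_all,
                      tests=tests, summary=summary, counts=counts)


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, counts: dict):
    header = (f"# ehhscan {__version__} config={config.config_hash()} "
              + " ".join(f"{k}={v}" for k, v in sorted(counts.items())) + "\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_scan(config: PipelineConfig, panel=None, out_dir=None) -> ScanResult:
    """Full scan with outputs: regions BED, haplotype/test TSVs, summary TSV."""
    if panel is None:
        panel = load_panel(config)
    result = scan_panel(panel, config)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    _write_tsv(core.regions_to_bed(result.regions), out / "core_regions.bed",
               config, result.counts)
    haps = pd.DataFrame(
        [(r.region_id, h.alleles, h.count, h.frequency)
         for r in result.regions for h in r.core_haplotypes],
        columns=["region_id", "haplotype", "count", "frequency"])
    _write_tsv(haps, out / "core_haplotypes.tsv", config, result.counts)
    _write_tsv(result.tests_all, out / "tests_all.tsv", config, result.counts)
    _write_tsv(result.tests, out / "tests.tsv", config, result.counts)
    _write_tsv(result.summary, out / "scan_summary.tsv", config, result.counts)
    for alpha in config.alphas:
        if len(result.tests):
            sig = result.tests.loc[result.tests["p_value"] < alpha,
                                   ["chrom", "start_bp", "end_bp", "region_id"]]
            sig = sig.drop_duplicates().reset_index(drop=True)
        else:
            sig = pd.DataFrame(columns=["chrom", "start_bp", "end_bp", "region_id"])
        _write_tsv(sig, out / f"significant_regions_{alpha:g}.bed", config,
                   result.counts)
    logger.info("run_scan: %s", result.counts)
    return result


def run_enrichment(config: PipelineConfig, result: ScanResult,
                   genes=None, terms=None, descriptions=None,
                   alpha: float | None = None, out_dir=None) -> pd.DataFrame:
    """Extend significant regions, map genes, run term enrichment; write TSVs."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alpha = alpha if alpha is not None else min(config.alphas)
    if genes is None:
        if not config.genes_bed:
            raise ValueError("no gene annotation supplied")
        genes = io.read_genes_bed(config.genes_bed)
    if terms is None:
        if not config.term_assoc:
            raise ValueError("no term association supplied")
        terms, descriptions = io.read_term_map(config.term_assoc, config.term_desc)
    if config.term_subset:
        with open(config.term_subset) as fh:
            subset = {ln.strip() for ln in fh if ln.strip()}
        terms = {t: g for t, g in terms.items() if t in subset}
    sig_regions = significance.significant_regions(result.regions, result.tests,
                                                   alpha)
    if not sig_regions:
        path = out / "enrichment.tsv"
        with open(path, "w") as fh:
            fh.write(f"# ehhscan {__version__} config={config.config_hash()} "
                     f"n_significant_regions=0 alpha={alpha}\n"
                     "# no significant regions at this level; nothing to enrich\n")
        logger.warning("run_enrichment: no significant regions at alpha=%g", alpha)
        return pd.DataFrame()
    chrom_lengths = dict(config.chrom_lengths)
    for chrom in {r.chrom for r in sig_regions}:
        if chrom not in chrom_lengths:
            cols = result.panel.chrom_indices(chrom)
            chrom_lengths[chrom] = int(
                result.panel.snps["pos_bp"].to_numpy()[cols[-1]] + 1)
    extended = enrichment.extend_regions(sig_regions, config.extension_pad_bp,
                                         chrom_lengths)
    study = enrichment.map_genes(extended, genes)
    background = set(genes["gene_id"].astype(str))
    table = enrichment.hypergeometric_enrichment(study, background, terms,
                                                 descriptions)
    counts = {"n_significant_regions": len(sig_regions),
              "n_extended_regions": len(extended),
              "n_study_genes": len(study), "n_background_genes": len(background)}
    _write_tsv(table, out / "enrichment.tsv", config, counts)
    ext_df = pd.DataFrame([(r.chrom, r.start_bp, r.end_bp, r.region_id)
                           for r in extended],
                          columns=["chrom", "start_bp", "end_bp", "region_id"])
    _write_tsv(ext_df, out / "extended_regions.bed", config, counts)
    with open(out / "study_genes.txt", "w") as fh:
        fh.write("\n".join(sorted(study)) + "\n")
    logger.info("run_enrichment: %s", counts)
    return table
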