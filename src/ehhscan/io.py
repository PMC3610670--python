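"""Phased haplotype panel container and I/O.

The panel is the pipeline's canonical in-memory object: an H x S matrix of
{0,1} alleles over H chromosome copies (two per diploid sample) and an
ordered SNP table with physical (bp, 0-based internal) and genetic (cM)
coordinates.  Phasing and imputation are upstream concerns: the readers
refuse missing or unphased genotypes rather than guessing, because any
silent fill-in would corrupt downstream haplotype-homozygosity statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SNP_COLUMNS = ["id", "chrom", "pos_bp", "pos_cm", "ref", "alt"]


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class HaplotypePanel:
    """Fully phased biallelic SNP panel.

    Parameters
    ----------
    alleles : ndarray of uint8, shape (H, S)
        One row per chromosome copy, entries in {0, 1}.
    snps : DataFrame with columns id, chrom, pos_bp, pos_cm, ref, alt
        Sorted by (chrom, pos_bp); pos_bp is 0-based; pos_cm may be NaN
        until a genetic map is attached.
    sample_ids : list of str, length H // 2
    """

    alleles: np.ndarray
    snps: pd.DataFrame
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D (copies x SNPs)")
        h, s = self.alleles.shape
        if h % 2 != 0:
            raise ValueError(f"number of chromosome copies must be even, got {h}")
        if len(self.snps) != s:
            raise ValueError(
                f"SNP table has {len(self.snps)} rows but matrix has {s} columns"
            )
        if not self.sample_ids:
            self.sample_ids = [f"sample{i}" for i in range(h // 2)]
        if len(self.sample_ids) * 2 != h:
            raise ValueError("sample_ids length must equal H/2")
        extra = self.alleles[(self.alleles != 0) & (self.alleles != 1)]
        if extra.size:
            raise ValueError("allele matrix must contain only 0/1 (no missing data)")
        self.snps = self.snps.reset_index(drop=True)
        self._check_sorted()

    def _check_sorted(self):
        for _, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("SNP positions must be strictly increasing per chromosome")
            cm = grp["pos_cm"].to_numpy(dtype=float)
            cm = cm[~np.isnan(cm)]
            if cm.size and np.any(np.diff(cm) < 0):
                raise ValueError("genetic positions must be non-decreasing per chromosome")

    @property
    def n_copies(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.snps["chrom"]))

    def chrom_indices(self, chrom) -> np.ndarray:
        """Column indices of SNPs on one chromosome (contiguous by sortedness)."""
        cache = getattr(self, "_chrom_cache", None)
        if cache is None:
            cache = self._chrom_cache = {}
        if chrom not in cache:
            cache[chrom] = np.flatnonzero((self.snps["chrom"] == chrom).to_numpy())
        return cache[chrom]

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the '1' allele per SNP."""
        return self.alleles.mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, mask_or_idx) -> "HaplotypePanel":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypePanel(
            alleles=self.alleles[:, idx],
            snps=self.snps.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def drop_chromosomes(self, excluded) -> "HaplotypePanel":
        """Remove all SNPs on the given chromosome labels (e.g. sex chromosomes)."""
        excluded = {str(c) for c in excluded}
        keep = ~self.snps["chrom"].astype(str).isin(excluded).to_numpy()
        return self.subset_snps(keep)


def read_phased_vcf(path, on_invalid: str = "error") -> HaplotypePanel:
    """Read a phased VCF into a :class:`HaplotypePanel`.

    Only biallelic SNP records with fully phased GT fields ("|" separator,
    no missing alleles) are accepted.  ``on_invalid`` controls what happens
    to records that fail: "error" (default) raises :class:`FormatError`
    naming the record, "skip" drops them and logs a count.

    VCF positions are 1-based; they are stored 0-based internally.
    """
    from cyvcf2 import VCF

    if on_invalid not in ("error", "skip"):
        raise ValueError("on_invalid must be 'error' or 'skip'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    columns = []
    n_skipped = 0
    for var in vcf:
        label = f"{var.CHROM}:{var.POS} ({var.ID or '.'})"
        bad = None
        if len(var.ALT) != 1:
            bad = "not biallelic"
        elif len(var.REF) != 1 or len(var.ALT[0]) != 1:
            bad = "not a SNP"
        else:
            gt = np.asarray(var.genotype.array())
            # columns: allele_a, allele_b, phased flag
            if gt.shape[1] < 3:
                bad = "missing GT"
            elif np.any(gt[:, :2] < 0):
                bad = "missing genotype call"
            elif not np.all(gt[:, 2]):
                bad = "unphased genotype (\"/\" separator)"
        if bad is not None:
            if on_invalid == "error":
                raise FormatError(f"record {label}: {bad}")
            n_skipped += 1
            continue
        columns.append(gt[:, :2].reshape(-1))
        rows.append(
            (var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS - 1, np.nan,
             var.REF, var.ALT[0])
        )
    if n_skipped:
        logger.info("read_phased_vcf: skipped %d invalid records", n_skipped)
    if not rows:
        raise FormatError(f"{path}: no usable phased biallelic SNP records")
    alleles = np.stack(columns, axis=1).astype(np.uint8)
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    return HaplotypePanel(alleles=alleles, snps=snps, sample_ids=samples)


def read_haplotype_table(geno_path, map_path) -> HaplotypePanel:
    """Read a plain-text haplotype matrix plus SNP map.

    ``geno_path``: one line per chromosome copy, a string of 0/1 characters
    (consecutive pairs of lines are the two copies of one sample).
    ``map_path``: TSV with columns id, chrom, pos_bp and optionally pos_cm.
    """
    with open(geno_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{geno_path}: empty haplotype file")
    if len(lines) % 2 != 0:
        raise FormatError(f"{geno_path}: odd number of chromosome copies ({len(lines)})")
    smap = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    required = {"id", "chrom", "pos_bp"}
    if not required.issubset(smap.columns):
        raise FormatError(f"{map_path}: map needs columns {sorted(required)}")
    s = len(smap)
    for k, ln in enumerate(lines):
        if len(ln) != s:
            raise FormatError(
                f"{geno_path}: row {k} has {len(ln)} alleles, map has {s} SNPs"
            )
        if set(ln) - {"0", "1"}:
            raise FormatError(f"{geno_path}: row {k} contains non-0/1 characters")
    alleles = np.frombuffer("".join(lines).encode(), dtype=np.uint8).reshape(
        len(lines), s
    ) - ord("0")
    snps = pd.DataFrame(
        {
            "id": smap["id"].astype(str),
            "chrom": smap["chrom"].astype(str),
            "pos_bp": smap["pos_bp"].astype(np.int64),
            "pos_cm": smap["pos_cm"].astype(float) if "pos_cm" in smap else np.nan,
            "ref": smap["ref"].astype(str) if "ref" in smap else "A",
            "alt": smap["alt"].astype(str) if "alt" in smap else "G",
        }
    )
    return HaplotypePanel(alleles=alleles.astype(np.uint8), snps=snps)


def write_haplotype_table(panel: HaplotypePanel, geno_path, map_path) -> None:
    """Inverse of :func:`read_haplotype_table` (bit-exact round trip)."""
    digits = panel.alleles + ord("0")
    with open(geno_path, "w") as fh:
        for row in digits:
            fh.write(row.tobytes().decode() + "\n")
    panel.snps.to_csv(map_path, sep="\t", index=False)


def apply_maf_filter(panel: HaplotypePanel, min_maf: float = 0.03) -> HaplotypePanel:
    """Remove SNPs with minor allele frequency strictly below ``min_maf``.

    The boundary is kept: a SNP at exactly ``min_maf`` is retained, since
    the removal rule is "MAF less than" the threshold.
    """
    maf = panel.maf()
    keep = maf >= min_maf
    removed = int((~keep).sum())
    logger.info("apply_maf_filter: removed %d of %d SNPs (MAF < %g)",
                removed, panel.n_snps, min_maf)
    if removed == panel.n_snps:
        logger.warning("apply_maf_filter: no SNPs survive the MAF filter")
    return panel.subset_snps(keep)


def attach_genetic_map(panel: HaplotypePanel, map_source, strict: bool = True
                       ) -> HaplotypePanel:
    """Set per-SNP genetic positions (cM).

    ``map_source`` is either a constant recombination rate in cM/Mb
    (``pos_cm = pos_bp * rate / 1e6``) or a DataFrame with columns
    (chrom, pos_bp, pos_cm) giving explicit map points; explicit points
    take precedence where present and, in non-strict mode, the constant
    default rate of 1 cM/Mb fills gaps.
    """
    snps = panel.snps.copy()
    if np.isscalar(map_source):
        rate = float(map_source)
        snps["pos_cm"] = snps["pos_bp"].to_numpy() * rate / 1e6
    else:
        gm = map_source
        merged = snps.merge(
            gm[["chrom", "pos_bp", "pos_cm"]],
            on=["chrom", "pos_bp"], how="left", suffixes=("_old", ""),
        )
        missing = merged["pos_cm"].isna()
        if missing.any() and strict:
            raise FormatError(
                f"genetic map does not cover {int(missing.sum())} panel SNPs"
            )
        filled = merged["pos_cm"].to_numpy(dtype=float)
        filled[missing.to_numpy()] = (
            merged.loc[missing, "pos_bp"].to_numpy() * 1.0 / 1e6
        )
        snps["pos_cm"] = filled
    out = HaplotypePanel(alleles=panel.alleles, snps=snps,
                         sample_ids=list(panel.sample_ids))
    return out


def read_genes_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED (chrom, start, end, name): 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start_bp", "end_bp", "gene_id"],
                     dtype={0: str, 3: str})
    if (df["start_bp"] >= df["end_bp"]).any():
        raise FormatError(f"{path}: BED intervals must satisfy start < end")
    return df[["gene_id", "chrom", "start_bp", "end_bp"]]


def read_genes_gff3(path, feature: str = "gene", id_attr: str = "ID") -> pd.DataFrame:
    """Read gene intervals from a minimal GFF3 (1-based closed -> 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get(id_attr, attrs.get("Name", f"{parts[0]}:{parts[3]}"))
            rows.append((gid, parts[0], int(parts[3]) - 1, int(parts[4])))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start_bp", "end_bp"])
    if df.empty:
        raise FormatError(f"{path}: no '{feature}' features found")
    return df


def read_term_map(assoc_path, desc_path=None):
    """Read a gene->term association TSV plus optional term descriptions.

    ``assoc_path``: two columns (gene_id, term_id), one association per
    line, GeneMerge style (a gene may carry several terms via repeated
    rows or a semicolon-joined second column).  Returns
    ``(terms: dict term_id -> set of gene_ids, descriptions: dict)``.
    """
    assoc = pd.read_csv(assoc_path, sep="\t", header=None,
                        names=["gene_id", "term_id"], dtype=str, comment="#")
    terms: dict = {}
    for gene, term_field in assoc.itertuples(index=False):
        if pd.isna(term_field):
            continue
        for term in str(term_field).split(";"):
            term = term.strip()
            if term:
                terms.setdefault(term, set()).add(str(gene))
    descriptions = {}
    if desc_path is not None:
        desc = pd.read_csv(desc_path, sep="\t", header=None,
                           names=["term_id", "description"], dtype=str, comment="#")
        descriptions = dict(zip(desc["term_id"], desc["description"]))
    return terms, descriptions
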