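"""Frequency filtering and frequency-binned significance of REHH tests.

Sweep candidates must be common: core haplotypes with frequency below 20%
are discarded (strictly "less than", so the boundary is retained).  REHH
is then compared within core-haplotype frequency bins, because its null
distribution shifts with frequency: within each bin ln(REHH) is fitted
with a Gaussian and the p-value is the upper-tail probability
(``gaussian_log``), or, assumption-free, the within-bin upper empirical
rank (``empirical_rank``).  Thresholding is strict (p < alpha).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def filter_by_frequency(tests: pd.DataFrame, min_freq: float = 0.20
                        ) -> pd.DataFrame:
    """Keep defined tests with core-haplotype frequency >= min_freq."""
    if tests.empty:
        return tests.copy()
    keep = (tests["frequency"] >= min_freq) & tests["defined"]
    out = tests.loc[keep].reset_index(drop=True)
    logger.info("filter_by_frequency: kept %d of %d tests (freq >= %g, defined)",
                len(out), len(tests), min_freq)
    return out


def _merged_bins(freqs, min_freq, bin_width, min_bin_n):
    """Assign tests to frequency bins over [min_freq, 1], merging sparse bins.

    Bins with fewer than ``min_bin_n`` tests are merged with the nearest
    (by bin-center distance, lower on ties) non-empty neighbouring group
    until all groups meet the occupancy floor or one group remains.
    Returns an integer group id per test.
    """
    n_bins = max(1, int(np.ceil((1.0 - min_freq) / bin_width)))
    idx = np.floor((freqs - min_freq) / bin_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    # groups: list of (member bin indices); start one group per occupied bin
    occupied = sorted(set(idx.tolist()))
    groups = [[b] for b in occupied]
    def gcount(g):
        return int(np.isin(idx, g).sum())
    def gcenter(g):
        return min_freq + bin_width * (np.mean(g) + 0.5)
    while len(groups) > 1:
        counts = [gcount(g) for g in groups]
        small = [t for t, c in enumerate(counts) if c < min_bin_n]
        if not small:
            break
        t = min(small, key=lambda t: counts[t])
        # merge with the nearest neighbouring group
        neighbors = [u for u in (t - 1, t + 1) if 0 <= u < len(groups)]
        u = min(neighbors, key=lambda u: (abs(gcenter(groups[u]) - gcenter(groups[t])), u))
        a, b = sorted((t, u))
        groups[a] = sorted(groups[a] + groups[b])
        del groups[b]
    gid = np.empty(len(idx), dtype=int)
    for g, members in enumerate(groups):
        gid[np.isin(idx, members)] = g
    return gid


def assign_p_values(tests: pd.DataFrame, min_freq: float = 0.20,
                    bin_width: float = 0.05, method: str = "gaussian_log",
                    min_bin_n: int = 10) -> pd.DataFrame:
    """Attach a p-value to every test, binned by core-haplotype frequency.

    ``gaussian_log``: within each bin, fit mean and sd (ddof=1) of
    ln(REHH); p = upper-tail normal probability.  Bins whose ln(REHH)
    variance is zero (or with a single test) fall back to the empirical
    rank, with a log note.  ``empirical_rank``: p = (# bin values >=
    value) / bin size.
    """
    if method not in ("gaussian_log", "empirical_rank"):
        raise ValueError(f"unknown p-value method {method!r}")
    out = tests.copy()
    if out.empty:
        out["p_value"] = np.array([], dtype=float)
        out["log_rehh"] = np.array([], dtype=float)
        return out
    if (out["rehh"] <= 0).any() or out["rehh"].isna().any():
        raise ValueError("assign_p_values requires defined rehh > 0 for all tests")
    x = np.log(out["rehh"].to_numpy(dtype=float))
    out["log_rehh"] = x
    gid = _merged_bins(out["frequency"].to_numpy(dtype=float), min_freq,
                       bin_width, min_bin_n)
    out["freq_bin"] = gid
    p = np.empty(len(out), dtype=float)
    for g in np.unique(gid):
        sel = gid == g
        xs = x[sel]
        use_rank = method == "empirical_rank"
        if not use_rank:
            mu = xs.mean()
            sd = xs.std(ddof=1) if len(xs) > 1 else 0.0
            if sd == 0.0:
                logger.info("assign_p_values: zero variance in bin %d; "
                            "falling back to empirical rank", g)
                use_rank = True
            else:
                p[sel] = stats.norm.sf(xs, loc=mu, scale=sd)
        if use_rank:
            p[sel] = (xs[:, None] <= xs[None, :]).sum(axis=1) / len(xs)
    out["p_value"] = p
    return out


def call_significant(tests: pd.DataFrame, alphas=(0.05, 0.01)):
    """Strict-threshold significance calls per alpha level.

    Returns (per-alpha dict of test subsets, region flag table).  A region
    is significant at a level when any of its tests is (OR rule).
    """
    if "p_value" not in tests.columns:
        raise ValueError("call_significant requires assigned p-values")
    by_alpha = {}
    region_cols = ["region_id", "chrom", "start_bp", "end_bp"]
    flags = tests[region_cols].drop_duplicates().reset_index(drop=True)
    for alpha in alphas:
        hit = tests.loc[tests["p_value"] < alpha].reset_index(drop=True)
        by_alpha[alpha] = hit
        sig_regions = set(hit["region_id"])
        flags[f"significant_{alpha:g}"] = flags["region_id"].isin(sig_regions)
    return by_alpha, flags


def significant_regions(regions, tests: pd.DataFrame, alpha: float = 0.01):
    """CoreRegion subset whose best test beats alpha (strict)."""
    hit = set(tests.loc[tests["p_value"] < alpha, "region_id"])
    return [r for r in regions if r.region_id in hit]


def summarize_scan(panel, regions, tests: pd.DataFrame,
                   alphas=(0.05, 0.01)) -> pd.DataFrame:
    """Per-chromosome scan summary plus a totals row.

    Columns mirror a genome-scan bookkeeping table: SNP count, mean
    adjacent-marker spacing (kb), region count and length statistics (kb),
    SNPs inside regions, test count and significant-test counts per alpha.
    All statistics are recomputed from the inputs, never carried over.
    """
    rows = []
    has_p = "p_value" in tests.columns and len(tests)
    for chrom in panel.chromosomes:
        cols = panel.chrom_indices(chrom)
        pos = panel.snps["pos_bp"].to_numpy()[cols]
        spacing = (pos[-1] - pos[0]) / (len(pos) - 1) / 1e3 if len(pos) > 1 else np.nan
        regs = [r for r in regions if r.chrom == str(chrom)]
        lengths = np.array([r.length_bp for r in regs]) / 1e3
        t = tests.loc[tests["chrom"] == str(chrom)] if len(tests) else tests
        row = {
            "chrom": str(chrom),
            "n_snps": len(pos),
            "mean_spacing_kb": spacing,
            "n_regions": len(regs),
            "total_region_kb": float(lengths.sum()),
            "max_region_kb": float(lengths.max()) if len(regs) else 0.0,
            "mean_region_kb": float(lengths.mean()) if len(regs) else np.nan,
            "sd_region_kb": float(lengths.std(ddof=1)) if len(regs) > 1 else np.nan,
            "snps_in_regions": int(sum(r.n_snps for r in regs)),
            "n_tests": int(len(t)),
        }
        for alpha in alphas:
            row[f"n_sig_{alpha:g}"] = (
                int((t["p_value"] < alpha).sum()) if has_p and len(t) else 0)
        rows.append(row)
    df = pd.DataFrame(rows)
    all_len = np.array([r.length_bp for r in regions]) / 1e3
    pos_all = panel.snps["pos_bp"].to_numpy()
    gaps = []
    for chrom in panel.chromosomes:
        p = pos_all[panel.chrom_indices(chrom)]
        if len(p) > 1:
            gaps.append(np.diff(p))
    gaps = np.concatenate(gaps) if gaps else np.array([np.nan])
    total = {
        "chrom": "total",
        "n_snps": int(df["n_snps"].sum()),
        "mean_spacing_kb": float(np.mean(gaps) / 1e3),
        "n_regions": int(df["n_regions"].sum()),
        "total_region_kb": float(df["total_region_kb"].sum()),
        "max_region_kb": float(df["max_region_kb"].max()) if len(df) else 0.0,
        "mean_region_kb": float(all_len.mean()) if len(all_len) else np.nan,
        "sd_region_kb": float(all_len.std(ddof=1)) if len(all_len) > 1 else np.nan,
        "snps_in_regions": int(df["snps_in_regions"].sum()),
        "n_tests": int(df["n_tests"].sum()),
    }
    for alpha in alphas:
        total[f"n_sig_{alpha:g}"] = int(df[f"n_sig_{alpha:g}"].sum())
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
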