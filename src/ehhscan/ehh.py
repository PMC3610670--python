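"""Extended haplotype homozygosity (EHH) and relative EHH (REHH).

EHH of a core haplotype at genetic distance x is the probability that two
randomly chosen carrier chromosomes are identical over the whole interval
from the core edge out to x.  With carrier extended-haplotype groups of
sizes e_i among c carriers this is sum_i C(e_i,2) / C(c,2): groups only
split as the interval grows, so every profile starts at 1 and is
non-increasing.

REHH compares the tested core haplotype's EHH at a fixed matched genetic
distance (0.5 cM by default, suited to the long-range LD of cattle) with
the pooled EHH of all other core haplotypes of the same region at that
distance, correcting for local recombination-rate variation.  Pooled
"others" homozygosity starts from groups defined by the non-tested copies'
own core haplotypes, so groups never merge across distinct core
haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CoreHaplotype, CoreRegion
from .io import HaplotypePanel

logger = logging.getLogger(__name__)

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"


@dataclass
class EHHProfile:
    region_id: str
    haplotype: str
    direction: str
    distances_cm: np.ndarray  # from the core edge, starting at 0
    ehh: np.ndarray           # starting at 1
    c: int                    # carrier count
    reached_zero: bool        # decayed to 0 before the chromosome end

    @property
    def points(self):
        return list(zip(self.distances_cm, self.ehh))


@dataclass
class RehhValue:
    ehh_tested: float
    ehh_others: float
    rehh: float
    defined: bool
    drop_reason: str | None = None  # singleton | no_others | edge | zero_others


def _homozygosity_path(alleles, rows, cols, init_labels):
    """Homozygosity after extending group labels through successive columns.

    Returns (values, reached_zero): values[k] is the homozygosity after
    including cols[:k+1]; the walk stops early once it hits 0.
    """
    labels = np.asarray(init_labels, dtype=np.int64)
    c = len(rows)
    denom = c * (c - 1) / 2.0
    values = []
    reached_zero = False
    for col in cols:
        key = labels * 2 + alleles[rows, col]
        _, labels = np.unique(key, return_inverse=True)
        cnt = np.bincount(labels)
        h = float((cnt * (cnt - 1) // 2).sum() / denom)
        values.append(h)
        if h == 0.0:
            reached_zero = True
            break
    return np.array(values), reached_zero


def _flank_columns(panel: HaplotypePanel, region: CoreRegion, direction: str):
    """(edge column, ordered flank columns, signed step) for one direction."""
    chrom_cols = panel.chrom_indices(region.chrom)
    lo, hi = int(chrom_cols[0]), int(chrom_cols[-1])
    if direction == DOWNSTREAM:
        edge = region.snp_end_idx
        cols = np.arange(edge + 1, hi + 1)
    elif direction == UPSTREAM:
        edge = region.snp_start_idx
        cols = np.arange(edge - 1, lo - 1, -1)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return edge, cols


def _truncate_cols(cols, pos_cm, edge, max_cm):
    """Keep flank columns out to the first marker at distance >= max_cm."""
    if max_cm is None or len(cols) == 0:
        return cols
    dist = np.abs(pos_cm[cols] - pos_cm[edge])
    beyond = np.flatnonzero(dist >= max_cm)
    return cols if beyond.size == 0 else cols[: beyond[0] + 1]


def ehh_profile(panel: HaplotypePanel, region: CoreRegion, hap: CoreHaplotype,
                direction: str, max_cm: float | None = None) -> EHHProfile | None:
    """EHH decay profile of one core haplotype in one direction.

    Returns None (with a log note) for singleton haplotypes, where EHH is
    undefined.  Distances are genetic (cM), measured from the region's
    outermost core SNP in the tested direction; the profile extends to the
    chromosome end or until EHH reaches 0, whichever comes first.  With
    ``max_cm`` the walk stops at the first marker at or beyond that
    distance (enough to interpolate any target <= max_cm).
    """
    c = hap.count
    if c < 2:
        logger.debug("ehh_profile: singleton haplotype %s skipped", hap.alleles)
        return None
    edge, cols = _flank_columns(panel, region, direction)
    pos_cm = panel.snps["pos_cm"].to_numpy(dtype=float)
    if np.isnan(pos_cm[edge]):
        raise ValueError("genetic map not attached (pos_cm is NaN)")
    cols = _truncate_cols(cols, pos_cm, edge, max_cm)
    values, reached_zero = _homozygosity_path(
        panel.alleles, hap.carriers, cols, np.zeros(c, dtype=np.int64))
    k = len(values)
    dist = np.abs(pos_cm[cols[:k]] - pos_cm[edge]) if k else np.empty(0)
    return EHHProfile(
        region_id=region.region_id, haplotype=hap.alleles, direction=direction,
        distances_cm=np.concatenate([[0.0], dist]),
        ehh=np.concatenate([[1.0], values]),
        c=c, reached_zero=reached_zero,
    )


def ehh_at_distance(profile, target_cm: float = 0.5) -> float:
    """EHH at a genetic distance, linearly interpolated between markers.

    Once a profile has decayed to 0 it stays 0, so targets beyond a
    decayed profile return 0.  If the profile ends at the chromosome edge
    before reaching ``target_cm`` the value is undefined and NaN is
    returned (the caller drops the test).
    """
    if target_cm < 0:
        raise ValueError("target genetic distance must be >= 0")
    d, e = profile.distances_cm, profile.ehh
    if len(d) == 0:
        return float("nan")
    if target_cm > d[-1]:
        return 0.0 if profile.reached_zero else float("nan")
    return float(np.interp(target_cm, d, e))


def _others_profile(panel, region, hap, direction, max_cm=None):
    """Pooled-others homozygosity curve (distances, values, reached_zero).

    Non-tested copies start in groups given by their own core haplotype;
    unlike a single-haplotype EHH profile this curve does not start at 1.
    """
    mask = np.ones(panel.n_copies, dtype=bool)
    mask[hap.carriers] = False
    rows = np.flatnonzero(mask)
    if len(rows) < 2:
        return None
    init = np.empty(len(rows), dtype=np.int64)
    owner = np.empty(panel.n_copies, dtype=np.int64)
    for t, other in enumerate(region.core_haplotypes):
        owner[other.carriers] = t
    init[:] = owner[rows]
    edge, cols = _flank_columns(panel, region, direction)
    pos_cm = panel.snps["pos_cm"].to_numpy(dtype=float)
    cols = _truncate_cols(cols, pos_cm, edge, max_cm)
    # starting homozygosity over the core itself
    cnt = np.bincount(init)
    c = len(rows)
    h0 = float((cnt * (cnt - 1) // 2).sum() / (c * (c - 1) / 2.0))
    values, reached_zero = _homozygosity_path(panel.alleles, rows, cols, init)
    k = len(values)
    dist = np.abs(pos_cm[cols[:k]] - pos_cm[edge]) if k else np.empty(0)
    prof = EHHProfile(
        region_id=region.region_id, haplotype="(others)", direction=direction,
        distances_cm=np.concatenate([[0.0], dist]),
        ehh=np.concatenate([[h0], values]),
        c=c, reached_zero=reached_zero or h0 == 0.0,
    )
    if h0 == 0.0:
        # all non-tested copies are distinct already at the core
        prof.ehh = np.array([0.0])
        prof.distances_cm = np.array([0.0])
    return prof


def rehh(panel: HaplotypePanel, region: CoreRegion, hap: CoreHaplotype,
         direction: str, target_cm: float = 0.5) -> RehhValue:
    """REHH of one core haplotype in one direction at the matched distance.

    Undefined cases are flagged, never coerced: singleton tested haplotype,
    fewer than 2 non-tested copies (e.g. a frequency-1 haplotype),
    chromosome edge reached before the matched distance, or pooled-others
    EHH of exactly 0.
    """
    nan = float("nan")
    if hap.count < 2:
        return RehhValue(nan, nan, nan, False, "singleton")
    others = _others_profile(panel, region, hap, direction, max_cm=target_cm)
    if others is None:
        return RehhValue(nan, nan, nan, False, "no_others")
    tested = ehh_profile(panel, region, hap, direction, max_cm=target_cm)
    e_t = ehh_at_distance(tested, target_cm)
    e_o = ehh_at_distance(others, target_cm)
    if np.isnan(e_t) or np.isnan(e_o):
        return RehhValue(e_t, e_o, nan, False, "edge")
    if e_o == 0.0:
        return RehhValue(e_t, e_o, nan, False, "zero_others")
    return RehhValue(e_t, e_o, e_t / e_o, True, None)


def all_rehh_tests(panel: HaplotypePanel, regions, target_cm: float = 0.5
                   ) -> pd.DataFrame:
    """One REHH test per (core haplotype x direction) over all regions.

    Returns a tidy DataFrame (one row per test) including dropped tests
    with their drop_reason; downstream significance assignment works on
    the defined subset.
    """
    rows = []
    for region in regions:
        for hap in region.core_haplotypes:
            for direction in (UPSTREAM, DOWNSTREAM):
                rv = rehh(panel, region, hap, direction, target_cm)
                rows.append({
                    "region_id": region.region_id,
                    "chrom": region.chrom,
                    "start_bp": region.start_bp,
                    "end_bp": region.end_bp,
                    "haplotype": hap.alleles,
                    "frequency": hap.frequency,
                    "direction": direction,
                    "ehh_tested": rv.ehh_tested,
                    "ehh_others": rv.ehh_others,
                    "rehh": rv.rehh,
                    "defined": rv.defined,
                    "drop_reason": rv.drop_reason or "",
                })
    df = pd.DataFrame(rows, columns=[
        "region_id", "chrom", "start_bp", "end_bp", "haplotype", "frequency",
        "direction", "ehh_tested", "ehh_others", "rehh", "defined",
        "drop_reason"])
    if len(df):
        dropped = (~df["defined"]).sum()
        logger.info("all_rehh_tests: %d tests, %d dropped (%s)", len(df), dropped,
                    df.loc[~df["defined"], "drop_reason"].value_counts().to_dict())
    return df


def profiles_table(profiles) -> pd.DataFrame:
    """Long-form (region, haplotype, direction, pos_cm, ehh) table for plotting."""
    rows = []
    for p in profiles:
        if p is None:
            continue
        for d, e in zip(p.distances_cm, p.ehh):
            rows.append((p.region_id, p.haplotype, p.direction, d, e))
    return pd.DataFrame(rows, columns=["region_id", "haplotype", "direction",
                                       "pos_cm", "ehh"])
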