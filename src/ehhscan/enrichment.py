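"""Region extension, gene mapping and hypergeometric gene-set enrichment.

Significant core regions are padded (1 Mb to each side by default) to form
annotation target regions; genes overlapping a target region by at least
1 bp (half-open intervals) form the study set.  Per term, enrichment is
the upper-tail hypergeometric probability of drawing at least the observed
number of term genes in a study-set-sized draw from the background
universe, Bonferroni-corrected over the number of terms actually tested
(GeneMerge semantics).  The ratio reported per term is
(study_count/study_total) / (pop_count/pop_total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ExtendedRegion:
    region_id: str
    chrom: str
    start_bp: int
    end_bp: int


def extend_regions(regions, pad_bp: int = 1_000_000, chrom_lengths=None,
                   merge: bool = True):
    """Pad regions by ``pad_bp`` on both sides, clamped to the chromosome.

    ``regions`` is anything with chrom/start_bp/end_bp/region_id (e.g.
    CoreRegion objects or a BED-like DataFrame).  ``chrom_lengths`` maps
    chromosome label -> length bp; required for right-clamping.  With
    ``merge`` (default), overlapping extended regions on one chromosome
    are unioned so downstream gene counting counts each gene once.
    """
    if chrom_lengths is None:
        raise ValueError("chrom_lengths required (config or inferred from last SNP)")
    recs = []
    if isinstance(regions, pd.DataFrame):
        it = regions.itertuples(index=False)
        recs = [(str(r.chrom), int(r.start_bp), int(r.end_bp), str(r.region_id))
                for r in it]
    else:
        recs = [(str(r.chrom), int(r.start_bp), int(r.end_bp), str(r.region_id))
                for r in regions]
    out = []
    for chrom, start, end, rid in recs:
        if chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r} (no length supplied)")
        L = int(chrom_lengths[chrom])
        out.append(ExtendedRegion(rid, chrom, max(0, start - pad_bp),
                                  min(L, end + pad_bp)))
    if not merge:
        return sorted(out, key=lambda r: (r.chrom, r.start_bp))
    merged = []
    by_chrom: dict = {}
    for r in out:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: r.start_bp)
        cur = rs[0]
        cur_ids = [cur.region_id]
        for r in rs[1:]:
            if r.start_bp <= cur.end_bp:  # overlap or abut
                cur = ExtendedRegion(cur.region_id, chrom, cur.start_bp,
                                     max(cur.end_bp, r.end_bp))
                cur_ids.append(r.region_id)
            else:
                merged.append(ExtendedRegion(",".join(cur_ids), chrom,
                                             cur.start_bp, cur.end_bp))
                cur, cur_ids = r, [r.region_id]
        merged.append(ExtendedRegion(",".join(cur_ids), chrom,
                                     cur.start_bp, cur.end_bp))
    return merged


def map_genes(extended, genes: pd.DataFrame) -> set:
    """Genes overlapping any extended region by >= 1 bp (half-open intervals).

    Each gene is counted once regardless of how many regions it touches.
    """
    trees: dict = {}
    for r in extended:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start_bp, r.end_bp)
    study = set()
    for row in genes.itertuples(index=False):
        tree = trees.get(str(row.chrom))
        if tree is not None and tree.overlap(int(row.start_bp), int(row.end_bp)):
            study.add(str(row.gene_id))
    return study


def enrichment_ratio(pop_count: int, pop_total: int, study_count: int,
                     study_total: int) -> float:
    """(study_count/study_total) / (pop_count/pop_total)."""
    return (study_count / study_total) / (pop_count / pop_total)


def hypergeometric_enrichment(study: set, background: set, terms: dict,
                              descriptions: dict | None = None,
                              min_study_hits: int = 1,
                              bonferroni: str = "tested") -> pd.DataFrame:
    """Per-term hypergeometric upper-tail enrichment with Bonferroni control.

    p_raw(term) = P(X >= study_count) with X ~ Hypergeometric(pop_total,
    pop_count, study_total).  The Bonferroni multiplier is the number of
    terms with at least ``min_study_hits`` study genes (``bonferroni=
    "tested"``, GeneMerge semantics) or the number of terms in the map
    (``"all"``).  Results are sorted by raw p, term id on ties.
    """
    study = {str(g) for g in study}
    background = {str(g) for g in background}
    if not study <= background:
        extra = sorted(study - background)[:5]
        raise ValueError(f"study genes missing from background, e.g. {extra}")
    if bonferroni not in ("tested", "all"):
        raise ValueError("bonferroni must be 'tested' or 'all'")
    pop_total = len(background)
    study_total = len(study)
    rows = []
    for term_id in sorted(terms):
        term_genes = {str(g) for g in terms[term_id]} & background
        pop_count = len(term_genes)
        study_count = len(term_genes & study)
        if pop_count == 0 or study_count < min_study_hits:
            continue
        p_raw = float(stats.hypergeom.sf(study_count - 1, pop_total, pop_count,
                                         study_total))
        rows.append({
            "term_id": term_id,
            "description": (descriptions or {}).get(term_id, ""),
            "pop_count": pop_count, "pop_total": pop_total,
            "study_count": study_count, "study_total": study_total,
            "ratio": enrichment_ratio(pop_count, pop_total, study_count,
                                      study_total),
            "p_raw": p_raw,
        })
    df = pd.DataFrame(rows, columns=["term_id", "description", "pop_count",
                                     "pop_total", "study_count", "study_total",
                                     "ratio", "p_raw"])
    n_tests = len(df) if bonferroni == "tested" else len(terms)
    df["p_bonferroni"] = np.minimum(1.0, df["p_raw"] * max(n_tests, 1))
    df = df.sort_values(["p_raw", "term_id"], kind="mergesort").reset_index(drop=True)
    logger.info("hypergeometric_enrichment: %d terms tested (of %d in map)",
                len(df), len(terms))
    return df


def intersect_gene_lists(study: set, reference) -> dict:
    """Case-normalized symbol intersection of a study set with a reference list.

    Returns overlap count, percentage of the reference recovered, and the
    sorted member list.
    """
    s = {str(g).upper() for g in study}
    ref = [str(g).upper() for g in reference]
    ref_set = set(ref)
    members = sorted(s & ref_set)
    n = len(members)
    return {
        "n_overlap": n,
        "n_reference": len(ref_set),
        "fraction_of_reference_pct": 100.0 * n / len(ref_set) if ref_set else 0.0,
        "members": members,
    }
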