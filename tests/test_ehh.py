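import numpy as np
import pytest

from ehhscan import core, ehh, simulate
from conftest import make_panel, random_panel, pairwise_identity_fraction


def _region_over(panel, i, j):
    pos = panel.snps["pos_bp"].to_numpy()
    r = core.CoreRegion(f"r{i}-{j}", "1", i, j, int(pos[i]), int(pos[j]) + 1,
                        j - i + 1)
    r.core_haplotypes = core.enumerate_core_haplotypes(panel, r)
    return r


def test_profile_starts_at_one_and_groups_split_2_1_1():
    """4 carriers whose extensions split into groups 2/1/1 give
    EHH = C(2,2)/C(4,2) = 1/6 at that marker."""
    #        core  f1  f2
    a = np.array([
        [1, 0, 0],
        [1, 0, 0],
        [1, 0, 1],
        [1, 1, 0],
        [0, 0, 0],
        [0, 1, 1],
    ], dtype=np.uint8)
    panel = make_panel(a)
    region = _region_over(panel, 0, 0)
    hap = next(h for h in region.core_haplotypes if h.alleles == "1")
    prof = ehh.ehh_profile(panel, region, hap, ehh.DOWNSTREAM)
    assert prof.ehh[0] == 1.0 and prof.distances_cm[0] == 0.0
    # after f1: groups {0,1,2}/{3} -> (3+0)/6; after f2: {0,1}/{2}/{3} -> 1/6
    assert prof.ehh[1] == pytest.approx(3 / 6)
    assert prof.ehh[2] == pytest.approx(1 / 6)


def test_identical_carriers_hold_ehh_at_one():
    a = np.vstack([np.tile([1, 0, 1, 1, 0], (4, 1)),
                   np.array([[0, 1, 0, 1, 1], [0, 0, 1, 0, 1]] * 2)]
                  ).astype(np.uint8)
    panel = make_panel(a)
    region = _region_over(panel, 0, 0)
    hap = next(h for h in region.core_haplotypes if h.carriers.tolist() == [0, 1, 2, 3])
    prof = ehh.ehh_profile(panel, region, hap, ehh.DOWNSTREAM)
    assert np.all(prof.ehh == 1.0)


def test_singleton_haplotype_skipped():
    a = np.array([[1, 0], [0, 0], [0, 1], [0, 1]], dtype=np.uint8)
    panel = make_panel(a)
    region = _region_over(panel, 0, 0)
    singleton = next(h for h in region.core_haplotypes if h.count == 1)
    assert ehh.ehh_profile(panel, region, singleton, ehh.DOWNSTREAM) is None
    rv = ehh.rehh(panel, region, singleton, ehh.DOWNSTREAM)
    assert not rv.defined and rv.drop_reason == "singleton"


def test_group_count_equals_pairwise_oracle(rng):
    """Group-count formula == direct pairwise-IBS enumeration on random
    small panels, at every profile point."""
    for _ in range(30):
        h = int(rng.integers(3, 16)) * 2
        s = int(rng.integers(4, 12))
        panel = random_panel(rng, h, s)
        i = int(rng.integers(0, s - 1))
        region = _region_over(panel, i, i)
        for hap in region.core_haplotypes:
            if hap.count < 2:
                continue
            prof = ehh.ehh_profile(panel, region, hap, ehh.DOWNSTREAM)
            cols = np.arange(i + 1, i + len(prof.ehh))
            for k, val in enumerate(prof.ehh[1:], start=1):
                oracle = pairwise_identity_fraction(panel.alleles, hap.carriers,
                                                    cols[:k])
                assert val == pytest.approx(oracle)


def test_profiles_non_increasing_and_symmetric(rng):
    """Monotone decay; reversing SNP order swaps upstream/downstream."""
    panel = random_panel(rng, 20, 10)
    rev = make_panel(panel.alleles[:, ::-1])
    for i in range(3, 7):
        region = _region_over(panel, i, i)
        region_rev = _region_over(rev, panel.n_snps - 1 - i, panel.n_snps - 1 - i)
        for hap in region.core_haplotypes:
            if hap.count < 2:
                continue
            down = ehh.ehh_profile(panel, region, hap, ehh.DOWNSTREAM)
            assert np.all(np.diff(down.ehh) <= 0)
            hap_rev = next(h for h in region_rev.core_haplotypes
                           if h.alleles == hap.alleles)
            up_rev = ehh.ehh_profile(rev, region_rev, hap_rev, ehh.UPSTREAM)
            np.testing.assert_allclose(up_rev.ehh, down.ehh)


def test_ehh_at_distance_interpolation():
    prof = ehh.EHHProfile("r", "1", ehh.DOWNSTREAM,
                          np.array([0.0, 0.4, 0.6]), np.array([1.0, 0.8, 0.4]),
                          c=4, reached_zero=False)
    assert ehh.ehh_at_distance(prof, 0.5) == pytest.approx(0.6)
    assert ehh.ehh_at_distance(prof, 0.4) == pytest.approx(0.8)  # at a marker
    with pytest.raises(ValueError):
        ehh.ehh_at_distance(prof, -0.1)


def test_ehh_at_distance_edge_and_zero_rules():
    short = ehh.EHHProfile("r", "1", ehh.DOWNSTREAM,
                           np.array([0.0, 0.3]), np.array([1.0, 0.7]),
                           c=4, reached_zero=False)
    assert np.isnan(ehh.ehh_at_distance(short, 0.5))  # chromosome edge
    decayed = ehh.EHHProfile("r", "1", ehh.DOWNSTREAM,
                             np.array([0.0, 0.3]), np.array([1.0, 0.0]),
                             c=4, reached_zero=True)
    assert ehh.ehh_at_distance(decayed, 0.5) == 0.0  # stays at zero


def test_rehh_ratio_and_identical_decay():
    """Tested haplotype decaying identically to the pooled rest -> REHH = 1."""
    # core column splits copies 4/4; both groups stay internally identical
    a = np.array([[1, 0, 1]] * 4 + [[0, 1, 0]] * 4, dtype=np.uint8)
    panel = make_panel(a)
    region = _region_over(panel, 0, 0)
    for hap in region.core_haplotypes:
        rv = ehh.rehh(panel, region, hap, ehh.DOWNSTREAM, target_cm=0.05)
        assert rv.defined and rv.rehh == pytest.approx(1.0)


def test_rehh_frequency_one_flagged_not_infinite():
    a = np.hstack([np.ones((6, 1), dtype=np.uint8),
                   np.array([[0], [1]] * 3, dtype=np.uint8)])
    panel = make_panel(a)
    region = _region_over(panel, 0, 0)
    (hap,) = region.core_haplotypes
    rv = ehh.rehh(panel, region, hap, ehh.DOWNSTREAM)
    assert not rv.defined and rv.drop_reason == "no_others"
    assert np.isnan(rv.rehh)


def test_planted_sweep_has_top_rehh_in_its_region(rng):
    """The swept core haplotype beats every other haplotype of its region,
    verified by exhaustive per-haplotype REHH."""
    cfg = simulate.SimulationConfig(n_copies=200, n_snps=400, seed=7)
    panel = simulate.simulate_neutral_panel(cfg)
    pos = panel.snps["pos_bp"].to_numpy()
    panel, truth = simulate.plant_sweep(panel, int(pos[200]), 0.4, 1.0, seed=8)
    lo, hi = truth.sweep_tract_bp
    carriers = set(truth.sweep_carriers.tolist())
    regions = [r for r in core.detect_core_regions(panel)
               if lo <= r.start_bp and r.end_bp <= hi and r.n_snps >= 3]
    # pick a region well inside the tract; the sweep haplotype is the one
    # whose carriers include the planted carrier set
    region = min(regions, key=lambda r: abs((r.start_bp + r.end_bp) / 2
                                            - (lo + hi) / 2))
    swept = next(h for h in region.core_haplotypes
                 if carriers <= set(h.carriers.tolist()))
    values = {}
    for hap in region.core_haplotypes:
        for direction in (ehh.UPSTREAM, ehh.DOWNSTREAM):
            rv = ehh.rehh(panel, region, hap, direction)
            if rv.defined:
                values[(hap.alleles, direction)] = rv.rehh
    swept_best = max(v for (h, d), v in values.items() if h == swept.alleles)
    others_best = max((v for (h, d), v in values.items() if h != swept.alleles),
                      default=0.0)
    assert swept_best > others_best


def test_all_rehh_tests_counts_and_drop_reasons(rng):
    panel = random_panel(rng, 30, 12)
    regions = core.detect_core_regions(panel, min_core_snps=2)
    tests = ehh.all_rehh_tests(panel, regions)
    n_haps = sum(len(r.core_haplotypes) for r in regions)
    assert len(tests) == 2 * n_haps  # one test per (haplotype x direction)
    assert set(tests.loc[~tests["defined"], "drop_reason"]) <= {
        "singleton", "no_others", "edge", "zero_others"}
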