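import itertools

import numpy as np
import pandas as pd
import pytest

from ehhscan.io import HaplotypePanel


def make_panel(alleles, positions=None, chrom="1", rate_cm_per_mb=1.0,
               spacing_bp=50_000):
    """Panel from a 0/1 matrix; default equally spaced markers, 1 cM/Mb."""
    a = np.asarray(alleles, dtype=np.uint8)
    h, s = a.shape
    pos = (np.asarray(positions, dtype=np.int64) if positions is not None
           else np.arange(s, dtype=np.int64) * spacing_bp + 10_000)
    snps = pd.DataFrame({
        "id": [f"m{i}" for i in range(s)],
        "chrom": chrom,
        "pos_bp": pos,
        "pos_cm": pos * rate_cm_per_mb / 1e6,
        "ref": "A",
        "alt": "G",
    })
    return HaplotypePanel(alleles=a, snps=snps)


def random_panel(rng, h, s, **kw):
    """Random polymorphic panel (every column segregating)."""
    while True:
        a = (rng.random((h, s)) < rng.uniform(0.15, 0.85, size=s)).astype(np.uint8)
        col = a.mean(axis=0)
        if np.all((col > 0) & (col < 1)):
            return make_panel(a, **kw)


def pairwise_identity_fraction(alleles, rows, cols):
    """Brute-force oracle: fraction of row pairs identical over cols."""
    rows = list(rows)
    if len(rows) < 2:
        raise ValueError("need >= 2 rows")
    same = 0
    pairs = 0
    for i, j in itertools.combinations(rows, 2):
        pairs += 1
        if len(cols) == 0 or np.array_equal(alleles[i, cols], alleles[j, cols]):
            same += 1
    return same / pairs


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
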