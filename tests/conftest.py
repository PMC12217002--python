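import numpy as np
import pandas as pd
import pytest

from drugmr.instruments import HarmonizedSet
from drugmr.sumstats import GeneRegion


def make_harmonized(bx, sx, by, sy, **kw):
    """Build a HarmonizedSet directly from effect arrays (non-palindromic
    alleles, consecutive positions)."""
    bx, sx, by, sy = (np.asarray(a, dtype=float) for a in (bx, sx, by, sy))
    n = len(bx)
    t = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n)],
        "chrom": "1", "pos": np.arange(n) + 1,
        "effect_allele": "A", "other_allele": "G",
        "beta_exp": bx, "se_exp": sx, "pval_exp": np.full(n, 1e-10),
        "beta_out": by, "se_out": sy,
        "eaf_exp": np.full(n, 0.3), "eaf_out": np.full(n, 0.3),
    })
    return HarmonizedSet(kw.get("exposure_id", "exp"),
                         kw.get("outcome_id", "out"), t)


def random_valid_instruments(rng, n=30, theta=0.5):
    """Strong, independent instruments with outcome noise only."""
    bx = rng.uniform(0.05, 0.15, n)
    sx = np.full(n, 0.002)
    sy = rng.uniform(0.03, 0.08, n)
    by = theta * bx + sy * rng.standard_normal(n)
    return make_harmonized(bx + sx * rng.standard_normal(n), sx, by, sy)


@pytest.fixture
def synth_region():
    return GeneRegion("SYNTH", "1", 10_000_000, 10_030_000)
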