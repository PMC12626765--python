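import numpy as np
import pandas as pd
import pytest

from mrmediate import SumStats, TriadModel, simulate_triad


def make_instruments(seed: int, j: int, slope: float = 0.4,
                     intercept: float = 0.0, noise: float = 1.0) -> pd.DataFrame:
    """Random harmonized instrument table with by = a + b*bx + N(0, sy*noise)."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.05, 0.4, j) * rng.choice([-1.0, 1.0], j)
    sx = rng.uniform(0.005, 0.02, j)
    sy = rng.uniform(0.02, 0.1, j)
    by = intercept + slope * bx + noise * sy * rng.standard_normal(j)
    return pd.DataFrame({
        "variant_id": [f"sv{i}" for i in range(j)],
        "bx": bx, "sx": sx, "by": by, "sy": sy,
    })


def sumstats_from_rows(rows, trait_name="t", trait_type="continuous") -> SumStats:
    """Build a SumStats from (variant_id, chr, pos, ea, oa, eaf, beta, se, pval, n)."""
    cols = ["variant_id", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]
    return SumStats(trait_name, trait_type, pd.DataFrame(rows, columns=cols))


@pytest.fixture(scope="session")
def triad():
    """One deterministic simulated exposure/mediator/outcome triad."""
    return simulate_triad(TriadModel(seed=7))


@pytest.fixture()
def instruments20():
    return make_instruments(seed=20, j=20)
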