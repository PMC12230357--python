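import numpy as np
import pandas as pd
import pytest

from mrpath.instruments import HarmonizedSet
from mrpath.sumstats import SummaryStats


def make_sumstats(trait_id, rows):
    """SummaryStats from a list of dicts; fills eaf/n with NaN if absent."""
    df = pd.DataFrame(rows)
    for col in ("eaf", "n"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]]
    df["snp"] = df["snp"].str.lower()
    return SummaryStats(trait_id, df)


def make_harmonized(bx, sy, by, sx=None, n_exp=np.nan, n_out=np.nan, eaf=None):
    """HarmonizedSet straight from effect arrays (all rows kept)."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    eaf = np.full_like(bx, 0.3) if eaf is None else np.asarray(eaf, float)
    df = pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(len(bx))],
            "beta_exp": bx,
            "se_exp": sx,
            "beta_out": by,
            "se_out": sy,
            "eaf_exp": eaf,
            "eaf_out": eaf,
            "n_exp": float(n_exp),
            "n_out": float(n_out),
            "action": "kept",
        }
    )
    return HarmonizedSet("exp", "out", df)


@pytest.fixture
def harmonized_factory():
    return make_harmonized


@pytest.fixture
def sumstats_factory():
    return make_sumstats


def random_harmonized(rng, n=10, beta=0.5):
    """Random well-behaved instrument set with true slope ``beta``."""
    bx = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    sy = rng.uniform(0.005, 0.05, n)
    by = beta * bx + rng.normal(0, sy)
    return make_harmonized(bx, sy, by)
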