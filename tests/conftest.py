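import numpy as np
import pandas as pd
import pytest

from leukdriver import synthetic_cohort as sc

COVARIATES = ["gc", "rep_timing", "coverage", "log_length"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small null cohort shared by read-only tests."""
    cfg = sc.CohortConfig(n_samples=40, n_regions=200, seed=99)
    return sc.generate_cohort(cfg)


def enumerate_poisson_binomial(p):
    """Brute-force Poisson-binomial PMF by summing over all 2^n outcomes."""
    p = np.asarray(p, dtype=float)
    n = p.size
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    probs = np.prod(np.where(masks == 1, p, 1 - p), axis=1)
    return np.bincount(masks.sum(axis=1), weights=probs, minlength=n + 1)


def make_segments(states, lengths=None, contig_prefix="chr"):
    """One whole-contig segment per state, for chromosome-count fixtures."""
    if lengths is None:
        lengths = [1_000_000] * len(states)
    rows = []
    for i, (s, ln) in enumerate(zip(states, lengths)):
        rows.append(
            {"contig": f"{contig_prefix}{i + 1}", "start": 1, "end": ln, "state": s}
        )
    return pd.DataFrame(rows)
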