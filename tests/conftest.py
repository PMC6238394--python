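import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_domain():
    """One 1 Mb chromosome fully annotated as BLACK."""
    chrom_sizes = {"chr2L": 1_000_000}
    domains = pd.DataFrame(
        [("chr2L", 0, 1_000_000, "BLACK")],
        columns=["chrom", "start", "end", "state"],
    )
    return chrom_sizes, domains


def brute_force_autocorrelation(x, max_lag):
    """Direct-summation oracle for the lag-0-normalised autocovariance.

    O(n * L): one explicit pass per lag, independent of the FFT path.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    xc = x - mu
    denom = np.sum(xc * xc)
    r = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        r[k] = np.sum(xc[: len(x) - k] * xc[k:]) / denom
    return r
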