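"""Shared fixtures: synthetic studies at the sizes used across the suite."""

import numpy as np
import pandas as pd
import pytest

from beadvar.simulate import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """Full default study: nested batches, planted fractions, SNP effects."""
    return generate_study(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def chip_only_study():
    """Only the chip factor planted (0.30) - the recovery benchmark."""
    cfg = SimulationConfig(seed=11, variance_fractions={"chip": 0.30},
                           n_mismatch_probes=0, n_null_in_probe_snps=0)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def noise_only_study():
    """No log-scale signal: raw-scale noise sd = 0.1*mean + 5 only."""
    cfg = SimulationConfig(seed=4, signal_log_sd=0.0, variance_fractions={},
                           n_mismatch_probes=0, n_null_in_probe_snps=0,
                           noise_c1=0.1, noise_c2=5.0, expressed_fraction=1.0,
                           baseline_range=(6.0, 14.0))
    return generate_study(cfg)


def ols_oracle(X: np.ndarray, y: np.ndarray):
    """Brute-force normal-equations OLS: beta, se, two-sided t p-values.

    Independent of the package's fitting path on purpose.
    """
    from scipy import stats

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, p


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
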