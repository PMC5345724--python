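import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import oathgwas as og

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def ols_oracle(y, x, Z, subset, with_intercept_df=True):
    """Independent least-squares oracle on individual-level data.

    Fits y ~ 1 + x + Z[:, subset] by normal equations and returns
    (beta, se) for [x, covariates].  ``with_intercept_df=False`` uses
    df = n - k - 1 (predictors only), matching the default reconstruction
    convention.
    """
    n = y.size
    cols = [np.ones(n), x] + [Z[:, i - 1] for i in subset]
    X = np.column_stack(cols)
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    k = len(subset)
    df = n - X.shape[1] if with_intercept_df else n - k - 1
    s2 = resid @ resid / df
    se = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
    return b[1:], se[1:]


@pytest.fixture
def small_dataset():
    """n=80 individual-level dataset with 3 covariates and one tested locus."""
    rng = np.random.default_rng(42)
    n, m = 80, 3
    Z = rng.normal(size=(n, m))
    x = rng.binomial(2, 0.3, size=n).astype(float)
    y = 0.4 * x + Z @ np.array([0.3, -0.2, 0.1]) + rng.normal(size=n)
    return y, x, Z


@pytest.fixture
def encoded(small_dataset):
    y, x, Z = small_dataset
    generic = og.encode_generic(y, Z)
    locus = og.encode_locus(x, y, Z, snp_id="rs1", chrom="1", pos=100,
                            a1="A", a2="G")
    return generic, locus


@pytest.fixture
def worked_phi():
    return og.worked_example_phi()
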