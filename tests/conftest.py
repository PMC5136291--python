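import numpy as np
import pytest

from pathkat.synthgen import SimSpec, generate_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A small default-condition bundle shared across read-only tests."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(SimSpec(seed=3), out)


@pytest.fixture(scope="session")
def bundle_missing(tmp_path_factory):
    """Bundle with missing genotype calls, for round-trip tests."""
    out = tmp_path_factory.mktemp("bundle_missing")
    return generate_bundle(SimSpec(seed=5, missing_fraction=0.03), out)


def make_design(n, k_cov, rng):
    """Intercept + standard-normal covariates."""
    return np.column_stack([np.ones(n), rng.standard_normal((n, k_cov))])


def make_genotypes(n, mafs, rng):
    return rng.binomial(2, np.asarray(mafs)[None, :], size=(n, len(mafs))).astype(float)
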