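import warnings

import pytest

from rtdkit.io import read_genome, read_gtf
from rtdkit.simulate import FixtureSpec, generate


@pytest.fixture(scope="session")
def fixture_truth(tmp_path_factory):
    """A medium synthetic dataset shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("fixture")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        truth = generate(FixtureSpec(seed=11, n_genes=30), outdir)
    return truth


@pytest.fixture(scope="session")
def fixture_genome(fixture_truth):
    return read_genome(fixture_truth.paths["genome"])


@pytest.fixture(scope="session")
def fixture_assembly(fixture_truth):
    return read_gtf(fixture_truth.paths["assembly"])


@pytest.fixture(scope="session")
def fixture_reference(fixture_truth):
    return read_gtf(fixture_truth.paths["reference"])
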