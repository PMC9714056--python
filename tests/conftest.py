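import numpy as np
import pytest

from amyhex import (
    DescriptorConfig,
    FixtureSpec,
    SplitSpec,
    extract_all,
    gen_labelled_fixture,
    load_tables,
    make_split,
)


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def config():
    return DescriptorConfig()


@pytest.fixture(scope="session")
def random_hexapeptides():
    """20 random hexapeptides for oracle comparisons."""
    from amyhex.fixtures import gen_random_peptides

    return [r.sequence for r in gen_random_peptides(20, 6, seed=99)]


@pytest.fixture(scope="session")
def small_features(tables):
    """Features of a small noise-free fixture (30/class train, 15/class test)."""
    fx = gen_labelled_fixture(FixtureSpec(n_per_class=45, seed=3))
    train, test = make_split(fx, SplitSpec(30, 15, seed=4))
    return extract_all(train, None, tables), extract_all(test, None, tables)
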