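import warnings

import pytest

from lipidflex import (
    condense,
    default_config,
    generate,
    make_qc_fixture,
    normalize_mol_percent,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One full study-design dataset (240 study samples, 10 sample types)."""
    return generate(default_config(seed=11))


@pytest.fixture(scope="session")
def study_features(default_dataset):
    matrix, _ = default_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        molpct = normalize_mol_percent(matrix.subset(roles=("study",)))
        return condense(molpct)


@pytest.fixture()
def qc_fixture():
    return make_qc_fixture(seed=5)
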