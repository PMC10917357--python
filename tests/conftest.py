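import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from clirms import chem, digest, search, simulate  # noqa: E402


@pytest.fixture(scope="session")
def toy_proteins():
    return [simulate.toy_protein()]


@pytest.fixture(scope="session")
def toy_rna():
    return simulate.toy_rna()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """A clean 48-doublet simulation of the built-in scenario."""
    proteins, rna, ds = simulate.default_scenario(n_pairs=48, seed=11)
    return proteins, rna, ds


@pytest.fixture(scope="session")
def search_space(toy_proteins):
    """Target + decoy precursor candidates for the toy protein."""
    peptides = digest.digest_protein(
        toy_proteins[0], max_missed=2, length_range=(1, 60)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        decoys = search.build_decoys(peptides)
    candidates = digest.generate_candidates(
        peptides + decoys, digest.enumerate_compositions(4)
    )
    return peptides, decoys, candidates


@pytest.fixture(scope="session")
def scheme():
    return chem.LabelScheme.full_13c15n()
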