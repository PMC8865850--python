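import numpy as np
import pytest

from pearkit import AmpliconSpec, EditSpec, make_demo_amplicon


@pytest.fixture(scope="session")
def sub_amplicon() -> AmpliconSpec:
    """Substitution-edit amplicon (splice-donor fix) used across tests."""
    return make_demo_amplicon(seed=11, edit_kind="substitution")


@pytest.fixture(scope="session")
def ins_amplicon() -> AmpliconSpec:
    return make_demo_amplicon(seed=12, edit_kind="insertion")


@pytest.fixture(scope="session")
def del_amplicon() -> AmpliconSpec:
    return make_demo_amplicon(seed=13, edit_kind="deletion")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
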