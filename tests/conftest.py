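import numpy as np
import pytest

from haini.chem_features import DescriptorVector, default_provider
from haini.cyp_features import CYPProfile
from haini.data_io import DrugRecord


@pytest.fixture(scope="session")
def provider():
    return default_provider()


@pytest.fixture
def toy_vectors():
    """Two tiny aligned descriptor vectors for operator arithmetic."""
    fa = DescriptorVector("A", ("x", "y"), np.array([2.0, 3.0]))
    fb = DescriptorVector("B", ("x", "y"), np.array([5.0, 7.0]))
    return fa, fb


@pytest.fixture
def tiny_drugs():
    """Handful of real molecules with assorted CYP profiles."""
    return [
        DrugRecord("aspirin-like", "CC(=O)Oc1ccccc1C(=O)O",
                   CYPProfile("aspirin-like", frozenset({"1A2", "3A4"}))),
        DrugRecord("aniline-like", "Nc1ccc(Cl)cc1",
                   CYPProfile("aniline-like", frozenset(),
                              frozenset({"2B6", "2C8"}), frozenset({"2D6", "3A4"}))),
        DrugRecord("ether", "CCOc1ccc(CC)cc1",
                   CYPProfile("ether", frozenset({"2C9"}), frozenset({"1A2"}))),
        DrugRecord("amine", "CCN(C)Cc1ccc(F)cc1",
                   CYPProfile("amine", frozenset({"2D6"}), frozenset(),
                              frozenset({"2C19"}))),
    ]
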