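import numpy as np
import pytest

from legumepep import (
    BioactiveFragment,
    BioactiveFragmentDB,
    load_identified_peptides,
    load_screening_reference,
)
from legumepep.digestion import load_enzyme_rules


@pytest.fixture(scope="session")
def enzyme_rules():
    return load_enzyme_rules()


@pytest.fixture(scope="session")
def screening_reference():
    return load_screening_reference()


@pytest.fixture(scope="session")
def identified_peptides():
    return load_identified_peptides()


@pytest.fixture
def tiny_db():
    """Small hand-built database with one EC50-bearing record."""
    return BioactiveFragmentDB(
        [
            BioactiveFragment("PR", "ACE inhibitor", ec50_uM=4.0),
            BioactiveFragment("EE", "stimulating"),
            BioactiveFragment("EEE", "stimulating"),
            BioactiveFragment("G", "antioxidant"),
        ]
    )


def random_protein_string(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
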