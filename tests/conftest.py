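from importlib import resources

import pytest

from idrscape.io import read_fasta
from idrscape.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def reference_records():
    """The bundled FMRP/SAM68 worked-example sequences."""
    path = resources.files("idrscape.data").joinpath(
        "reference_sequences_synthetic.fasta"
    )
    return {r.id: r for r in read_fasta(str(path))}


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fully reproducible synthetic cohort shared across tests."""
    return generate_cohort(CohortSpec(n_readers=25, n_enzymes=25, seed=42))
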