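import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from spcpipe.design import StudyDesign
from spcpipe.simulate import generate_protein_db

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design():
    """Default 6/9/9 Control/Sepsis/Recovery cohort with pairing."""
    return StudyDesign.default()


@pytest.fixture(scope="session")
def two_group_design():
    return StudyDesign(
        samples={"Control": ("C1", "C2", "C3"), "Case": ("K1", "K2", "K3", "K4")}
    )


@pytest.fixture(scope="session")
def small_db():
    return generate_protein_db(60, mean_length=80, seed=11)


def random_peptide_map(rng, max_proteins=12, max_peptides=20):
    """Random peptide->protein instance with realistic sparse sharing:
    most peptides proteotypic, a minority shared by 2-4 proteins."""
    n_prot = int(rng.integers(2, max_proteins + 1))
    n_pep = int(rng.integers(2, max_peptides + 1))
    out = {}
    for j in range(n_pep):
        m = min(int(rng.choice([1, 2, 3, 4], p=[0.6, 0.25, 0.1, 0.05])), n_prot)
        out[f"pep{j}"] = {f"pr{x}" for x in rng.choice(n_prot, m, replace=False)}
    return out


def toy_matrix(rng, n_rows=12, samples=("C1", "C2", "C3", "K1", "K2", "K3")):
    counts = pd.DataFrame(
        rng.integers(0, 40, size=(n_rows, len(samples))),
        index=[f"P{i:03d}" for i in range(n_rows)],
        columns=list(samples),
    )
    lengths = pd.Series(rng.integers(50, 400, n_rows), index=counts.index)
    return counts, lengths
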