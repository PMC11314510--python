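import numpy as np
import pandas as pd
import pytest

from bryorisk.cohort import CohortConfig, generate_cohort


@pytest.fixture()
def tiny_csv(tmp_path):
    """Three-species trait CSV covering EN / LC / DD and missing cells."""
    text = (
        "species,iucn_category,Plant sex,Sporophyte presence,"
        "Vegetative reproduction,Seta length,Substrate breadth\n"
        "Bryum alpha,EN,dioicous,present,present,12.5,rock|soil\n"
        "Bryum beta,LC,monoicous,,present,4-8,4\n"
        "Bryum gamma,DD,dioicous,absent,,,1\n"
    )
    path = tmp_path / "tiny.csv"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """A larger cohort for recovery-style checks."""
    return generate_cohort(CohortConfig(n_species=4000, seed=7))
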