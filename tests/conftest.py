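import pandas as pd
import pytest
from importlib import resources

from reyrisk import (
    DEFAULT_ELEMENTS,
    default_exposure_profiles,
    load_reference_set,
    load_toxicology,
    read_concentrations,
)


@pytest.fixture(scope="session")
def ref():
    return load_reference_set()


@pytest.fixture(scope="session")
def tox():
    return load_toxicology()


@pytest.fixture(scope="session")
def profiles():
    child, adult = default_exposure_profiles()
    return {"child": child, "adult": adult}


@pytest.fixture(scope="session")
def group_means():
    """Published worldwide fly/bottom-ash REY group means (mg/kg)."""
    path = resources.files("reyrisk").joinpath("data", "study_group_means.csv")
    return read_concentrations(str(path))


@pytest.fixture(scope="session")
def serbia_mean_conc(group_means):
    """Mean of the Serbian fly and bottom ash group means, one-row table."""
    reys = list(DEFAULT_ELEMENTS.reys)
    mean = group_means.loc[["serbia_fly", "serbia_bottom"], reys].mean()
    return pd.DataFrame([mean], index=pd.Index(["serbia_mean"], name="sample_id"))


@pytest.fixture(scope="session")
def lumped_rey():
    """Total-REY concentration as one lumped pseudo-element column.

    All REYs share one RfD and CSF, so the family HI/TCR depends only on
    the total; assigning the total to a single member is exact.
    """
    def make(total: float) -> pd.DataFrame:
        return pd.DataFrame(
            {"Ce": [total]}, index=pd.Index(["lumped"], name="sample_id"))
    return make
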