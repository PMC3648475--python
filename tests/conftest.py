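import numpy as np
import pandas as pd
import pytest

from figsel.classification_eval import run_harness
from figsel.passport_climate import AccessionPassport, ClimateProfile, Collection
from figsel.reference import ANALYSIS_VARIABLES
from figsel.synthetic_data import GeneratorConfig, gen_bundle


def make_passport(
    accession_id: str,
    site_id: str = "S1",
    precyr: float = 420.0,
    ariyr: float = 0.3,
    bio15: float = 60.0,
    tminyr: float = 6.0,
    tmaxyr: float = 18.0,
    bio4: float = 700.0,
    bio16: float | None = None,
    bio19: float = 120.0,
    latitude: float | None = None,
    longitude: float | None = None,
) -> AccessionPassport:
    """A valid passport with sensible dry-band defaults, overridable per test."""
    return AccessionPassport(
        accession_id=accession_id,
        site_id=site_id,
        climate=ClimateProfile(
            precyr=precyr,
            ariyr=ariyr,
            tminyr=tminyr,
            tmaxyr=tmaxyr,
            bio4=bio4,
            bio15=bio15,
            bio16=bio16 if bio16 is not None else 0.4 * precyr,
            bio19=bio19,
        ),
        latitude=latitude,
        longitude=longitude,
    )


@pytest.fixture(scope="session")
def default_bundle():
    """Trait-only synthetic dataset at the default study conditions (201/201)."""
    return gen_bundle(GeneratorConfig(seed=7), mode="trait_only")


@pytest.fixture(scope="session")
def traits_and_labels(default_bundle):
    X = default_bundle.traits[list(ANALYSIS_VARIABLES)]
    y = default_bundle.traits["label"]
    return X, y


@pytest.fixture(scope="session")
def harness_summaries(traits_and_labels):
    """The 10-repetition harness on the default synthetic data, all families."""
    X, y = traits_and_labels
    return run_harness(X, y, n_runs=10, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
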