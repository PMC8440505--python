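import numpy as np
import pandas as pd
import pytest

from practice_archetypes import clustering, features
from practice_archetypes.geospatial import load_area_attributes, load_coordinate_lookup
from practice_archetypes.synthetic_data import (
    ArchetypeSpec,
    default_archetypes,
    generate_records,
    sample_feature_level,
)

COHORT_SEED = 42
WINDOW = features.month_window("2018-04", 12)


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def cohort(archetypes):
    """Default record-level cohort; generated once per session."""
    return generate_records(archetypes, months=12, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def coords(cohort):
    return load_coordinate_lookup(cohort.coordinates)


@pytest.fixture(scope="session")
def areas(cohort):
    return load_area_attributes(cohort.areas)


@pytest.fixture(scope="session")
def truth(cohort):
    return cohort.truth.set_index("practice_id")


@pytest.fixture(scope="session")
def profiles(cohort, coords, areas):
    return features.build_practice_profiles(
        cohort.dispensing, cohort.sizes, coords, areas, WINDOW
    )


@pytest.fixture(scope="session")
def feature_cohort(archetypes):
    """Feature-level cohort (fast path), seed 42."""
    return sample_feature_level(archetypes, COHORT_SEED)


@pytest.fixture(scope="session")
def fitted(profiles):
    """Standardised matrix, params and a labelled k=2 model on the cohort."""
    Z, params = clustering.standardise(profiles)
    model = clustering.label_clusters(
        clustering.fit_kmeans(Z, 2, COHORT_SEED), params
    )
    return Z, params, model


@pytest.fixture(scope="session")
def tiny_archetypes():
    """Two very small, very separated archetypes for cheap record-level tests."""
    chapter_mix = {1: 0.5, 4: 0.3, 2: 0.2}
    section_mix = {s: 1.0 / 3 for s in (3, 7, 9)}
    a = ArchetypeSpec(
        label="A", n_practices=4,
        feature_means=(8.0, 120.0, 2.0, 1.0, 4000.0, 1000.0),
        feature_sds=(1.0, 5.0, 0.2, 0.1, 200.0, 50.0),
        deprivation_mix=(0.25, 0.25, 0.25, 0.25),
        chapter_mix=chapter_mix, chapter4_section_mix=section_mix,
        dispersion_target_km=5.0, missing_bnf_rate=0.0,
    )
    b = ArchetypeSpec(
        label="B", n_practices=6,
        feature_means=(3.0, 60.0, 15.0, 5.0, 300.0, 2000.0),
        feature_sds=(0.5, 3.0, 1.0, 0.5, 30.0, 80.0),
        deprivation_mix=(0.25, 0.25, 0.25, 0.25),
        chapter_mix=chapter_mix, chapter4_section_mix=section_mix,
        dispersion_target_km=20.0, missing_bnf_rate=0.0,
    )
    return (a, b)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_archetypes):
    return generate_records(tiny_archetypes, months=12, seed=7)


def toy_dispensing():
    """Two practices, two months, hand-checkable item counts."""
    return pd.DataFrame({
        "practice_id": ["P1", "P1", "P1", "P2", "P2"],
        "pharmacy_id": ["A", "A", "B", "A", "C"],
        "year_month": ["2018-04", "2018-05", "2018-04", "2018-04", "2018-05"],
        "items": [10, 20, 30, 5, 15],
    })
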