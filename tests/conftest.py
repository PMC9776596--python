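"""Shared fixtures: one small synthetic study reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gutmwas.containers import CLASSIFIERS
from gutmwas.profiles import (ProfilingConfiguration, aggregate_profiles,
                              deduplicate_samples, normalize_abundance)
from gutmwas.synthetic import plant_effects, generate_catalog, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """24 patients, 40 species, moderate planted effects."""
    seed = 7
    catalog = generate_catalog(40, seed)
    truth = plant_effects(catalog, n_enriched=2, n_depleted=2, log2_fc=3.0,
                          seed=seed + 17, similarity_shrinkage=0.3)
    return simulate_study(n_patients=24, n_species=40, frac_case=8 / 24,
                          n_duplicate_patients=4, truth=truth,
                          depth=50_000, seed=seed)


@pytest.fixture(scope="session")
def patient_abundance(small_study):
    """Deduplicated per-patient abundance from the small study."""
    config = ProfilingConfiguration(frozenset(CLASSIFIERS), "complete")
    merged = aggregate_profiles(small_study["profiles"], config)
    abundance = normalize_abundance(merged, small_study["catalog"])
    return deduplicate_samples(abundance, small_study["cohort"])


@pytest.fixture(scope="session")
def patient_labels(small_study, patient_abundance):
    byp = (small_study["cohort"].drop_duplicates("patient_id")
           .set_index("patient_id"))
    return byp.loc[patient_abundance.sample_ids, "outcome"].to_numpy(int)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def simplex_matrix(rng):
    x = np.exp(rng.normal(0.0, 1.5, size=(30, 25)))
    return x / x.sum(axis=1, keepdims=True)
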