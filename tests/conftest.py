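"""Shared fixtures.

Session-scoped fixtures build the default synthetic study (22 samples,
440 fiber-pair spectra at native resolution) once; unit tests that do not
need the full-size study use the small generator configs below.
"""

from __future__ import annotations

import numpy as np
import pytest

from lssnd import clustering as cl
from lssnd import histology as hist
from lssnd import spectra as sp
from lssnd import synthetic as syn
from lssnd.loocv import SpectraDataset

STUDY_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    return syn.generate_cohort(syn.CohortConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def default_records(default_cohort):
    return syn.generate_study_spectra(default_cohort, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def default_matrix(default_records):
    """Normalized, filtered, concatenated spectra: (440, 7296) + sample ids."""
    return sp.preprocess_dataset(default_records)


@pytest.fixture(scope="session")
def default_assignment(default_matrix):
    """Clustering of the default set at k = 5 (with full eigenvalue list)."""
    X, _ = default_matrix
    return cl.spectral_cluster(X, k=5, seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_matrix, default_cohort) -> SpectraDataset:
    X, sids = default_matrix
    classes = {m.sample_id: hist.assign_nd_class(m.true_nd)
               for m in default_cohort}
    return SpectraDataset(X, sids, classes)


# -- small-scale material for unit tests ------------------------------------

@pytest.fixture
def small_gen() -> syn.SpectrumGenConfig:
    return syn.SpectrumGenConfig(n_points_per_fiber=256)


def make_small_cohort(n_per_class: int = 4, n_acquisitions: int = 6,
                      n_points: int = 240, seed: int = 0,
                      ages=None):
    """Compact cohort + preprocessed matrix for classifier tests.

    Ages are chosen one clump per ND class so the three classes are balanced
    and well separated.
    """
    if ages is None:
        base = {"high": 4.3, "medium": 6.3, "low": 12.0}
        ages = []
        for cls, a in base.items():
            ages += [a + 0.05 * i for i in range(n_per_class)]
    cfg = syn.CohortConfig(n_samples=len(ages), ages_months=tuple(ages),
                           n_acquisitions_per_sample=n_acquisitions,
                           n_profile_groups=3, seed=seed)
    cohort = syn.generate_cohort(cfg)
    gen = syn.SpectrumGenConfig(n_points_per_fiber=n_points)
    records = syn.generate_study_spectra(cohort, gen, n_acquisitions,
                                         seed=seed)
    X, sids = sp.preprocess_dataset(
        records, sp.FilterSpec(sd_measures=5, kernel_measures=20))
    classes = {m.sample_id: hist.assign_nd_class(m.true_nd) for m in cohort}
    return cohort, SpectraDataset(X, sids, classes)


#: balanced classes (5 per ND band) on a smooth ND continuum away from the
#: ND floor: under label permutation, held-out predictions follow neighbours
#: whose shuffled labels are independent of the held-out one, so accuracy
#: sits near 1/3
NULL_COHORT_AGES = (4.3, 4.5, 4.7, 4.9, 5.1,
                    5.6, 6.0, 6.4, 6.8, 7.3,
                    8.3, 9.0, 9.8, 10.8, 12.5)


@pytest.fixture(scope="session")
def small_dataset():
    return make_small_cohort()
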