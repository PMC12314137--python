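"""Shared fixtures: tiny hand-built cohorts and one strong synthetic cohort.

The strong-shift cohort and its fitted clustering are session-scoped:
UMAP's JIT warm-up and the bootstrap runs dominate suite runtime, so every
test that needs a realistic cohort reuses the same fitted objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shockmetab import MetabolicClusterModel, RunConfig
from shockmetab.io import BELOW_LOD, MEASURED, MISSING, CohortTables
from shockmetab.simulate import default_spec, simulate_cohort

COHORT_SEED = 11
STABILITY_SEED = 23


def make_tables(conc, status=None, families=None, clinical=None, patients=None,
                metabolites=None) -> CohortTables:
    """Build a CohortTables from plain arrays for unit tests."""
    conc = np.asarray(conc, dtype=float)
    n, m = conc.shape
    patients = patients or [f"P{i+1:02d}" for i in range(n)]
    metabolites = metabolites or [f"M{j+1:02d}" for j in range(m)]
    if status is None:
        status = np.full((n, m), MEASURED, dtype=object)
    status_df = pd.DataFrame(np.asarray(status, dtype=object),
                             index=patients, columns=metabolites)
    conc_df = pd.DataFrame(conc, index=patients, columns=metabolites)
    conc_df = conc_df.mask(status_df != MEASURED)
    families = families or ["amino_acids"] * m
    annotations = pd.Series(families, index=metabolites, name="family")
    if clinical is None:
        clinical = pd.DataFrame(
            {
                "admission_cause": ["septic" if i % 2 else "cardiogenic"
                                    for i in range(n)],
                "apache2": 20 + np.arange(n) % 10,
                "sofa": 10 + np.arange(n) % 5,
                "n_organ_failures": np.arange(n) % 4,
                "icu_death": [False] * n,
                "hospital_death": [i % 3 == 0 for i in range(n)],
            },
            index=patients,
        )
    return CohortTables(concentrations=conc_df, status=status_df,
                        annotations=annotations, clinical=clinical)


@pytest.fixture(scope="session")
def strong_cohort():
    """Default study-like cohort: three phenotypes with strong family shifts."""
    return simulate_cohort(default_spec(rng_seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cluster_results(strong_cohort):
    return MetabolicClusterModel(strong_cohort.tables, RunConfig()).fit()


@pytest.fixture(scope="session")
def stability_report(cluster_results):
    from shockmetab import bootstrap_stability

    return bootstrap_stability(cluster_results, n_boot=100, seed=STABILITY_SEED)
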