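import numpy as np
import pytest

from ssipre.catalog import TestCatalogEntry, default_catalog
from ssipre.preprocess import DailyGrid
from ssipre.synth import CohortSpec, generate_cohort


def make_grid(series: dict[tuple[str, str], dict[int, float]], obs_days: int,
              patient_ids=None, test_names=None) -> DailyGrid:
    """Build a DailyGrid from {(patient, test): {day: value}} sparse series."""
    if patient_ids is None:
        patient_ids = sorted({p for p, _ in series})
    if test_names is None:
        test_names = sorted({t for _, t in series})
    n_p, n_t, n_d = len(patient_ids), len(test_names), obs_days + 1
    values = np.full((n_p, n_t, n_d), np.nan)
    mask = np.zeros((n_p, n_t, n_d), dtype=bool)
    for (pid, test), obs in series.items():
        i, t = patient_ids.index(pid), test_names.index(test)
        for day, val in obs.items():
            values[i, t, obs_days - day] = val
            mask[i, t, obs_days - day] = True
    return DailyGrid(list(patient_ids), list(test_names), obs_days, values, mask)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """A 120-patient cohort with default (planted) effects."""
    spec = CohortSpec(n_patients=120, prevalence=0.25, seed=11)
    patients, labs = generate_cohort(spec, catalog)
    return spec, patients, labs


def toy_entry(lo=4.0, hi=10.0, name="T", price=30.0, rate30=2.0):
    return TestCatalogEntry(test_name=name, price=price, ref_low=lo, ref_high=hi, rate30=rate30)
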