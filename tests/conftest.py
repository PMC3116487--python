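import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from maldianova.design import build_design
from maldianova.simulate import (NoiseParams, PlantedEffect, default_families,
                                 simulate_dataset)


@pytest.fixture(scope="session")
def small_design():
    """2 genotypes x 2 diets x 1 week, 8 spectra / 2 samples per cell."""
    cells = {(g, d, 3): (8, 2) for g in ["B6", "NZO"] for d in ["SD", "CHF"]}
    return build_design(["B6", "NZO"], ["SD", "CHF"], [3], cells)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    fams = default_families(3000, n_families=3, peaks_per_family=3,
                            n_singletons=4, seed=1)
    effects = [PlantedEffect("fam1", "diet", {"CHF": 1.2})]
    return simulate_dataset(small_design, fams, effects,
                            axis_length=3000, seed=7)


def make_sample_matrix(n_samples=60, n_families=5, peaks_per_family=4,
                       n_noise=20, rho=0.9, diet_effect=2.0, seed=5):
    """Sample-averaged-scale profile matrix with planted peak families.

    Family 1 carries a diet effect (CHF shifted); remaining families are
    correlated but uninformative; noise peaks are iid.  Returns
    (profiles DataFrame, sample sheet, family-of map).
    """
    rng = np.random.default_rng(seed)
    sheet = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_samples)],
        "spectrum_id": [f"s{i}" for i in range(n_samples)],
        "spectrum_file": [f"s{i}.csv" for i in range(n_samples)],
        "genotype": rng.choice(["B6", "NZO", "SJL"], n_samples),
        "diet": rng.choice(["SD", "HF", "CHF"], n_samples),
        "week": rng.choice([3, 4, 6, 8], n_samples),
        "preparation": 1,
        "replicate": 1,
    })
    rows, names, fam_of = [], [], {}
    for f in range(n_families):
        shared = rng.standard_normal(n_samples)
        for j in range(peaks_per_family):
            mz = 1000.0 + f * 100 + j
            prof = (np.sqrt(rho) * shared
                    + np.sqrt(1 - rho) * rng.standard_normal(n_samples))
            if f == 0:
                prof = prof + (sheet.diet == "CHF").to_numpy() * diet_effect
            rows.append(prof)
            names.append(mz)
            fam_of[mz] = f
    for k in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
        names.append(3000.0 + k)
        fam_of[3000.0 + k] = -1 - k
    profiles = pd.DataFrame(rows, index=pd.Index(names, name="mz"),
                            columns=sheet.sample_id)
    return profiles, sheet, fam_of


@pytest.fixture(scope="session")
def planted_profiles():
    return make_sample_matrix()
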