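import numpy as np
import pandas as pd
import pytest

from resiphen import SimConfig, simulate_dataset
from resiphen.simulate import simulate_pedigree


@pytest.fixture(scope="session")
def small_cfg():
    """~80 offspring, artifacts and perturbations at default rates."""
    return SimConfig(n_sires=4, n_dams=20, offspring_per_litter=4, n_cg=4, seed=3)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def clean_cfg():
    """~120 offspring, no artifacts, no perturbations: pure growth + noise."""
    return SimConfig(
        n_sires=4, n_dams=24, offspring_per_litter=5, n_cg=4, seed=11,
        perturbation_rate=0.0,
        artifact_rates={"spike": 0, "adaptation": 0, "missing": 0, "gross": 0},
    )


@pytest.fixture(scope="session")
def clean_sim(clean_cfg):
    return simulate_dataset(clean_cfg)


@pytest.fixture(scope="session")
def toy_pedigree():
    """Founders 1-2, full sibs 3-4, animal 5 = offspring of the full sibs."""
    return pd.DataFrame(
        dict(id=[1, 2, 3, 4, 5], sire=[0, 0, 1, 1, 3], dam=[0, 0, 2, 2, 4])
    )


@pytest.fixture(scope="session")
def family_pedigree():
    """500 offspring from 10 sires x 50 dams (pedigree only)."""
    cfg = SimConfig(n_sires=10, n_dams=50, offspring_per_litter=10, n_cg=8, seed=21)
    return simulate_pedigree(cfg)


def linear_records(n_animals=5, slope=1.0, start=40.0, noise=0.0, seed=0,
                   ages=None, pen=0):
    """Deterministic long-format records on an exact line, for QC fixtures."""
    rng = np.random.default_rng(seed)
    ages = np.arange(95, 156) if ages is None else np.asarray(ages)
    rows = []
    for a in range(n_animals):
        w = start + slope * (ages - 95) + (rng.normal(0, noise, len(ages)) if noise else 0.0)
        rows.append(pd.DataFrame(dict(
            animal_id=a + 1, age_d=ages, weight_kg=w,
            fi_g_per_d=2000.0 + 5.0 * (ages - 95), dur_s_per_d=4000.0,
            nvisits_per_d=10.0, pen=pen, compartment=0, farm=0, cg=0,
            sex="M", birth_date=pd.Timestamp("2020-01-01"),
            entry_date=pd.Timestamp("2020-03-11"),
        )))
    return pd.concat(rows, ignore_index=True)
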