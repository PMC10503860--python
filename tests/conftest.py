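import numpy as np
import pandas as pd
import pytest

from neuroslope import SimConfig, simulate_cohort


def tiny_sim_config(**overrides) -> SimConfig:
    """A fast cohort: 16^3 volumes, few subjects, few SNPs."""
    base = dict(
        n_subjects=12,
        n_snps=40,
        volume_shape=(16, 16, 16),
        aging_region=((2, 6), (2, 6), (2, 6)),
        disease_region=((10, 14), (10, 14), (10, 14)),
        visits_min=3,
        visits_max=4,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(tiny_sim_config())


def random_visit_table(rng: np.random.Generator, n_subjects=3, max_visits=8) -> pd.DataFrame:
    """Random matched-visit table for brute-force pairing comparisons."""
    rows = []
    for s in range(n_subjects):
        n = int(rng.integers(1, max_visits + 1))
        days = np.sort(rng.choice(np.arange(0, 1200, 10), size=n, replace=False))
        dx = ["CN", "MCI", "AD"][int(rng.integers(0, 3))]
        for d in days:
            rows.append((f"P{s}", float(d), 70.0, dx, float(rng.uniform(0, 60))))
    return pd.DataFrame(
        rows, columns=["subject_id", "visit_day", "age_years", "diagnosis", "adas13"]
    )
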