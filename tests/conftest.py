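import numpy as np
import pandas as pd
import pytest

from ncrisk import Cohort, GeneratorConfig, generate_cohort


def make_cohort_frame(n=6, **overrides) -> pd.DataFrame:
    """Small hand-built cohort frame with complete, analyzable defaults."""
    base = {
        "patient_id": [f"P{i}" for i in range(n)],
        "age_years": np.linspace(10, 60, n),
        "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
        "primary_site": ["thoracic", "head_neck"] * (n // 2)
                        + ["thoracic"] * (n % 2),
        "fusion": ["BRD4"] * n,
        "histology": ["squamous"] * n,
        "tumor_diameter_cm": np.linspace(2, 8, n),
        "metastasis_baseline": ["yes", "no"] * (n // 2) + ["yes"] * (n % 2),
        "ever_surgery": ["no"] * n,
        "ever_radiation": ["yes"] * n,
        "ever_chemo": ["yes"] * n,
        "os_months": np.arange(1, n + 1, dtype=float),
        "os_event": [1] * n,
        "efs_months": np.arange(1, n + 1, dtype=float) * 0.5,
        "efs_event": [1] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def small_cohort() -> Cohort:
    return Cohort(make_cohort_frame())


@pytest.fixture(scope="session")
def calibrated_cohort_2000():
    """One default-condition synthetic cohort of 2,000 registry patients."""
    cohort, latent = generate_cohort(GeneratorConfig(n_patients=2000, seed=7))
    return cohort, latent
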