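import numpy as np
import pandas as pd
import pytest

from dietherit import simdata


@pytest.fixture(scope="session")
def small_genotypes() -> simdata.GenotypeMatrix:
    """2,000 individuals x 300 SNPs with block-wise LD, shared across tests."""
    return simdata.simulate_genotypes(2_000, 300, seed=42, rho_range=(0.1, 0.95))


@pytest.fixture(scope="session")
def qc_table() -> tuple[pd.DataFrame, pd.Series]:
    """Hand-built questionnaire records covering every QC rule boundary."""
    rows = [
        # iid, qidx, energy, typical, completed, duration, preg, cancer
        ("a", 1, 900.0, 1, 1, 10.0, 0, 0),     # energy below 1,000 kJ
        ("a", 2, 1000.0, 1, 1, 10.0, 0, 0),    # boundary energy passes
        ("m", 1, 19_500.0, 1, 1, 10.0, 0, 0),  # male below 20 MJ: keep
        ("f", 1, 19_500.0, 1, 1, 10.0, 0, 0),  # female above 18 MJ: drop
        ("b", 1, 8_000.0, 0, 1, 10.0, 0, 0),   # atypical diet
        ("b", 2, 8_000.0, 1, 1, 4.0, 0, 0),    # under 5 minutes
        ("b", 3, 8_000.0, 1, 1, 5.0, 0, 0),    # exactly 5 minutes passes
        ("c", 1, 8_000.0, 1, 0, 10.0, 0, 0),   # incomplete
        ("c", 2, 8_000.0, 1, 1, 10.0, 1, 0),   # recent pregnancy
        ("c", 3, 8_000.0, 1, 1, 10.0, 0, 1),   # recent cancer
        ("c", 4, 8_000.0, 1, 1, 10.0, 0, 0),   # clean
    ]
    q = pd.DataFrame(
        rows,
        columns=["iid", "qidx", "energy_kj", "typical_diet", "completed",
                 "duration_min", "pregnant_recent", "cancer_recent"],
    )
    sex = pd.Series({"a": 0, "m": 1, "f": 0, "b": 1, "c": 0})
    return q, sex


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
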