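import numpy as np
import pandas as pd
import pytest

from poolfit import FitnessSpec, SimConfig, make_reference, simulate_counts


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A 30-strain, 3-time-point experiment small enough for FASTQ round trips."""
    return SimConfig(
        n_strains=30,
        depth=2000,
        schedule=(0, 5, 10),
        n_tech_reps=1,
        seed=101,
        fitness_spec=FitnessSpec(0.2, 0.7, 0.9),
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    truth, counts = simulate_counts(small_config)
    return truth, counts


@pytest.fixture(scope="session")
def small_reference(small_config) -> pd.DataFrame:
    return make_reference(small_config)


def toy_counts(rows: list[dict]) -> pd.DataFrame:
    """Build a CountTable from sparse row dicts, filling schema defaults."""
    defaults = {
        "barcode_position": "B1",
        "pool": "hybrid",
        "background": "hybrid",
        "condition": "YPD",
        "bio_rep": "A",
        "tech_rep": 1,
        "timepoint_index": 0,
        "generations": 0.0,
    }
    out = pd.DataFrame([{**defaults, **r} for r in rows])
    return out


def sort_counts(df: pd.DataFrame) -> pd.DataFrame:
    cols = [
        "strain_id",
        "barcode_position",
        "pool",
        "condition",
        "bio_rep",
        "tech_rep",
        "timepoint_index",
    ]
    return (
        df.sort_values(cols)
        .reset_index(drop=True)
        .astype({"tech_rep": int, "timepoint_index": int, "count": int, "generations": float})
    )
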