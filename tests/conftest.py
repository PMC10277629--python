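import numpy as np
import pandas as pd
import pytest

from longidecomp import synth
from longidecomp.config import CohortConfig, PipelineConfig
from longidecomp.pipeline import simulate_cohort

BASE_ALPHA = (6.0, 14.0, 10.0, 8.0, 7.0, 6.0, 5.0, 4.0)


def small_cohort(seed: int, n_genes: int = 400, shifted: bool = True,
                 regulated_fraction: float = 0.05, mixed_markers: int = 4,
                 tau: float = 0.3, n_subjects: int = 14):
    """A reduced cohort for unit tests: same design, fewer genes."""
    cfg = PipelineConfig(
        cohort=CohortConfig(
            n_genes=n_genes,
            n_subjects=n_subjects,
            markers_per_type=10,
            baseline_alpha=BASE_ALPHA,
            shift_schedule=(("T1", 0.6), ("T2", 0.85), ("T3", 1.0)) if shifted else (),
            regulated_fraction=regulated_fraction,
            mixed_markers=mixed_markers,
            tau=tau,
        ),
        seed=seed,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One shifted cohort with planted regulation, shared across tests."""
    return small_cohort(seed=20)


@pytest.fixture(scope="session")
def null_cohort():
    """Global null: no composition shift, no regulation."""
    return small_cohort(seed=21, shifted=False, regulated_fraction=0.0, mixed_markers=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_screen():
    """Hand-built screen table for the call/onset/classify rules."""
    return pd.DataFrame(
        {
            "q": [0.01, 0.2, 0.01, 0.01, 0.04],
            "log2FC_T1": [0.5, 3.0, 1.0, -0.2, -1.5],
            "log2FC_T2": [1.2, 3.0, 0.4, 0.3, -2.0],
            "log2FC_T3": [1.5, 3.0, 0.2, 0.9, -0.4],
            "converged": [True, True, True, True, True],
        },
        index=pd.Index([f"g{i}" for i in range(5)], name="gene"),
    )
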