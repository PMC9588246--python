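import numpy as np
import pandas as pd
import pytest

from lipidmeth import (
    ClpmParams,
    MediationParams,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Small two-visit cohort with planted EWAS and cross-lagged signal."""
    cfg = SimulationConfig(
        n_pairs=60,
        n_cpgs=80,
        clpm_params={
            0: ClpmParams(rho1=0.5, rho2=0.0),
            1: ClpmParams(rho1=0.0, rho2=-0.4),
        },
        signal_lipids={0: "TG", 1: "HDL_C"},
        xs_effects={0: 0.05, 1: -0.05},
        seed=11,
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no methylation-lipid association at all."""
    cfg = SimulationConfig(n_pairs=80, n_cpgs=100, seed=5)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_panel(rng, n=60, columns=("lipid_b", "meth_b", "lipid_f", "meth_f")):
    """Generic random multivariate panel with mild cross-correlation."""
    k = len(columns)
    a = rng.standard_normal((k, k)) * 0.3 + np.eye(k)
    data = rng.standard_normal((n, k)) @ a.T
    return pd.DataFrame(data, columns=list(columns))
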