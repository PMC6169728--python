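import warnings

import numpy as np
import pytest

from genfactor.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Simulation-scale fits routinely emit convergence/sparse warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = SimulationConfig(n_families=800, n_variants=200, seed=314, n_pcs=2)
    cohort, panel, sumstats, truth = simulate_cohort(cfg)
    return cfg, cohort, panel, sumstats, truth


def factor_map(cfg: SimulationConfig) -> dict:
    return {
        f: [it for it in cfg.items if it.rstrip("0123456789") == f]
        for f in cfg.factors
    }
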