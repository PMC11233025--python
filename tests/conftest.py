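import numpy as np
import pandas as pd
import pytest

from opioid_its import design, synthetic


@pytest.fixture(scope="session")
def timeline():
    return design.default_timeline()


#: Coefficient vector with realistic regional magnitudes, positive expected
#: rate over the whole 1999-2022 range (used as recovery truth throughout).
TRUE_BETA = np.array([0.1920, 0.0032, -0.0111, -0.0036, -0.0713, 0.0110,
                      -0.0082, 0.5231, 0.0178, -0.0160])


@pytest.fixture(scope="session")
def true_beta():
    return TRUE_BETA.copy()


@pytest.fixture(scope="session")
def full_design(timeline):
    return design.build_design_matrix(np.arange(1, 287), timeline)


@pytest.fixture(scope="session")
def sim_inputs(tmp_path_factory):
    """A small synthetic WONDER input set written to disk once per session."""
    out = tmp_path_factory.mktemp("sim")
    from opioid_its import pipeline
    paths = pipeline.simulate_stage(str(out), seed=20240501)
    return paths


def single_stratum_series(beta, timeline, population=1e7, seed=0, noise="poisson-counts"):
    """Helper: one region's monthly series from a known truth, constant population."""
    t = np.arange(1, 287)
    X = design.build_design_matrix(t, timeline).to_numpy()
    mu = X @ beta
    lam = mu * population / 1e5
    if noise == "poisson-counts":
        deaths = np.random.default_rng(seed).poisson(lam).astype(float)
    else:
        deaths = lam
    return pd.DataFrame({"t": t, "deaths": deaths,
                         "population": float(population),
                         "rate": 1e5 * deaths / population})
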