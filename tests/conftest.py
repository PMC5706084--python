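import warnings

import numpy as np
import pandas as pd
import pytest

import sedsource as ss


def make_matrix(values, points=None, chemicals=None, kind="hq"):
    """Build a ContaminationMatrix from a plain 2-D array."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    points = points or [f"S{i + 1:02d}" for i in range(n)]
    chemicals = chemicals or [f"chem{j + 1}" for j in range(m)]
    df = pd.DataFrame(values, index=points, columns=chemicals)
    return ss.ContaminationMatrix(df, value_kind=kind)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default synthetic scenario (seed 11)."""
    scenario = ss.SyntheticScenario(seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result, metrics = ss.simulate_and_run(scenario)
    return scenario, result, metrics


@pytest.fixture(scope="session")
def small_registry():
    """Three-chemical registry with full PNEC information for risk tests."""
    return ss.ChemicalRegistry(
        [
            ss.ChemicalProfile(
                "metal_a", ss.ChemClass.HEAVY_METAL, lcl_limit=10.0, kp=100.0, pnec_water=0.05
            ),
            ss.ChemicalProfile(
                "pah_b",
                ss.ChemClass.PAH,
                lcl_limit=0.5,
                kp=1000.0,
                toxicity_endpoints=((10.0, 1000.0), (2.0, 1000.0)),
            ),
            ss.ChemicalProfile(
                "hc_c", ss.ChemClass.HYDROCARBON, lcl_limit=50.0, pnec_sediment=25.0
            ),
        ]
    )
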