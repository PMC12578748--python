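import numpy as np
import pandas as pd
import pytest

from mixsurv.scenarios import ScenarioConfig, SurvivalDataset, generate_dataset


@pytest.fixture(scope="session")
def scenario1_small() -> SurvivalDataset:
    """A modest base-case dataset for contract and estimand tests."""
    return generate_dataset(ScenarioConfig(scenario_id=1, n_subjects=600, seed=42))


@pytest.fixture(scope="session")
def linear_dataset() -> SurvivalDataset:
    """Log-linear variant of scenario 1 (correctly specified for Cox PH)."""
    return generate_dataset(
        ScenarioConfig(scenario_id=1, n_subjects=1500, seed=7, hazard_variant="linear")
    )


def toy_dataset(times, events, n_exposures=2) -> SurvivalDataset:
    """Hand-built dataset with deterministic covariates, for bookkeeping tests."""
    n = len(times)
    rng = np.random.default_rng(0)
    return SurvivalDataset(
        time=np.asarray(times, dtype=float),
        event=np.asarray(events, dtype=int),
        exposures=pd.DataFrame(
            rng.lognormal(size=(n, n_exposures)),
            columns=[f"M{j+1}" for j in range(n_exposures)],
        ),
        confounders=pd.DataFrame(
            {"C1": rng.integers(0, 2, n).astype(float), "C2": rng.normal(size=n)}
        ),
    )
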