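"""Shared fixtures.

The expensive session fixtures (the 20-case simulation cohort and the
models trained from it) are built once and reused by the dosimetry,
cohort and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from spacersim import cohort, phantom, simulate

# mesh-gap and connected-component warnings are expected on coarse phantoms
warnings.filterwarnings("ignore", message="wall gap .*")
warnings.filterwarnings("ignore", message="mask has .* connected components")


@pytest.fixture(scope="session")
def phantom_case():
    """Default-grid phantom, seed 1."""
    return phantom.generate_phantom(1)


@pytest.fixture(scope="session")
def sim_result(phantom_case):
    """One full S1 insertion simulation (seed-1 case)."""
    return simulate.simulate_scenario(
        phantom_case, phantom.SpacerScenario("S1")
    )


@pytest.fixture(scope="session")
def cohort_df():
    """The 20-case x 4-scenario simulation-phase cohort."""
    return cohort.run_cohort(cohort.CohortSettings(n_cases=20))


@pytest.fixture(scope="session")
def dss_models(cohort_df):
    nn, threshold, bayes = cohort.train_dss(cohort_df, seed=0)
    return {"nn": nn, "threshold": threshold, "bayes": bayes}
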