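"""Shared synthetic scenarios, generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cpdr import (
    ExpressionMatrix,
    ScenarioConfig,
    simulate_cell_lines,
    simulate_cohort,
    simulate_perturbation_library,
    simulate_sensitivity_and_response,
)


@pytest.fixture(scope="session")
def std_scenario():
    """The standard end-to-end scenario: 3 subtypes, carriers, 5/20 reversers."""
    cfg = ScenarioConfig(seed=7)
    cohort, normals, truth = simulate_cohort(cfg)
    library = simulate_perturbation_library(cfg, truth)
    lines = simulate_cell_lines(cfg, truth)
    sens, response = simulate_sensitivity_and_response(cfg, truth)
    return {
        "cfg": cfg,
        "cohort": cohort,
        "normals": normals,
        "truth": truth,
        "library": library,
        "cell_lines": lines,
        "sens": sens,
        "response": response,
    }


@pytest.fixture(scope="session")
def purification_scenario():
    """Contaminated single-subtype cohort with a distinct cancer baseline."""
    cfg = ScenarioConfig(
        seed=5, k=1, samples_per_subtype=20, n_normals=10,
        carrier_fraction=1.0, alpha_range=(0.2, 0.7),
        distinct_cancer_baseline=True,
    )
    cohort, normals, truth = simulate_cohort(cfg)
    return {"cfg": cfg, "cohort": cohort, "normals": normals, "truth": truth}


@pytest.fixture()
def small_log2_matrix():
    """Deterministic 6-gene x 4-sample log2 matrix."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.uniform(0, 10, size=(6, 4)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(4)],
    )
    return ExpressionMatrix(data, "log2")
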