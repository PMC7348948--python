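import numpy as np
import pandas as pd
import pytest

from funcresp import ExperimentTable, FRParams, generate_trials
from funcresp.study import STUDY_DENSITIES, STUDY_REPLICATES, reference_params


@pytest.fixture(scope="session")
def predator_aggregate_params() -> FRParams:
    """Generating truth of the single-predator aggregate treatment."""
    return reference_params("predator_single", "aggregate")


@pytest.fixture(scope="session")
def predator_cell_table(predator_aggregate_params) -> ExperimentTable:
    """One simulated single-predator aggregate cell at the study design."""
    return generate_trials(
        {("aggregate", "predator_single"): predator_aggregate_params},
        STUDY_DENSITIES,
        STUDY_REPLICATES,
        seed=0,
    )


@pytest.fixture(scope="session")
def two_cell_table() -> ExperimentTable:
    """Both single-predator distribution treatments in one table."""
    cells = {
        ("aggregate", "predator_single"): reference_params("predator_single", "aggregate"),
        ("uniform", "predator_single"): reference_params("predator_single", "uniform"),
    }
    return generate_trials(cells, STUDY_DENSITIES, STUDY_REPLICATES, seed=0)


def make_design_skeleton(densities=STUDY_DENSITIES, replicates=STUDY_REPLICATES) -> ExperimentTable:
    """Empty (killed = 0) two-distribution design for the GLMM generator."""
    rows = []
    for dist in ("aggregate", "uniform"):
        for rep in range(1, replicates + 1):
            for d in densities:
                rows.append(
                    {
                        "density": d,
                        "killed": 0,
                        "distribution": dist,
                        "enemy": "predator_single",
                        "replicate": rep,
                    }
                )
    return ExperimentTable(pd.DataFrame(rows), 1.0)


@pytest.fixture(scope="session")
def glmm_design() -> ExperimentTable:
    return make_design_skeleton()
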