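import numpy as np
import pandas as pd
import pytest

from flowparse import design, glm, stimuli


@pytest.fixture(scope="session")
def scan_design():
    return design.build_scan_sequence(seed=7)


@pytest.fixture(scope="session")
def modulator_table(scan_design):
    """Random but fixed per-movie modulator values for every trial."""
    rng = np.random.default_rng(0)
    ids = sorted({t.movie_id for t in scan_design.trials})
    return pd.DataFrame(
        {
            "movie_id": ids,
            "QoM": rng.uniform(0.0, 6.0, len(ids)),
            "SoM": rng.uniform(0.0, 30.0, len(ids)),
            "SMS": rng.uniform(0.0, 10.0, len(ids)),
            "OMS": rng.uniform(0.0, 10.0, len(ids)),
        }
    )


@pytest.fixture(scope="session")
def design_matrix(scan_design, modulator_table):
    return glm.build_design_matrix(
        scan_design, modulator_table, n_volumes=160, tr=2.0
    )


@pytest.fixture(scope="session")
def identifiable_design_matrix(design_matrix):
    """Full-rank variant: the deliberately redundant movement regressor
    (an exact sum of the four motion-condition event trains) dropped."""
    keep = [i for i, n in enumerate(design_matrix.names) if n != "movement"]
    return glm.DesignMatrix(
        design_matrix.matrix[:, keep],
        [design_matrix.names[i] for i in keep],
        design_matrix.tr,
        design_matrix.highpass_cutoff,
    )


@pytest.fixture(scope="session")
def small_trial_specs():
    """Two trials per motion condition at the default matcher-friendly size."""
    return stimuli.make_trial_specs(seed=1, n_per_condition=2, n_frames=6)
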