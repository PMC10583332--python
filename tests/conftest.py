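import numpy as np
import pytest

from noddinorms import (CohortConfig, generate_participants,
                        generate_roi_values, select_analysis_sample)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-configuration cohort (296 participants) with ROI values and
    the planted-truth map; shared across tests that only read it."""
    cfg = CohortConfig(seed=11)
    participants = generate_participants(cfg)
    roi_table, truth = generate_roi_values(participants, cfg)
    return cfg, participants, roi_table, truth


@pytest.fixture(scope="session")
def analysis_sample(default_cohort):
    cfg, participants, roi_table, truth = default_cohort
    retained, ledger = select_analysis_sample(participants)
    roi = roi_table[roi_table["participant_id"].isin(retained["participant_id"])]
    return cfg, retained, roi


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
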