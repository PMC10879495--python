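import numpy as np
import pandas as pd
import pytest

from gazesal.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-category cohort generated once for the whole session:
    (config, fixation_table, specs, maps)."""
    cfg = CohortConfig(n_schz=4, n_hc=4, n_stimuli=6,
                       categories=("congruent", "physically_salient"),
                       seed=11, map_w=80, map_h=45)
    table, specs, maps = generate_cohort(cfg)
    return cfg, table, specs, maps


@pytest.fixture()
def fixation_frame():
    """Hand-written three-fixation trial for arithmetic checks."""
    return pd.DataFrame({
        "subject_id": ["s1"] * 3,
        "group": ["HC"] * 3,
        "stimulus_id": ["img1"] * 3,
        "category": ["congruent"] * 3,
        "fix_index": [1, 2, 3],
        "x_px": [100.0, 200.0, 300.0],
        "y_px": [50.0, 60.0, 70.0],
        "onset_ms": [0.0, 200.0, 500.0],
        "duration_ms": [200.0, 300.0, 250.0],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
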