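import numpy as np
import pytest

import ska2sig as sk


@pytest.fixture(scope="session")
def small_config():
    """Reduced probe universe; all signal/noise parameters at defaults."""
    return sk.SimulationConfig(n_probes=2000, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return sk.generate_multicohort_study(small_config)


@pytest.fixture(scope="session")
def discovery(small_study):
    """Run the full discovery chain once; reused across tests."""
    screen = sk.interaction_screen(small_study["brain"])
    candidates = sk.select_candidates(screen)
    retained, auc_table = sk.probewise_auc_filter(
        candidates, small_study["train_blood"])
    model = sk.train_biosignature_pca(small_study["train_blood"], retained,
                                      cohort_name="train_blood")
    return {"screen": screen, "candidates": candidates, "retained": retained,
            "auc_table": auc_table, "model": model}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
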