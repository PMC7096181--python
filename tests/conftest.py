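import numpy as np
import pytest

from spikegamma.synth import SyntheticConfig, make_recording


@pytest.fixture(scope="session")
def small_cohort():
    """Four short recordings with strong coupling, shared across tests."""
    cfg = SyntheticConfig(n_recordings=4, n_trials_per_side=10,
                          coupling_depth=0.8, include_wideband=False, seed=7)
    recs, truths = [], []
    for r in range(4):
        rng = np.random.default_rng(np.random.SeedSequence([7, r]))
        rec, tr = make_recording(cfg, rng, f"rec{r}", keep_gamma_phase=True)
        recs.append(rec)
        truths.append(tr)
    return recs, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
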