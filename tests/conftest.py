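import numpy as np
import pandas as pd
import pytest

import voicelight as vl


def synthetic_beta_series(grid_shape=(6, 6, 6), n_runs=4, n_words=12,
                          signal=0.0, noise=1.0, seed=0,
                          informative=None):
    """Build a TrialBetaSeries directly (no GLM): balanced 3-speaker,
    word x speaker design, optional speaker-specific mean patterns on
    ``informative`` voxels (boolean mask)."""
    rng = np.random.default_rng(seed)
    speakers = ["anne", "betty", "chloe"]
    words = [f"w{i:02d}" for i in range(1, n_words + 1)]
    rows = []
    for run in range(1, n_runs + 1):
        for w in words:
            for s in speakers:
                rows.append({"speaker": s, "word": w, "run": run})
    meta = pd.DataFrame(rows)
    n_trials = len(meta)
    betas = rng.normal(0.0, noise, size=(n_trials,) + tuple(grid_shape))
    if signal and informative is not None:
        patt = rng.normal(0.0, signal, size=(3, int(informative.sum())))
        s_idx = meta["speaker"].map(
            {s: i for i, s in enumerate(speakers)}
        ).to_numpy()
        betas[:, informative] += patt[s_idx]
    return vl.TrialBetaSeries(betas=betas, meta=meta,
                              voxel_size=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def default_design():
    return vl.generate_design(vl.DesignSpec(seed=11))


@pytest.fixture(scope="session")
def answered_events(default_design):
    return vl.simulate_responses(
        default_design, vl.BehaviorModel(ability=0.62), seed=12
    )


@pytest.fixture(scope="session")
def small_phantom():
    return vl.PhantomSpec(grid_shape=(8, 8, 6))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return vl.PhantomSpec(grid_shape=(6, 6, 5), noise_sigma=0.0,
                          drift_amplitude=0.0)
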