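import numpy as np
import pandas as pd
import pytest

import holeboard as hb


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size characterization cohort (179 mice, 5 trials), fixed seed."""
    config = hb.SyntheticConfig(seed=1)
    raw, latent_scores, truth = hb.simulate_phase1_cohort(config)
    return {"config": config, "raw": raw, "latent": latent_scores, "truth": truth}


@pytest.fixture(scope="session")
def default_scores(default_cohort):
    return hb.compute_dimension_scores(default_cohort["raw"])


@pytest.fixture(scope="session")
def default_residuals(default_scores):
    """Mixed-model residual trajectories of the default cohort."""
    tidy, meta = hb.fit_residual_model(default_scores)
    ids, traj = hb.residual_matrix(tidy)
    return {"tidy": tidy, "meta": meta, "ids": ids, "trajectories": traj}


@pytest.fixture(scope="session")
def small_cohort():
    """24-mouse cohort for fast unit tests."""
    config = hb.SyntheticConfig(seed=5, n_per_strain={"C": 8, "B6N": 8, "129S2": 8})
    raw, latent_scores, truth = hb.simulate_phase1_cohort(config)
    return {"config": config, "raw": raw, "latent": latent_scores, "truth": truth}


@pytest.fixture(scope="session")
def characterized_truth(default_cohort):
    """Cohort truth with latent types exposed as response types (phase-2 input)."""
    truth = default_cohort["truth"].rename(columns={"latent_type": "response_type"})
    return truth


def two_blob_trajectories(rng, n_per_blob=4, separation=8.0, spread=0.5):
    """Two well-separated Gaussian blobs of 5x3 trajectories."""
    a = rng.normal(0.0, spread, size=(n_per_blob, 5, 3))
    b = rng.normal(0.0, spread, size=(n_per_blob, 5, 3)) + separation / np.sqrt(15)
    X = np.concatenate([a, b])
    labels = np.array([0] * n_per_blob + [1] * n_per_blob)
    return X, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
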