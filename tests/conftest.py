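import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from dualrisk.cohort import (
    Cohort,
    FeatureSpec,
    calibrate_intercept,
    default_scenario,
    generate_cohort,
)


class LinearSigmoidModel:
    """Hand-weighted logistic toy model: sigma(b0 + sum w_j x_j +
    sum v_jk x_j x_k).  The analytic oracle attribution tests score
    against."""

    def __init__(self, weights=None, pair_weights=None, intercept=0.0):
        self.weights = weights or {}
        self.pair_weights = pair_weights or {}
        self.intercept = intercept

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(features), float(self.intercept))
        for name, w in self.weights.items():
            eta = eta + w * features[name].to_numpy(dtype=float)
        for (j, k), v in self.pair_weights.items():
            eta = eta + v * features[j].to_numpy(dtype=float) * features[
                k
            ].to_numpy(dtype=float)
        return expit(eta)


@pytest.fixture(scope="session")
def calibrated_default():
    model = default_scenario()
    calibrate_intercept(model, n_probe=100_000, seed=0)
    return model


@pytest.fixture(scope="session")
def cohort_100k(calibrated_default):
    return generate_cohort(calibrated_default, 100_000, seed=1)


@pytest.fixture(scope="session")
def cohort_20k(calibrated_default):
    return generate_cohort(calibrated_default, 20_000, seed=2)


def binary_cohort(n_features: int, n: int, seed: int, weights=None) -> Cohort:
    """Small all-binary cohort with outcome from a logistic model."""
    rng = np.random.default_rng(seed)
    names = [f"x{i}" for i in range(n_features)]
    feats = pd.DataFrame(
        {nm: rng.integers(0, 2, n).astype(np.int64) for nm in names}
    )
    eta = np.zeros(n)
    for i, nm in enumerate(names):
        w = 0.0 if weights is None else weights.get(nm, 0.0)
        eta += w * feats[nm]
    y = (rng.random(n) < expit(eta - 1.0)).astype(np.int64)
    if y.sum() == 0:
        y[0] = 1
    if y.sum() == n:
        y[0] = 0
    return Cohort(
        features=feats,
        y=y,
        y_documented=y,
        y_coded=np.zeros_like(y),
        feature_specs=[FeatureSpec(nm, "binary") for nm in names],
        seed=seed,
    )
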