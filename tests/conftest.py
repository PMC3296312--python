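"""Shared fixtures.

The heavy session-scoped fixtures (calibrations, 100-test protocol sets,
trained scoring models) are built lazily on first use, so unit tests stay
fast; the acceptance tests share a single generation of each set.
"""

from __future__ import annotations

import numpy as np
import pytest

from svsfuse import (
    LabelImage,
    RaterSet,
    ScoringModel,
    build_protocol,
    calibrate_sigma,
)

# fixed suite seeds: calibration, training set, testing set
CAL_SEED = 11
TRAIN_SEED = 1001
TEST_SEED = 2002


def img(values, **kw) -> LabelImage:
    return LabelImage(np.asarray(values), **kw)


def raters(*arrays) -> RaterSet:
    return RaterSet(tuple(img(a) for a in arrays))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def sigma2d():
    return calibrate_sigma("2d", seed=CAL_SEED)


@pytest.fixture(scope="session")
def sigma3d():
    return calibrate_sigma("3d", seed=CAL_SEED)


@pytest.fixture(scope="session")
def train2d(sigma2d):
    return build_protocol("2d", n_grid=10, seed=TRAIN_SEED, sigma_max=sigma2d)


@pytest.fixture(scope="session")
def test2d(sigma2d):
    return build_protocol("2d", n_grid=10, seed=TEST_SEED, sigma_max=sigma2d)


@pytest.fixture(scope="session")
def train3d(sigma3d):
    return build_protocol("3d", n_grid=10, seed=TRAIN_SEED, sigma_max=sigma3d)


@pytest.fixture(scope="session")
def test3d(sigma3d):
    return build_protocol("3d", n_grid=10, seed=TEST_SEED, sigma_max=sigma3d)


@pytest.fixture(scope="session")
def model2d(train2d):
    return ScoringModel.train(train2d, provenance={"seed": TRAIN_SEED, "set_id": "2d"})


@pytest.fixture(scope="session")
def model3d(train3d):
    return ScoringModel.train(train3d, provenance={"seed": TRAIN_SEED, "set_id": "3d"})


@pytest.fixture(scope="session")
def eval2d(test2d, model2d):
    """Per-test fusion evaluations of the 2D testing set (all methods +
    the 2D-trained selector)."""
    from svsfuse import evaluate_tests

    return evaluate_tests(test2d, {"SVS-2D": model2d}, set_id="2d")


@pytest.fixture(scope="session")
def eval3d(test3d, model3d, model2d):
    """Per-test fusion evaluations of the 3D testing set, with both the
    3D-trained and the cross-applied 2D-trained selector."""
    from svsfuse import evaluate_tests

    return evaluate_tests(test3d, {"SVS-3D": model3d, "SVS-2D": model2d}, set_id="3d")
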