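"""Shared fixtures: small synthetic scenes and the default evaluation cohort.

The expensive end-to-end artefacts (default cohort, its feature cache and
cross-validation results) are session-scoped so the acceptance tests share
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from handuse.data_model import Role, Side
from handuse.synthetic_scenes import CohortConfig, SceneConfig, generate_cohort, generate_task


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One 60-frame bilateral task with both roles planted."""
    config = SceneConfig(
        seed=7,
        n_frames=60,
        frame_size=(128, 72),
        interaction_segments=[
            (10, 40, Side.MORE_AFFECTED, Role.MANIPULATOR),
            (15, 50, Side.LESS_AFFECTED, Role.STABILIZER),
        ],
    )
    return generate_task(config)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 3-subject cohort small enough for per-module tests."""
    config = CohortConfig(
        seed=11, n_subjects=3, tasks_per_subject=3, n_frames=70, frame_size=(128, 72)
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-scale cohort used by the acceptance suite."""
    return generate_cohort(CohortConfig(seed=20260930))


@pytest.fixture(scope="session")
def default_cache(default_cohort):
    from handuse.evaluation import build_feature_cache

    return build_feature_cache(default_cohort)


@pytest.fixture(scope="session")
def losocv_interaction(default_cohort, default_cache):
    from handuse.evaluation import run_losocv

    return run_losocv(default_cohort, "interaction", cache=default_cache)


@pytest.fixture(scope="session")
def lotocv_interaction(default_cohort, default_cache):
    from handuse.evaluation import run_lotocv

    return run_lotocv(default_cohort, "interaction", cache=default_cache)


@pytest.fixture(scope="session")
def losocv_role(default_cohort, default_cache):
    from handuse.evaluation import run_losocv

    return run_losocv(default_cohort, "role", cache=default_cache)
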