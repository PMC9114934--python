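"""Shared fixtures: arm models, task, surrogate rollouts and repertoires.

Expensive artifacts (surrogate trajectory sets, NMF repertoires) are
session-scoped so the whole suite generates them once.
"""

import dataclasses

import numpy as np
import pytest

from synreach import arm as arm_mod
from synreach import expert, synergies, task as task_mod


@pytest.fixture(scope="session")
def model():
    return arm_mod.arm_preset("original")


@pytest.fixture(scope="session")
def task():
    return task_mod.TaskSpec()


@pytest.fixture(scope="session")
def undamped_model(model):
    """Conservative variant for energy-balance checks."""
    return dataclasses.replace(model, joint_damping=0.0)


@pytest.fixture(scope="session")
def home_pose(model):
    return arm_mod.initial_pose(model)


@pytest.fixture(scope="session")
def surrogate_trajectories(model, task):
    """Surrogate-expert rollouts for the two training planes (8 each)."""
    out = {}
    for plane in ("horizontal", "sagittal"):
        targets = task_mod.make_targets(plane, 8, task)
        out[plane] = (expert.expert_trajectories(model, task, targets),
                      targets)
    return out


@pytest.fixture(scope="session")
def repertoires(surrogate_trajectories):
    """NMF repertoires at L=4 and L=8 for both training planes."""
    reps = {}
    for plane, (trajs, _) in surrogate_trajectories.items():
        X = synergies.build_action_matrix([t.actions for t in trajs])
        for L in (4, 8):
            rep = synergies.extract_synergies(
                X, L, synergies.NMFConfig(seed=0))
            rep.provenance["source"] = plane
            reps[(plane, L)] = rep
    return reps


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
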