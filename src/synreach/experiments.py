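"""End-to-end experiment drivers: expert generation, extraction, error maps,
reaching-error reports and the arm-length transfer study.

Three scale profiles are shipped:

``paper``  - PPO experts with the full training budget and 500 CMA-ES
             generations (hours of CPU; the study's own protocol),
``desk``   - surrogate experts, 200 CMA-ES generations (minutes),
``smoke``  - surrogate experts, 2 targets, 50 generations (CI-sized).

A single master seed fans out deterministic per-stage seeds that are
recorded in every artifact, so any reported statistic can be regenerated
from its stored trajectories.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import ppo
from .arm import ArmModel, arm_preset
from .errors import InvalidArgumentError
from .expert import expert_trajectories
from .generalize import CMAConfig, combine, optimize_target_set
from .synergies import NMFConfig, build_action_matrix, extract_synergies
from .task import TaskSpec, make_targets, reaching_errors, task_for

SUB_CM_FLAG = 1.0  # cm; reports flag conditions whose mean beats this


@dataclasses.dataclass(frozen=True)
class ExperimentScale:
    """One named experiment profile."""

    name: str
    expert_source: str            # "surrogate" or "policy"
    n_targets: int = 8
    cma_generations: int = 500
    cma_sigma: float = 1e-3
    nmf_restarts: int = 10
    ppo: ppo.PPOConfig = dataclasses.field(default_factory=ppo.PPOConfig)


SCALES = {
    "paper": ExperimentScale("paper", "policy", cma_generations=500,
                             cma_sigma=1e-3),
    "desk": ExperimentScale("desk", "surrogate", cma_generations=200,
                            cma_sigma=0.3),
    "smoke": ExperimentScale("smoke", "surrogate", n_targets=2,
                             cma_generations=50, cma_sigma=0.3,
                             nmf_restarts=3,
                             ppo=ppo.PPOConfig(n_epochs=2,
                                               steps_per_epoch=400,
                                               grad_steps_per_epoch=10)),
}


def get_scale(name: str) -> ExperimentScale:
    try:
        return SCALES[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown scale {name!r}; choose from {sorted(SCALES)}") from None


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = int(master) & 0xFFFFFFFF
    for ch in stage:
        h = (h * 31 + ord(ch)) & 0xFFFFFFFF
    return h % (2 ** 31 - 1)


def make_experts(model: ArmModel, task: TaskSpec, plane: str,
                 scale: ExperimentScale, seed: int, policy=None):
    """Expert trajectories for one plane's training target set."""
    targets = make_targets(plane, 8, task)
    if scale.expert_source == "surrogate":
        trajs = expert_trajectories(model, task, targets)
    else:
        if policy is None:
            cfg = dataclasses.replace(scale.ppo,
                                      seed=stage_seed(seed, f"ppo-{plane}"))
            policy, _, _ = ppo.train_policy(model, task, targets, cfg)
        trajs = ppo.rollout_policy(policy, model, task, targets,
                                   deterministic=True)
    for tr in trajs:
        tr.metadata["plane"] = plane
    return trajs


def repertoire_from_trajectories(trajs, L: int, scale: ExperimentScale,
                                 seed: int, label: str):
    X = build_action_matrix([tr.actions for tr in trajs])
    cfg = NMFConfig(seed=stage_seed(seed, f"nmf-{label}-{L}"),
                    n_restarts=scale.nmf_restarts)
    rep = extract_synergies(X, L, cfg)
    rep.provenance["source"] = label
    return rep


def build_repertoires(model: ArmModel, task: TaskSpec, scale: ExperimentScale,
                      seed: int, L_values, planes=("horizontal", "sagittal")):
    """Experts + repertoires at every requested synergy count per plane."""
    reps = {}
    experts = {}
    for plane in planes:
        trajs = make_experts(model, task, plane, scale, seed)
        experts[plane] = trajs
        for L in L_values:
            reps[(plane, L)] = repertoire_from_trajectories(
                trajs, L, scale, seed, plane)
    return experts, reps


def summarize(groups: dict, task: TaskSpec) -> pd.DataFrame:
    """Mean +- SD reaching errors (cm) per condition.

    ``groups`` maps a condition label to a list of (trajectory, target)
    pairs.  SD is the sample standard deviation (n-1).  Empty groups are
    dropped with a warning column-free row omitted.
    """
    rows = []
    for label, pairs in groups.items():
        if not pairs:
            continue
        errs = np.array([reaching_errors(tr, task, tg) for tr, tg in pairs])
        n = len(errs)
        rows.append({
            "condition": label,
            "n": n,
            "error_target_mean_cm": errs[:, 0].mean(),
            "error_target_sd_cm": errs[:, 0].std(ddof=1) if n > 1 else 0.0,
            "error_home_mean_cm": errs[:, 1].mean(),
            "error_home_sd_cm": errs[:, 1].std(ddof=1) if n > 1 else 0.0,
            "sub_1cm": bool(errs[:, 0].mean() < SUB_CM_FLAG),
        })
    return pd.DataFrame(rows)


def run_policy_benchmark(model: ArmModel, task: TaskSpec,
                         scale: ExperimentScale, seed: int,
                         policies: dict | None = None) -> pd.DataFrame:
    """Expert performance on learned sets (8 and 32 directions) and on the
    unlearned frontal/upper sets (the extrapolation-failure check)."""
    groups = {}
    for plane in ("horizontal", "sagittal"):
        policy = (policies or {}).get(plane)
        if scale.expert_source == "policy" and policy is None:
            raise InvalidArgumentError(
                f"no checkpoint for the {plane} policy; train one with "
                f"`synreach train --plane {plane}` first")

        def rollout(targets):
            if scale.expert_source == "surrogate":
                return expert_trajectories(model, task, targets)
            return ppo.rollout_policy(policy, model, task, targets)

        for n_dir, tag in ((8, "learned-8"), (32, "interpolation-32")):
            targets = make_targets(plane, n_dir, task)
            groups[f"{plane} targets / {plane} expert ({tag})"] = list(
                zip(rollout(targets), targets))
        for new_plane in ("frontal", "upper"):
            targets = make_targets(new_plane, 8, task)
            groups[f"{new_plane} targets / {plane} expert"] = list(
                zip(rollout(targets), targets))
    return summarize(groups, task)


def optimize_cell(reps, Lh, Ls, model, task, targets, scale, seed):
    """One (L_h, L_s) cell of the error map."""
    members = []
    if Lh > 0:
        members.append(reps[("horizontal", Lh)])
    if Ls > 0:
        members.append(reps[("sagittal", Ls)])
    if not members:
        raise InvalidArgumentError("(0, 0) has no synergies to optimize")
    combined = combine(members)
    cfg = CMAConfig(generations=scale.cma_generations,
                    initial_step=scale.cma_sigma,
                    seed=stage_seed(seed, f"cma-{Lh}-{Ls}"))
    return optimize_target_set(combined, model, task, targets, cfg)


def run_error_map(model: ArmModel, task: TaskSpec, plane: str,
                  Lh_range, Ls_range, scale: ExperimentScale,
                  seed: int, reps=None) -> pd.DataFrame:
    """Grid of mean reaching errors over (L_h, L_s) combinations."""
    L_values = sorted({L for L in [*Lh_range, *Ls_range] if L > 0})
    if reps is None:
        _, reps = build_repertoires(model, task, scale, seed, L_values)
    targets = make_targets(plane, scale.n_targets, task)
    rows = []
    for Lh in Lh_range:
        for Ls in Ls_range:
            if Lh == 0 and Ls == 0:
                continue
            _, summary = optimize_cell(reps, Lh, Ls, model, task, targets,
                                       scale, seed)
            rows.append({"L_h": Lh, "L_s": Ls, **summary})
    return pd.DataFrame(rows)


def run_transfer_study(source_presets, eval_preset: str,
                       scale: ExperimentScale, seed: int,
                       L: int = 4, plane: str = "frontal") -> pd.DataFrame:
    """Extract synergies on source arms, optimize them on the target arm.

    Each source arm's experts reach its own (length-scaled) home position;
    the extracted repertoires are then recombined and optimized for the
    evaluation arm's targets.
    """
    eval_model = arm_preset(eval_preset)
    eval_task = task_for(eval_model)
    targets = make_targets(plane, scale.n_targets, eval_task)
    rows = []
    for preset in source_presets:
        src_model = arm_preset(preset)
        src_task = task_for(src_model)
        reps = {}
        for pl in ("horizontal", "sagittal"):
            trajs = make_experts(src_model, src_task, pl, scale,
                                 stage_seed(seed, f"transfer-{preset}"))
            reps[(pl, L)] = repertoire_from_trajectories(
                trajs, L, scale, seed, f"{preset}-{pl}")
        _, summary = optimize_cell(reps, L, L, eval_model, eval_task,
                                   targets, scale,
                                   stage_seed(seed, f"cma-transfer-{preset}"))
        rows.append({"source_arm": preset, "eval_arm": eval_preset,
                     "L_h": L, "L_s": L, **summary,
                     "sub_1cm": summary["error_target_mean_cm"] < SUB_CM_FLAG})
    return pd.DataFrame(rows)
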