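"""Proximal policy optimization for the reaching task.

Self-contained numpy implementation: two-hidden-layer tanh networks for the
Gaussian policy (state-independent log standard deviations) and the critic,
generalized advantage estimation, the clipped surrogate objective, and Adam.
The trainer is environment-agnostic (it consumes an episode-sampling
callable), with a thin arm-specific wrapper matching the reaching task.

Default hyperparameters are the reaching study's: 3000 epochs of 10000
steps, gamma 0.99, clip 0.2, GAE lambda 0.97, learning rates 3e-4 / 1e-3,
80 gradient steps per epoch for each network.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .arm import ArmModel
from .errors import InvalidArgumentError, TrainingDivergedError
from .task import TaskSpec, Trajectory, run_episode


@dataclasses.dataclass(frozen=True)
class PolicyNetworkSpec:
    """Network trunk: two tanh hidden layers of 256 units by default."""

    input_size: int = 18
    hidden: tuple = (256, 256)
    output_size: int = 7


@dataclasses.dataclass(frozen=True)
class PPOConfig:
    n_epochs: int = 3000
    steps_per_epoch: int = 10000
    discount: float = 0.99
    clip_ratio: float = 0.2
    gae_lambda: float = 0.97
    policy_lr: float = 0.0003
    critic_lr: float = 0.001
    grad_steps_per_epoch: int = 80
    seed: int = 0
    entropy_coef: float = 0.0       # off by default
    kl_stop: float | None = None    # off by default
    normalize_obs: bool = True

    def __post_init__(self):
        if min(self.n_epochs, self.steps_per_epoch,
               self.grad_steps_per_epoch) <= 0:
            raise InvalidArgumentError("counts must be positive")
        if not (0 < self.discount <= 1 and 0 < self.gae_lambda <= 1):
            raise InvalidArgumentError("discount and lambda must lie in (0,1]")


class MLP:
    """Dense tanh network with manual backprop."""

    def __init__(self, sizes, rng, out_scale=1.0):
        self.W, self.b = [], []
        for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            scale = np.sqrt(2.0 / (n_in + n_out))
            if i == len(sizes) - 2:
                scale *= out_scale
            self.W.append(rng.normal(0.0, scale, size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))

    def forward(self, X):
        h = np.atleast_2d(X)
        cache = [h]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.tanh(h)
            cache.append(h)
        return h, cache

    def __call__(self, X):
        return self.forward(X)[0]

    def backward(self, cache, dY):
        """Gradients of sum(dY * output) w.r.t. parameters."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        d = dY
        for i in range(len(self.W) - 1, -1, -1):
            if i < len(self.W) - 1:
                d = d * (1.0 - cache[i + 1] ** 2)  # through tanh
            gW[i] = cache[i].T @ d
            gb[i] = d.sum(axis=0)
            d = d @ self.W[i].T
        return gW, gb

    @property
    def params(self):
        return self.W + self.b

    def grads_list(self, gW, gb):
        return gW + gb


class Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RunningNorm:
    """Streaming mean/variance observation normalizer."""

    def __init__(self, dim):
        self.mean = np.zeros(dim)
        self.var = np.ones(dim)
        self.count = 1e-4

    def update(self, batch):
        batch = np.atleast_2d(batch)
        bmean = batch.mean(axis=0)
        bvar = batch.var(axis=0)
        bn = batch.shape[0]
        delta = bmean - self.mean
        tot = self.count + bn
        self.mean += delta * bn / tot
        self.var = (self.var * self.count + bvar * bn
                    + delta ** 2 * self.count * bn / tot) / tot
        self.count = tot

    def __call__(self, x):
        return np.clip((x - self.mean) / np.sqrt(self.var + 1e-8), -10, 10)


class GaussianPolicy:
    """Diagonal-Gaussian torque policy with state-independent log-std."""

    def __init__(self, spec: PolicyNetworkSpec, seed=0, init_std=0.5,
                 normalize_obs=True):
        self.spec = spec
        rng = np.random.default_rng(seed)
        sizes = [spec.input_size, *spec.hidden, spec.output_size]
        self.net = MLP(sizes, rng, out_scale=0.01)
        self.log_std = np.full(spec.output_size, np.log(init_std))
        self.obs_norm = RunningNorm(spec.input_size) if normalize_obs else None

    def _norm(self, obs):
        return self.obs_norm(obs) if self.obs_norm is not None else obs

    def mean_action(self, obs):
        return self.net(self._norm(obs))

    def act(self, obs, rng=None, deterministic=False):
        mu = self.net(self._norm(obs))[0]
        if deterministic or rng is None:
            return mu
        return mu + np.exp(self.log_std) * rng.standard_normal(mu.shape)

    def log_prob(self, obs_normed, actions):
        mu, _ = self.net.forward(obs_normed)
        std = np.exp(self.log_std)
        z = (actions - mu) / std
        return (-0.5 * (z ** 2).sum(axis=1)
                - self.log_std.sum()
                - 0.5 * mu.shape[1] * np.log(2 * np.pi))

    def controller(self, rng=None, deterministic=False):
        """Observation -> torque callable for run_episode."""
        return lambda obs: self.act(obs, rng=rng, deterministic=deterministic)


def compute_gae(rewards, values, discount, lam):
    """GAE(gamma, lambda) advantages and return targets.

    ``values`` must be one element longer than ``rewards`` (bootstrap value
    of the state after the last step; 0 for a finished fixed-horizon task).
    """
    rewards = np.asarray(rewards, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.shape[0] != rewards.shape[0] + 1:
        raise InvalidArgumentError("values must be one longer than rewards")
    deltas = rewards + discount * values[1:] - values[:-1]
    adv = np.empty_like(deltas)
    acc = 0.0
    for t in range(len(deltas) - 1, -1, -1):
        acc = deltas[t] + discount * lam * acc
        adv[t] = acc
    return adv, adv + values[:-1]


def policy_surrogate_grads(policy: GaussianPolicy, obs, act, adv, logp_old,
                           clip_ratio, entropy_coef=0.0):
    """Gradients of the (negated) clipped surrogate w.r.t. policy parameters.

    Returns (grads, logp) with grads ordered as net weights, net biases,
    log_std.  The gradient flows only through samples where min() selects
    the unclipped branch: ratio <= 1+eps for positive advantages, ratio >=
    1-eps for negative ones.
    """
    mu, cache = policy.net.forward(obs)
    std = np.exp(policy.log_std)
    z = (act - mu) / std
    logp = (-0.5 * (z ** 2).sum(axis=1) - policy.log_std.sum()
            - 0.5 * mu.shape[1] * np.log(2 * np.pi))
    ratio = np.exp(logp - logp_old)
    active = np.where(adv >= 0, ratio <= 1 + clip_ratio,
                      ratio >= 1 - clip_ratio)
    coef = -(active * ratio * adv) / obs.shape[0]
    if not np.all(np.isfinite(coef)):
        raise TrainingDivergedError("non-finite policy loss",
                                    {"ratio_max": float(np.max(ratio))})
    dmu = coef[:, None] * (z / std)               # d(-surr)/d mu
    gW, gb = policy.net.backward(cache, dmu)
    dlogstd = (coef[:, None] * (z ** 2 - 1.0)).sum(axis=0)
    if entropy_coef:
        dlogstd -= entropy_coef  # d(-c*H)/dlogstd = -c per dimension
    return policy.net.grads_list(gW, gb) + [dlogstd], logp


def _minibatches(n, batch_count, rng):
    """Yield index slices covering a shuffled range in batch_count pieces."""
    idx = rng.permutation(n)
    size = max(1, int(np.ceil(n / batch_count)))
    start = 0
    while True:
        if start >= n:
            idx = rng.permutation(n)
            start = 0
        yield idx[start:start + size]
        start += size


def ppo_update(policy: GaussianPolicy, critic: MLP, batch: dict,
               config: PPOConfig, policy_opt: Adam, critic_opt: Adam,
               rng) -> dict:
    """One epoch of clipped-surrogate and critic updates.

    ``batch`` holds normalized observations, raw actions, advantages,
    old log-probabilities and return targets.  Advantages are standardized
    per batch.  Runs ``grad_steps_per_epoch`` minibatch Adam steps for the
    policy and the same number for the critic.
    """
    obs = batch["obs"]
    act = batch["act"]
    adv = batch["adv"]
    adv = (adv - adv.mean()) / (adv.std() + 1e-8)
    logp_old = batch["logp_old"]
    ret = batch["ret"]
    n = obs.shape[0]
    eps = config.clip_ratio

    stats = {}
    gen = _minibatches(n, config.grad_steps_per_epoch, rng)
    for _ in range(config.grad_steps_per_epoch):
        mb = next(gen)
        grads, logp = policy_surrogate_grads(
            policy, obs[mb], act[mb], adv[mb], logp_old[mb], eps,
            entropy_coef=config.entropy_coef)
        policy_opt.step(policy.net.params + [policy.log_std], grads)
        if config.kl_stop is not None:
            kl = float(np.mean(logp_old[mb] - logp))
            if kl > config.kl_stop:
                break
    stats["approx_kl"] = float(np.mean(
        logp_old - policy.log_prob(obs, act)))

    gen = _minibatches(n, config.grad_steps_per_epoch, rng)
    for _ in range(config.grad_steps_per_epoch):
        mb = next(gen)
        v, cache = critic.forward(obs[mb])
        err = v[:, 0] - ret[mb]
        if not np.all(np.isfinite(err)):
            raise TrainingDivergedError("non-finite critic loss")
        gW, gb = critic.backward(cache, (2.0 * err / len(mb))[:, None])
        critic_opt.step(critic.params, critic.grads_list(gW, gb))
    v, _ = critic.forward(obs)
    stats["critic_mse"] = float(np.mean((v[:, 0] - ret) ** 2))
    return stats


def train(sample_episode, obs_dim, act_dim, config: PPOConfig,
          spec: PolicyNetworkSpec | None = None, progress=None,
          checkpoint_path=None, checkpoint_every=100):
    """Generic PPO loop over an episode-sampling callable.

    ``sample_episode(controller, rng)`` must roll out one episode and return
    (observations (T,obs_dim), actions (T,act_dim), rewards (T,)).  Returns
    (policy, critic, log) where log is a list of per-epoch dicts.  When
    ``checkpoint_path`` is given, the policy is saved there every
    ``checkpoint_every`` epochs so an interrupted run stays recoverable.
    """
    spec = spec or PolicyNetworkSpec(input_size=obs_dim, output_size=act_dim)
    rng = np.random.default_rng(config.seed)
    policy = GaussianPolicy(spec, seed=config.seed,
                            normalize_obs=config.normalize_obs)
    critic = MLP([obs_dim, *spec.hidden, 1], np.random.default_rng(
        config.seed + 1))
    popt = Adam(policy.net.params + [policy.log_std], config.policy_lr)
    copt = Adam(critic.params, config.critic_lr)
    log = []
    for epoch in range(config.n_epochs):
        obs_l, act_l, eps = [], [], []
        steps = 0
        while steps < config.steps_per_epoch:
            raw = []

            def recording_controller(o):
                a = policy.act(o, rng=rng)
                raw.append(a)
                return a

            o, a, r = sample_episode(recording_controller, rng)
            obs_l.append(o)
            act_l.append(np.asarray(raw))
            eps.append(r)
            steps += len(r)
        obs_raw = np.concatenate(obs_l)
        if policy.obs_norm is not None:
            policy.obs_norm.update(obs_raw)
        obs = policy._norm(obs_raw)
        act = np.concatenate(act_l)
        logp_old = policy.log_prob(obs, act)
        advs, rets = [], []
        start = 0
        for r in eps:
            o_ep = obs[start:start + len(r)]
            v = critic(o_ep)[:, 0]
            v = np.append(v, 0.0)  # fixed horizon: terminal value 0
            a_ep, ret_ep = compute_gae(r, v, config.discount,
                                       config.gae_lambda)
            advs.append(a_ep)
            rets.append(ret_ep)
            start += len(r)
        batch = {"obs": obs, "act": act, "adv": np.concatenate(advs),
                 "ret": np.concatenate(rets), "logp_old": logp_old}
        stats = ppo_update(policy, critic, batch, config, popt, copt, rng)
        stats["epoch"] = epoch
        stats["mean_G"] = float(np.mean([r.sum() for r in eps]))
        log.append(stats)
        if progress is not None:
            progress(stats)
        if checkpoint_path is not None and (epoch + 1) % checkpoint_every == 0:
            save_policy(checkpoint_path, policy, config)
    return policy, critic, log


def train_policy(model: ArmModel, task: TaskSpec, targets,
                 config: PPOConfig | None = None,
                 spec: PolicyNetworkSpec | None = None, progress=None,
                 checkpoint_path=None, checkpoint_every=100):
    """Train a reaching policy over a target set (uniform target sampling)."""
    config = config or PPOConfig()
    targets = list(targets)
    if not targets:
        raise InvalidArgumentError("target set must be nonempty")

    def sample_episode(controller, rng):
        target = targets[rng.integers(len(targets))]
        traj = run_episode(model, task, target, controller)
        return traj.observations, traj.actions, traj.rewards

    policy, critic, log = train(sample_episode, 18, 7, config, spec,
                                progress, checkpoint_path, checkpoint_every)
    return policy, critic, log


def rollout_policy(policy: GaussianPolicy, model: ArmModel, task: TaskSpec,
                   targets, deterministic=True, seed=0) -> list:
    """One episode per target; deterministic mode uses the mean action."""
    out = []
    for k, target in enumerate(targets):
        rng = None if deterministic else np.random.default_rng(seed + k)
        traj = run_episode(model, task, target,
                           policy.controller(rng=rng,
                                             deterministic=deterministic))
        traj.metadata["source"] = "policy"
        out.append(traj)
    return out


# ---------------------------------------------------------------------------
# checkpointing

def save_policy(path, policy: GaussianPolicy, config: PPOConfig | None = None):
    path = Path(path)
    arrays = {f"W{i}": w for i, w in enumerate(policy.net.W)}
    arrays.update({f"b{i}": b for i, b in enumerate(policy.net.b)})
    arrays["log_std"] = policy.log_std
    if policy.obs_norm is not None:
        arrays["norm_mean"] = policy.obs_norm.mean
        arrays["norm_var"] = policy.obs_norm.var
        arrays["norm_count"] = np.array(policy.obs_norm.count)
    np.savez_compressed(path, **arrays)
    meta = {"spec": dataclasses.asdict(policy.spec)}
    if config is not None:
        meta["config"] = dataclasses.asdict(config)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_policy(path) -> GaussianPolicy:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = PolicyNetworkSpec(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in meta["spec"].items()})
    with np.load(path) as z:
        policy = GaussianPolicy(spec, normalize_obs="norm_mean" in z)
        policy.net.W = [z[f"W{i}"] for i in range(len(policy.net.W))]
        policy.net.b = [z[f"b{i}"] for i in range(len(policy.net.b))]
        policy.log_std = z["log_std"]
        if policy.obs_norm is not None:
            policy.obs_norm.mean = z["norm_mean"]
            policy.obs_norm.var = z["norm_var"]
            policy.obs_norm.count = float(z["norm_count"])
    return policy
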