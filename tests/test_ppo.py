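"""GAE, the clipped surrogate and the full training loop."""

import dataclasses

import numpy as np
import pytest

from synreach import ppo
from synreach.errors import InvalidArgumentError


def gae_oracle(rewards, values, gamma, lam):
    """Brute-force telescoped double sum over all (t, k) TD errors."""
    T = len(rewards)
    deltas = [rewards[t] + gamma * values[t + 1] - values[t]
              for t in range(T)]
    adv = np.zeros(T)
    for t in range(T):
        for k in range(T - t):
            adv[t] += (gamma * lam) ** k * deltas[t + k]
    return adv


class TestGAE:
    def test_all_zero(self):
        adv, ret = ppo.compute_gae(np.zeros(5), np.zeros(6), 0.99, 0.97)
        assert np.all(adv == 0) and np.all(ret == 0)

    def test_lambda_zero_is_td_error(self, rng):
        r = rng.normal(size=6)
        v = rng.normal(size=7)
        adv, _ = ppo.compute_gae(r, v, 0.99, 0.0)
        assert np.allclose(adv, r + 0.99 * v[1:] - v[:-1])

    def test_two_step_example_against_oracle(self):
        adv, ret = ppo.compute_gae([1.0, 1.0], [0.0, 0.0, 0.0], 0.99, 0.97)
        want = gae_oracle([1.0, 1.0], [0.0, 0.0, 0.0], 0.99, 0.97)
        assert np.allclose(adv, want, atol=1e-12)
        assert np.allclose(ret, want, atol=1e-12)  # values are zero

    def test_random_instances_against_oracle(self, rng):
        for _ in range(10):
            T = int(rng.integers(2, 30))
            r = rng.normal(size=T)
            v = rng.normal(size=T + 1)
            g, l = rng.uniform(0.5, 1.0, size=2)
            adv, ret = ppo.compute_gae(r, v, g, l)
            assert np.allclose(adv, gae_oracle(r, v, g, l), atol=1e-12)
            assert np.allclose(ret, adv + v[:-1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ppo.compute_gae(np.zeros(5), np.zeros(5), 0.99, 0.97)


def _tiny_policy(obs_dim=3, act_dim=2, seed=0):
    spec = ppo.PolicyNetworkSpec(input_size=obs_dim, hidden=(8, 8),
                                 output_size=act_dim)
    return ppo.GaussianPolicy(spec, seed=seed, normalize_obs=False)


def _surrogate_loss(policy, obs, act, adv, logp_old, eps):
    logp = policy.log_prob(obs, act)
    ratio = np.exp(logp - logp_old)
    clipped = np.clip(ratio, 1 - eps, 1 + eps)
    return -np.mean(np.minimum(ratio * adv, clipped * adv))


class TestClippedSurrogate:
    def _batch(self, policy, n=32, seed=1):
        rng = np.random.default_rng(seed)
        obs = rng.normal(size=(n, 3))
        act = np.stack([policy.act(o, rng=rng) for o in obs])
        adv = rng.normal(size=n)
        logp_old = policy.log_prob(obs, act)
        return obs, act, adv, logp_old

    def test_gradient_matches_finite_difference(self):
        policy = _tiny_policy()
        obs, act, adv, lp0 = self._batch(policy)
        lp0 = lp0 - 0.3  # perturb so ratios leave 1 and clipping engages
        grads, _ = ppo.policy_surrogate_grads(policy, obs, act, adv, lp0, 0.2)
        params = policy.net.params + [policy.log_std]
        h = 1e-6
        for p, g in zip(params, grads):
            idx = np.unravel_index(np.argmax(np.abs(g)), p.shape)
            old = p[idx]
            p[idx] = old + h
            up = _surrogate_loss(policy, obs, act, adv, lp0, 0.2)
            p[idx] = old - h
            dn = _surrogate_loss(policy, obs, act, adv, lp0, 0.2)
            p[idx] = old
            assert np.isclose(g[idx], (up - dn) / (2 * h), rtol=1e-4,
                              atol=1e-8)

    def test_ratio_one_equals_advantage_weighted_objective(self):
        policy = _tiny_policy()
        obs, act, adv, lp0 = self._batch(policy, seed=2)
        loss_clipped = _surrogate_loss(policy, obs, act, adv, lp0, 0.2)
        assert np.isclose(loss_clipped, -np.mean(adv))

    def test_clipped_samples_contribute_no_gradient(self):
        policy = _tiny_policy()
        obs, act, adv, lp0 = self._batch(policy, seed=3)
        adv = np.abs(adv)             # all positive advantages
        lp0 = lp0 - 1.0               # ratios e^1 >> 1 + eps: all clipped
        grads, _ = ppo.policy_surrogate_grads(policy, obs, act, adv, lp0,
                                              0.2)
        assert all(np.allclose(g, 0.0) for g in grads)

    def test_infinite_clip_equals_vanilla_policy_gradient(self):
        """With the clip disabled and ratios at 1, the surrogate gradient is
        the plain advantage-weighted score-function gradient."""
        policy = _tiny_policy(seed=4)
        obs, act, adv, lp0 = self._batch(policy, seed=4)
        grads, _ = ppo.policy_surrogate_grads(policy, obs, act, adv, lp0,
                                              np.inf)
        # vanilla policy gradient by finite differences of -E[A logp]
        params = policy.net.params + [policy.log_std]
        h = 1e-6
        for p, g in zip(params, grads):
            idx = np.unravel_index(np.argmax(np.abs(g)), p.shape)
            old = p[idx]
            p[idx] = old + h
            up = -np.mean(adv * policy.log_prob(obs, act))
            p[idx] = old - h
            dn = -np.mean(adv * policy.log_prob(obs, act))
            p[idx] = old
            assert np.isclose(g[idx], (up - dn) / (2 * h), rtol=1e-4,
                              atol=1e-8)


class TestPPOUpdate:
    def test_single_batch_critic_overfit(self, rng):
        policy = _tiny_policy(seed=5)
        critic = ppo.MLP([3, 8, 8, 1], np.random.default_rng(5))
        cfg = ppo.PPOConfig(n_epochs=1, steps_per_epoch=32,
                            grad_steps_per_epoch=20)
        obs = rng.normal(size=(32, 3))
        act = np.stack([policy.act(o, rng=rng) for o in obs])
        batch = {"obs": obs, "act": act, "adv": rng.normal(size=32),
                 "ret": rng.normal(size=32),
                 "logp_old": policy.log_prob(obs, act)}
        before = float(np.mean((critic(obs)[:, 0] - batch["ret"]) ** 2))
        stats = ppo.ppo_update(policy, critic, batch, cfg,
                               ppo.Adam(policy.net.params + [policy.log_std],
                                        3e-4),
                               ppo.Adam(critic.params, 1e-2),
                               np.random.default_rng(0))
        assert stats["critic_mse"] < before

    def test_default_config_hyperparameters(self):
        cfg = ppo.PPOConfig()
        assert cfg.n_epochs == 3000
        assert cfg.steps_per_epoch == 10000
        assert cfg.discount == 0.99
        assert cfg.clip_ratio == 0.2
        assert cfg.gae_lambda == 0.97
        assert cfg.policy_lr == 0.0003
        assert cfg.critic_lr == 0.001
        assert cfg.grad_steps_per_epoch == 80

    def test_default_network_spec(self):
        spec = ppo.PolicyNetworkSpec()
        assert spec.input_size == 18
        assert spec.hidden == (256, 256)
        assert spec.output_size == 7


def point_mass_episode(controller, rng):
    """1-d.f. reciprocating point-mass reach with the task's reward shape."""
    dt, T = 0.01, 100
    x0, xt, k1, k2 = 0.0, 0.15, 0.002, 0.2
    x, v = x0, 0.0
    obs = np.zeros((T, 4))
    rews = np.zeros(T)
    for t in range(T):
        o = np.array([x, v, xt, t * dt])
        obs[t] = o
        a = float(np.clip(np.asarray(controller(o)).ravel()[0], -2, 2))
        for _ in range(5):
            v += (a - 0.05 * v) / 0.05 * 0.002
            x += v * 0.002
        r = -k2 * a * a * dt
        if t == 49:
            r -= (x - xt) ** 2 + k1 * v * v
        if t == 99:
            r -= (x - x0) ** 2 + k1 * v * v
        rews[t] = r
    return obs, None, rews


class TestTraining:
    def test_point_mass_smoke_closes_half_the_gap(self):
        """Scaled-down training on the point-mass task must close at least
        50% of the reward gap to zero from its first-epoch level."""
        spec = ppo.PolicyNetworkSpec(input_size=4, hidden=(64, 64),
                                     output_size=1)
        cfg = ppo.PPOConfig(n_epochs=40, steps_per_epoch=1000, seed=0)
        _, _, log = ppo.train(point_mass_episode, 4, 1, cfg, spec)
        g0 = log[0]["mean_G"]
        g1 = np.mean([row["mean_G"] for row in log[-5:]])
        assert (g1 - g0) / (0.0 - g0) >= 0.5

    def test_arm_policy_action_contract(self, model, task):
        """Untrained policy rollout: 7-d torques within the actuator limit."""
        from synreach.task import make_targets

        targets = make_targets("horizontal", 8, task)
        cfg = ppo.PPOConfig(n_epochs=1, steps_per_epoch=200,
                            grad_steps_per_epoch=5, seed=0)
        spec = ppo.PolicyNetworkSpec(hidden=(16, 16))
        policy, _, log = ppo.train_policy(model, task, targets, cfg, spec)
        trajs = ppo.rollout_policy(policy, model, task, targets)
        assert len(trajs) == 8
        for tr in trajs:
            assert tr.actions.shape == (100, 7)
            assert np.all(np.abs(tr.actions) <= model.torque_limit + 1e-12)

    def test_rollouts_reproducible(self, model, task):
        from synreach.task import make_targets

        targets = make_targets("horizontal", 2, task)
        policy = ppo.GaussianPolicy(ppo.PolicyNetworkSpec(hidden=(8, 8)),
                                    seed=1)
        a = ppo.rollout_policy(policy, model, task, targets)
        b = ppo.rollout_policy(policy, model, task, targets)
        assert np.array_equal(a[0].actions, b[0].actions)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        policy = ppo.GaussianPolicy(
            ppo.PolicyNetworkSpec(input_size=5, hidden=(8, 8),
                                  output_size=2), seed=9)
        policy.obs_norm.update(rng.normal(size=(50, 5)))
        ppo.save_policy(tmp_path / "p.npz", policy, ppo.PPOConfig())
        back = ppo.load_policy(tmp_path / "p.npz")
        x = rng.normal(size=5)
        assert np.allclose(back.mean_action(x), policy.mean_action(x))
        assert back.spec == policy.spec
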