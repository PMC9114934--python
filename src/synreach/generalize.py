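"""Generalization to new targets by combining synergy repertoires.

Repertoires extracted from different experts are concatenated column-wise
into one basis W' (L' = sum of member counts).  A candidate solution
x in R^L' is mapped to nonnegative activation magnitudes h' = |x|, decoded
into an open-loop torque sequence W'h' (positive-minus-negative blocks), and
scored by the accumulated task reward G of the resulting episode.  CMA-ES
(covariance matrix adaptation evolution strategy, standard rank-mu update
with cumulative step-size adaptation) maximizes G over h' per target.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import arm as arm_mod
from . import _dynamics as dyn
from .arm import ArmModel
from .errors import InvalidArgumentError
from .synergies import SynergyRepertoire, unstack_column
from .task import TaskSpec, Trajectory, rewards_for, run_open_loop

DIVERGED_SCORE = -1.0e18


@dataclasses.dataclass
class CombinedRepertoire:
    """Column-concatenation [W_1 W_2 ...] of member repertoires."""

    W: np.ndarray
    M: int
    T: int
    member_labels: tuple
    column_spans: tuple  # (start, stop) per member

    @property
    def L(self) -> int:
        return self.W.shape[1]


def combine(repertoires) -> CombinedRepertoire:
    """Concatenate member repertoires into one combined basis."""
    reps = list(repertoires)
    if not reps:
        raise InvalidArgumentError("need at least one repertoire")
    M, T = reps[0].M, reps[0].T
    if any(r.M != M or r.T != T for r in reps):
        raise InvalidArgumentError("repertoires must share (M, T)")
    blocks, spans, labels = [], [], []
    start = 0
    for r in reps:
        blocks.append(r.W)
        spans.append((start, start + r.L))
        start += r.L
        labels.append(r.provenance.get("source", "unknown"))
    return CombinedRepertoire(np.concatenate(blocks, axis=1), M, T,
                              tuple(labels), tuple(spans))


def candidate_to_activity(x) -> np.ndarray:
    """Element-wise absolute value: CMA-ES searches all of R^L'."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("candidate must be finite")
    return np.abs(x)


def decode(combined, h) -> np.ndarray:
    """Activity vector -> signed T x M torque sequence W'h' (pos - neg)."""
    W = combined.W if hasattr(combined, "W") else np.asarray(combined, float)
    M, T = combined.M, combined.T
    h = np.asarray(h, dtype=float)
    if h.shape != (W.shape[1],):
        raise InvalidArgumentError("activity length must equal L'")
    return unstack_column(W @ h, M, T)


def default_population(L: int) -> int:
    """4 + floor(3 ln L') candidates per generation."""
    return 4 + int(math.floor(3.0 * math.log(L)))


@dataclasses.dataclass(frozen=True)
class CMAConfig:
    """CMA-ES settings; the objective is the accumulated reward G."""

    initial_step: float = 1e-3   # sigma of the initial Gaussian
    population: int | None = None  # default 4 + floor(3 ln L')
    generations: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.initial_step <= 0:
            raise InvalidArgumentError("initial_step must be positive")
        if self.population is not None and self.population < 4:
            raise InvalidArgumentError("population must be >= 4")


@dataclasses.dataclass
class OptimizationResult:
    best_activity: np.ndarray
    best_G: float
    curve: np.ndarray            # best-so-far G per generation
    trajectory: Trajectory | None
    config: CMAConfig
    n_diverged: int = 0


class CMAES:
    """Minimal covariance matrix adaptation evolution strategy (rank-mu)."""

    def __init__(self, x0, sigma, population, seed):
        self.n = len(x0)
        self.mean = np.asarray(x0, dtype=float).copy()
        self.sigma = float(sigma)
        self.lam = population
        self.rng = np.random.default_rng(seed)

        mu = self.lam // 2
        w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
        self.weights = w / w.sum()
        self.mu = mu
        self.mueff = 1.0 / np.sum(self.weights ** 2)
        n, mueff = self.n, self.mueff
        self.cs = (mueff + 2) / (n + mueff + 5)
        self.ds = 1 + 2 * max(0.0, math.sqrt((mueff - 1) / (n + 1)) - 1) + self.cs
        self.cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
        self.c1 = 2 / ((n + 1.3) ** 2 + mueff)
        self.cmu = min(1 - self.c1,
                       2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
        self.chiN = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))
        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.count = 0
        self._decompose()

    def _decompose(self):
        self.C = 0.5 * (self.C + self.C.T)
        vals, vecs = np.linalg.eigh(self.C)
        vals = np.maximum(vals, 1e-20)
        self.B = vecs
        self.D = np.sqrt(vals)
        self.invsqrtC = vecs @ np.diag(1.0 / self.D) @ vecs.T

    def ask(self) -> np.ndarray:
        z = self.rng.standard_normal((self.lam, self.n))
        self.last_y = z * self.D @ self.B.T  # y ~ N(0, C)
        return self.mean + self.sigma * self.last_y

    def tell(self, xs, losses) -> None:
        order = np.argsort(losses)
        xs = np.asarray(xs, dtype=float)[order[:self.mu]]
        old_mean = self.mean
        self.mean = self.weights @ xs
        y = (self.mean - old_mean) / self.sigma
        self.ps = ((1 - self.cs) * self.ps
                   + math.sqrt(self.cs * (2 - self.cs) * self.mueff)
                   * (self.invsqrtC @ y))
        hsig = (np.linalg.norm(self.ps)
                / math.sqrt(1 - (1 - self.cs) ** (2 * (self.count + 1)))
                < (1.4 + 2 / (self.n + 1)) * self.chiN)
        self.pc = ((1 - self.cc) * self.pc
                   + (math.sqrt(self.cc * (2 - self.cc) * self.mueff) * y
                      if hsig else 0.0))
        artmp = (xs - old_mean) / self.sigma
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc)
                               + (0.0 if hsig else
                                  self.cc * (2 - self.cc)) * self.C)
                  + self.cmu * (artmp.T * self.weights) @ artmp)
        self.sigma *= math.exp(self.cs / self.ds
                               * (np.linalg.norm(self.ps) / self.chiN - 1))
        self.count += 1
        self._decompose()


def optimize_candidates(objective, n_dim, config: CMAConfig):
    """Maximize a black-box objective(x) over R^n with CMA-ES.

    Returns (best_x, best_value, best-so-far curve).  The initial mean is
    zero and the initial step size config.initial_step.
    """
    lam = config.population or default_population(n_dim)
    es = CMAES(np.zeros(n_dim), config.initial_step, lam, config.seed)
    best_x = np.zeros(n_dim)
    best_v = -np.inf
    curve = np.empty(config.generations)
    for g in range(config.generations):
        xs = es.ask()
        values = np.array([objective(x) for x in xs])
        k = int(np.argmax(values))
        if values[k] > best_v:
            best_v = float(values[k])
            best_x = xs[k].copy()
        es.tell(xs, -values)
        curve[g] = best_v
    return best_x, best_v, curve


def _episode_score(model: ArmModel, task: TaskSpec, target, torques, ctx):
    """Accumulated reward of an open-loop episode (fast path)."""
    q0, params = ctx
    p, E, axis, m, com, inert, tip = params
    angles, vels, tippos, tipvel, done = dyn.open_loop_episode(
        q0, torques, p, E, axis, m, com, inert,
        np.asarray(model.gravity, dtype=float), model.joint_armature,
        model.joint_damping,
        np.asarray(model.joint_lower_limits, dtype=float),
        np.asarray(model.joint_upper_limits, dtype=float),
        model.torque_limit, model.integrator_substep, model.n_substeps, tip)
    if done < task.samples_per_episode:
        return DIVERGED_SCORE
    acts = np.clip(torques, -model.torque_limit, model.torque_limit)
    return float(rewards_for(task, target, tippos, tipvel, acts).sum())


def optimize_activities(combined: CombinedRepertoire, model: ArmModel,
                        task: TaskSpec, target,
                        config: CMAConfig | None = None) -> OptimizationResult:
    """CMA-ES over activation magnitudes for one target."""
    config = config or CMAConfig()
    target = np.asarray(target, dtype=float)
    q0 = arm_mod.initial_pose(model, task.home)
    ctx = (q0, arm_mod.chain_parameters(model))
    n_div = [0]

    def objective(x):
        torques = decode(combined, candidate_to_activity(x))
        g = _episode_score(model, task, target, torques, ctx)
        if g == DIVERGED_SCORE:
            n_div[0] += 1
        return g

    best_x, best_g, curve = optimize_candidates(objective, combined.L, config)
    h = candidate_to_activity(best_x)
    traj = run_open_loop(model, task, target, decode(combined, h))
    traj.metadata["source"] = "synergy"
    return OptimizationResult(h, best_g, curve, traj, config, n_div[0])


def optimize_target_set(combined: CombinedRepertoire, model: ArmModel,
                        task: TaskSpec, targets,
                        config: CMAConfig | None = None):
    """Independent per-target optimization plus mean +- SD error summary.

    Per-target seeds are derived deterministically from config.seed.
    Returns (results, summary) where summary holds mean/SD reaching errors
    in centimetres at both checkpoints.
    """
    from .task import reaching_errors

    config = config or CMAConfig()
    results = []
    errs = []
    for k, target in enumerate(targets):
        cfg = dataclasses.replace(config, seed=(config.seed + 1000003 * k)
                                  % (2 ** 31))
        res = optimize_activities(combined, model, task, target, cfg)
        results.append(res)
        errs.append(reaching_errors(res.trajectory, task, target))
    errs = np.asarray(errs)
    summary = {
        "error_target_mean_cm": float(errs[:, 0].mean()),
        "error_target_sd_cm": float(errs[:, 0].std(ddof=1)) if len(errs) > 1 else 0.0,
        "error_home_mean_cm": float(errs[:, 1].mean()),
        "error_home_sd_cm": float(errs[:, 1].std(ddof=1)) if len(errs) > 1 else 0.0,
        "n_targets": len(errs),
    }
    return results, summary
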