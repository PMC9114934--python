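"""Spatio-temporal motor-synergy extraction from signed torque trajectories.

A trial is a T x M signed action sequence (T samples, M joints).  Because NMF
factors only nonnegative data, each trial is first split into its positive
part a+ = max(a, 0) and negative part a- = -min(a, 0) (so a = a+ - a-), then
stacked into one column of the action matrix X (2MT rows: all positive
samples channel-major, then all negative ones).  X ~ W H with W >= 0
(2MT x L, the synergies) and H >= 0 (L x N, per-trial activation magnitudes).

The factorization uses multiplicative updates minimizing the squared
Frobenius error with multiple random restarts; reconstruction quality is
scored by R^2 against the signed trials.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

from .errors import InvalidArgumentError, UndefinedMetricError


@dataclasses.dataclass(frozen=True)
class NMFConfig:
    """Multiplicative-update NMF settings."""

    max_iter: int = 5000
    tol: float = 1e-6          # relative objective improvement
    n_restarts: int = 10
    seed: int = 0
    track_objective: bool = False  # keep the per-iteration objective curve


@dataclasses.dataclass
class ActionMatrix:
    """Nonnegative stacked action matrix, 2MT x N."""

    values: np.ndarray
    M: int
    T: int

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[0] != 2 * self.M * self.T:
            raise InvalidArgumentError("action matrix must be 2MT x N")
        if np.any(self.values < 0):
            raise InvalidArgumentError("action matrix must be nonnegative")

    @property
    def N(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class SynergyRepertoire:
    """Nonnegative synergy basis W (2MT x L) with extraction metadata."""

    W: np.ndarray
    H: np.ndarray
    M: int
    T: int
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise InvalidArgumentError("W and H must be nonnegative")
        if self.W.shape[0] != 2 * self.M * self.T:
            raise InvalidArgumentError("W must have 2MT rows")
        if self.W.shape[1] != self.H.shape[0]:
            raise InvalidArgumentError("W columns must match H rows")

    @property
    def L(self) -> int:
        return self.W.shape[1]

    def waveform(self, l: int) -> np.ndarray:
        """Signed T x M torque waveform of synergy l (positive - negative)."""
        return unstack_column(self.W[:, l], self.M, self.T)


def split_pos_neg(actions):
    """Positive and negative parts: (max(a,0), -min(a,0))."""
    a = np.asarray(actions, dtype=float)
    if not np.all(np.isfinite(a)):
        raise InvalidArgumentError("actions must be finite")
    return np.maximum(a, 0.0), -np.minimum(a, 0.0)


def stack_column(actions) -> np.ndarray:
    """One trial (T x M signed) -> 2MT nonnegative stacked column.

    Layout: all T samples of a+ in time-major order (each sample contributes
    its M channels), followed by the same for a-.
    """
    pos, neg = split_pos_neg(actions)
    return np.concatenate([pos.ravel(), neg.ravel()])


def unstack_column(column, M: int, T: int) -> np.ndarray:
    """Inverse of stack_column: 2MT vector -> signed T x M actions."""
    column = np.asarray(column, dtype=float)
    if column.shape != (2 * M * T,):
        raise InvalidArgumentError("column length must be 2MT")
    pos = column[:M * T].reshape(T, M)
    neg = column[M * T:].reshape(T, M)
    return pos - neg


def build_action_matrix(trials) -> ActionMatrix:
    """Stack N trials (each T x M signed) into the 2MT x N action matrix."""
    trials = [np.asarray(t, dtype=float) for t in trials]
    if not trials:
        raise InvalidArgumentError("need at least one trial")
    T, M = trials[0].shape
    if any(t.shape != (T, M) for t in trials):
        raise InvalidArgumentError("all trials must share (T, M)")
    X = np.column_stack([stack_column(t) for t in trials])
    return ActionMatrix(X, M=M, T=T)


def _nmf_multiplicative(X, L, rng, max_iter, tol, track=False):
    """Multiplicative-update NMF for squared Frobenius error (Lee-Seung)."""
    eps = 1e-12
    scale = np.sqrt(X.mean() / max(L, 1)) + eps
    W = scale * rng.random((X.shape[0], L)) + eps
    H = scale * rng.random((L, X.shape[1])) + eps
    prev = None
    curve = []
    for it in range(max_iter):
        W *= (X @ H.T) / (W @ (H @ H.T) + eps)
        H *= (W.T @ X) / ((W.T @ W) @ H + eps)
        obj = float(np.linalg.norm(X - W @ H) ** 2)
        if track:
            curve.append(obj)
        if prev is not None and prev - obj <= tol * max(prev, eps):
            return W, H, obj, True, curve
        prev = obj
    return W, H, prev, False, curve


def extract_synergies(X: ActionMatrix, L: int,
                      config: NMFConfig | None = None) -> SynergyRepertoire:
    """Best-of-restarts NMF factorization into L spatio-temporal synergies.

    Columns of W are normalized to unit Euclidean norm (H rescaled to
    compensate) and ordered by descending total activation (H row sums).
    """
    config = config or NMFConfig()
    if not 1 <= L <= X.N:
        raise InvalidArgumentError(f"L must lie in [1, N={X.N}]")
    rng = np.random.default_rng(config.seed)
    best = None
    converged = False
    curve = None
    for _ in range(config.n_restarts):
        W, H, obj, conv, c = _nmf_multiplicative(
            X.values, L, rng, config.max_iter, config.tol,
            track=config.track_objective)
        if best is None or obj < best[2]:
            best = (W, H, obj)
            converged = conv
            curve = c
    W, H, obj = best
    # resolve the scale indeterminacy, then order by activation mass
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    H = H * norms[:, None]
    order = np.argsort(-H.sum(axis=1), kind="stable")
    W, H = W[:, order], H[order]
    trials = [unstack_column(X.values[:, n], X.M, X.T) for n in range(X.N)]
    recon = [unstack_column((W @ H[:, n]), X.M, X.T) for n in range(X.N)]
    prov = {"L": L, "seed": config.seed, "restarts": config.n_restarts,
            "converged": bool(converged),
            "r_squared": r_squared(trials, recon)}
    if config.track_objective:
        prov["objective_curve"] = curve
    return SynergyRepertoire(W, H, M=X.M, T=X.T, provenance=prov)


def r_squared(original_trials, reconstructed_trials) -> float:
    """Pooled reconstruction R^2 over all trials.

    1 - SS_res / SS_tot, where SS_res sums squared action errors over all
    samples and trials, and SS_tot sums squared deviations from the grand
    mean action (one M-vector over all samples of all trials).
    """
    orig = [np.asarray(t, dtype=float) for t in original_trials]
    reco = [np.asarray(t, dtype=float) for t in reconstructed_trials]
    if len(orig) != len(reco) or any(a.shape != b.shape
                                     for a, b in zip(orig, reco)):
        raise InvalidArgumentError("trial lists must match in shape")
    A = np.concatenate(orig, axis=0)
    Ahat = np.concatenate(reco, axis=0)
    abar = A.mean(axis=0)
    ss_tot = float(((A - abar) ** 2).sum())
    if ss_tot == 0.0:
        raise UndefinedMetricError("zero total sum of squares")
    ss_res = float(((A - Ahat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def r_squared_per_trial(original_trials, reconstructed_trials) -> list:
    """Per-trial R^2 (each trial scored against its own mean action)."""
    out = []
    for a, ahat in zip(original_trials, reconstructed_trials):
        out.append(r_squared([a], [ahat]))
    return out


def fit_activities(W, trial) -> np.ndarray:
    """Nonnegative least-squares activities of one held-out trial."""
    W = np.asarray(W, dtype=float)
    x = stack_column(trial)
    if W.shape[0] != x.shape[0]:
        raise InvalidArgumentError("trial shape does not match W rows")
    h, _ = nnls(W, x)
    return h


def reconstruct(repertoire: SynergyRepertoire, h) -> np.ndarray:
    """Signed T x M reconstruction from an activity vector."""
    return unstack_column(repertoire.W @ np.asarray(h, float),
                          repertoire.M, repertoire.T)


def reconstruction_curve(trials, L_range, config: NMFConfig | None = None):
    """(L, pooled R^2) for each synergy count in L_range."""
    X = build_action_matrix(trials)
    orig = [np.asarray(t, dtype=float) for t in trials]
    out = []
    for L in L_range:
        rep = extract_synergies(X, L, config)
        reco = [reconstruct(rep, rep.H[:, n]) for n in range(X.N)]
        out.append((L, r_squared(orig, reco)))
    return out


# ---------------------------------------------------------------------------
# repertoire container: arrays in .npz plus a JSON sidecar

def save_repertoire(path, rep: SynergyRepertoire) -> None:
    path = Path(path)
    np.savez_compressed(path, W=rep.W, H=rep.H,
                        M=np.array(rep.M), T=np.array(rep.T))
    path.with_suffix(".json").write_text(
        json.dumps(rep.provenance, default=str, indent=1))


def load_repertoire(path) -> SynergyRepertoire:
    path = Path(path)
    with np.load(path) as z:
        rep = SynergyRepertoire(z["W"], z["H"], M=int(z["M"]), T=int(z["T"]))
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        rep.provenance = json.loads(sidecar.read_text())
    return rep
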