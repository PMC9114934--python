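"""Shared independent oracles used by the acceptance checks."""

import numpy as np


def planted_instance(seed, M=2, T=10, N=8, L=3):
    """Identifiable planted nonnegative factorization (anchors + disjoint
    positive/negative supports); see test_synergies for the rationale."""
    rng = np.random.default_rng(seed)
    MT = M * T
    W = rng.random((2 * MT, L)) ** 2
    sign_mask = rng.random(MT) < 0.5
    W[:MT][~sign_mask] = 0.0
    W[MT:][sign_mask] = 0.0
    for l in range(L):
        row = int(np.flatnonzero(sign_mask)[l])
        W[row] = 0.0
        W[row, l] = 1.0
        W[MT + row] = 0.0
    H = rng.random((L, N)) ** 2 + 0.1
    H[:, :L] = np.diag(1.0 + rng.random(L))
    return W, H


def gae_brute_force(rewards, values, gamma, lam):
    """Exhaustive double sum over all (t, k) temporal-difference errors."""
    T = len(rewards)
    deltas = [rewards[t] + gamma * values[t + 1] - values[t]
              for t in range(T)]
    adv = np.zeros(T)
    for t in range(T):
        for k in range(T - t):
            adv[t] += (gamma * lam) ** k * deltas[t + k]
    return adv
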